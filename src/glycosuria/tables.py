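"""Published per-subject reference values for the five-subject IVGTT cohort.

The raw time courses of the study cohort were never deposited, so these
per-subject estimates and anthropometrics are the only quantitative
anchor available: they parameterize the synthetic-data generator, seed
physiological starting points for fitting, and let the reporting module
check its cohort-summary conventions against printed rows.

All frames are indexed by subject id 1..5.  Units: GFR mL/min (use
``gfr_l_min`` for L/min), rates 1/min, concentrations mM, volumes L,
T^max mmol/min, TinTub min, phi cm/min, Loss (mmol/min)^2 for glucose
loss fits and mM^2 for glycemia fits.  Each glucose-loss table exists in
two variants keyed by the glycemia input used for the fit:
"interpolated" (piecewise-linear through the measured glycemias) or
"fitted" (two-compartment model prediction).
"""

from __future__ import annotations

import pandas as pd

_SUBJECT_INDEX = pd.Index([1, 2, 3, 4, 5], name="subject")

#: Anthropometrics and glomerular filtration rate of the cohort.
SUBJECTS = pd.DataFrame(
    {
        "sex": ["M", "F", "M", "F", "M"],
        "age": [85, 90, 74, 91, 88],
        "weight_kg": [72.0, 50.0, 69.0, 70.0, 50.0],
        "gfr_ml_min": [67.9, 23.0, 14.0, 67.5, 36.1],
    },
    index=_SUBJECT_INDEX,
)
SUBJECTS["gfr_l_min"] = SUBJECTS["gfr_ml_min"] / 1000.0

#: Two-compartment glycemia model estimates per subject (k_12 and k_g as
#: printed, 2-decimal rounded; recompute from the free parameters via
#: `glycemia.derive_equilibrium_rates` when full precision matters).
GLYCEMIA_FITS = pd.DataFrame(
    {
        "k_x1": [0.029, 0.040, 0.026, 0.000, 0.017],
        "k_21": [0.123, 0.159, 0.200, 0.050, 0.200],
        "G_b": [4.62, 6.39, 4.87, 4.35, 5.02],
        "Q_20": [32.64, 44.31, 41.55, 65.10, 21.47],
        "V_p": [5.80, 9.95, 9.64, 7.66, 7.20],
        "k_12": [0.10, 0.23, 0.23, 0.03, 0.34],
        "k_g": [0.79, 2.56, 1.22, 3.33e-05, 0.63],
    },
    index=_SUBJECT_INDEX,
)

#: RTH fits with the slope fixed at its theoretical value S = 1.
RTH_FIXED_S = {
    "interpolated": pd.DataFrame(
        {
            "T": [10.960, 9.029, 6.921, 16.603, 9.636],
            "V_B": [0.046, 0.006, 0.013, 0.014, 0.141],
            "loss": [6.03e-03, 6.42e-04, 2.03e-03, 4.81e-04, 3.75e-06],
        },
        index=_SUBJECT_INDEX,
    ),
    "fitted": pd.DataFrame(
        {
            "T": [11.416, 9.227, 7.095, 16.727, 5.018],
            "V_B": [0.064, 0.011, 0.024, 0.045, 0.477],
            "loss": [3.28e-03, 8.62e-04, 3.05e-03, 1.63e-03, 1.03e-05],
        },
        index=_SUBJECT_INDEX,
    ),
}

#: RTH fits with the slope S free (estimation bound (0, 10]).
RTH_FREE_S = {
    "interpolated": pd.DataFrame(
        {
            "T": [12.080, 10.291, 7.920, 10.558, 10.117],
            "S": [1.601, 3.478, 1.666, 0.100, 10.000],
            "V_B": [0.073, 0.016, 0.018, 0.010, 1.235],
            "loss": [1.58e-03, 2.53e-04, 1.14e-03, 1.05e-03, 3.64e-06],
        },
        index=_SUBJECT_INDEX,
    ),
    "fitted": pd.DataFrame(
        {
            "T": [11.921, 9.971, 9.809, 13.237, 5.018],
            "S": [1.174, 1.860, 5.161, 0.225, 0.260],
            "V_B": [0.074, 0.020, 0.090, 0.022, 0.115],
            "loss": [2.58e-03, 6.84e-04, 2.01e-03, 1.04e-03, 9.96e-06],
        },
        index=_SUBJECT_INDEX,
    ),
}

#: PTR fits (T^max in whole-tubule mmol/min; TinTub = L/phi with L = 1.5 cm).
PTR_FITS = {
    "interpolated": pd.DataFrame(
        {
            "tmax": [0.870, 0.234, 0.136, 1.392, 0.411],
            "tintub": [1.279, 1.198, 2.721, 1.000, 2.127],
            "phi": [1.173, 1.252, 0.551, 1.500, 0.705],
            "G_half": [0.590, 0.551, 0.671, 1.248, 0.001],
            "nu": [3.604, 4.098, 2.089, 1.272, 0.534],
            "V_B": [0.046, 0.004, 0.009, 0.010, 0.154],
            "loss": [1.81e-03, 1.76e-04, 1.52e-04, 4.32e-06, 4.89e-08],
        },
        index=_SUBJECT_INDEX,
    ),
    "fitted": pd.DataFrame(
        {
            "tmax": [0.91, 0.249, 0.146, 2.459, 0.405],
            "tintub": [1.207, 2.072, 3.520, 1.981, 3.464],
            "phi": [1.243, 0.724, 0.426, 0.757, 0.433],
            "G_half": [0.462, 0.198, 0.659, 5.334, 0.156],
            "nu": [5.606, 18.805, 2.077, 0.774, 13.089],
            "V_B": [0.068, 0.010, 0.019, 0.014, 0.272],
            "loss": [1.38e-03, 1.30e-04, 5.61e-05, 1.32e-04, 2.96e-07],
        },
        index=_SUBJECT_INDEX,
    ),
}


def glycemia_params_for_subject(subject: int, with_dose: bool = True):
    """Full `GlycemiaParams` for a cohort subject, k_12/k_g rederived at
    full precision from the equilibrium relations; dose 0.33 g/kg."""
    from .glycemia import GlycemiaParams, dose_mmol

    row = GLYCEMIA_FITS.loc[subject]
    D = dose_mmol(SUBJECTS.loc[subject, "weight_kg"]) if with_dose else 0.0
    return GlycemiaParams.from_free(
        k_x1=row["k_x1"], k_21=row["k_21"], G_b=row["G_b"],
        V_p=row["V_p"], Q_20=row["Q_20"], D=D)
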