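import pytest

import glycosuria as g


@pytest.fixture(scope="session")
def reference_subject():
    """Midpoint reference subject used across recovery and signature tests."""
    return g.reference_subject()


@pytest.fixture(scope="session")
def reference_curve(reference_subject):
    return g.solve_two_compartment(reference_subject.glycemia, t_end=60.0)


@pytest.fixture(scope="session")
def subject1_scenario():
    """Generator overridden to the published subject-1 operating point —
    the scenario whose slow bladder washout makes the phase-space loop
    resolvable at 5-min urine sampling."""
    from glycosuria.tables import GLYCEMIA_FITS, PTR_FITS, RTH_FIXED_S, SUBJECTS

    row3 = GLYCEMIA_FITS.loc[1]
    row6 = PTR_FITS["interpolated"].loc[1]
    rho = SUBJECTS.loc[1, "gfr_l_min"]
    return g.make_subject(seed=0, overrides={
        "weight_kg": SUBJECTS.loc[1, "weight_kg"], "gfr_l_min": rho,
        "G_b": row3["G_b"], "k_x1": row3["k_x1"], "k_21": row3["k_21"],
        "Q_20": row3["Q_20"], "V_p": row3["V_p"],
        "k_T": row6["tmax"] / rho, "G_half": row6["G_half"],
        "nu": row6["nu"], "phi": row6["phi"], "V_B": row6["V_B"],
        "T": RTH_FIXED_S["interpolated"].loc[1, "T"]})


@pytest.fixture(scope="session")
def noiseless_ptr_dataset(reference_subject):
    return g.generate_dataset(reference_subject, model="ptr",
                              noise=g.NoiseModel(glycemia_cv=0.0,
                                                 urine_cv=0.0, seed=0))


@pytest.fixture(scope="session")
def noiseless_ptr_fit(reference_subject, reference_curve, noiseless_ptr_dataset):
    """Default-protocol PTR fit of the noiseless reference dataset
    (shared: it is the slowest single fit in the suite)."""
    est = g.PTRRegressor(reference_curve, rho=reference_subject.gfr_l_min,
                         u_flow=reference_subject.u_flow,
                         baseline=reference_subject.glycemia.G_b, seed=0)
    est.fit(noiseless_ptr_dataset.urine_loss.times,
            noiseless_ptr_dataset.urine_loss.values)
    return est
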