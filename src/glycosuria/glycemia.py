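"""Two-compartment plasma glucose kinetics after an intravenous bolus.

Plasma glucose content ``Q1`` (mmol) exchanges with a storage compartment
``Q2`` (interstitial fluid) and is eliminated linearly from plasma:

    dQ1/dt = -(k_x1 + k_21) Q1 + k_12 Q2 + k_g
    dQ2/dt =  k_21 Q1 - k_12 Q2

with ``Q1(0) = G_b V_p + D`` (baseline content plus the instantaneous IV
dose) and ``Q2(0) = Q_20``.  Plasma concentration is ``C(t) = Q1(t)/V_p``.
Requiring the pre-bolus state ``(G_b V_p, Q_20)`` to be an equilibrium fixes

    k_12 = k_21 G_b V_p / Q_20        k_g = k_x1 G_b V_p

so only five parameters are free when fitting.

The system is linear with constant forcing, so it is solved in closed form
(matrix exponential of the augmented 3x3 system); a numerical integrator is
used only as an independent oracle in the test suite.  A piecewise-linear
interpolant of measured glycemias is provided as the model-free alternative
input to the glucose-loss models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .exceptions import InsufficientDataError, ValidationError

#: Molar mass of glucose, g/mol; fixed project-wide for mg <-> mmol conversion.
GLUCOSE_MOLAR_MASS = 180.156


def dose_mmol(weight_kg: float, dose_g_per_kg: float = 0.33) -> float:
    """IV bolus dose in mmol for a body weight, default 0.33 g glucose per kg."""
    return dose_g_per_kg * weight_kg * 1000.0 / GLUCOSE_MOLAR_MASS


def derive_equilibrium_rates(
    k_x1: float, k_21: float, G_b: float, V_p: float, Q_20: float
) -> tuple[float, float]:
    """Transfer rate ``k_12`` and net hepatic input ``k_g`` from equilibrium.

    With these values both compartment derivatives vanish at the baseline
    state ``(G_b V_p, Q_20)`` with no dose.

    Returns
    -------
    (k_12, k_g) : 1/min and mmol/min.
    """
    for name, v in [("k_x1", k_x1), ("k_21", k_21), ("G_b", G_b),
                    ("V_p", V_p), ("Q_20", Q_20)]:
        if not np.isfinite(v) or v < 0:
            raise ValidationError(f"{name} must be finite and >= 0, got {v}")
    if Q_20 == 0:
        raise ValidationError("Q_20 = 0: storage compartment is degenerate")
    baseline_content = G_b * V_p
    return k_21 * baseline_content / Q_20, k_x1 * baseline_content


@dataclass(frozen=True)
class GlycemiaParams:
    """Full parameter set of the two-compartment glycemia model.

    Rates are 1/min, ``k_g`` mmol/min, ``G_b`` mM, ``V_p`` L, ``Q_20`` and
    ``D`` mmol.
    """

    k_x1: float
    k_21: float
    k_12: float
    k_g: float
    G_b: float
    V_p: float
    Q_20: float
    D: float = 0.0

    def __post_init__(self):
        for name in ("k_x1", "k_21", "k_12", "k_g", "G_b", "V_p", "Q_20", "D"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValidationError(f"{name} must be finite, got {v}")
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        if self.V_p <= 0:
            raise ValidationError("V_p must be > 0")
        if self.G_b <= 0:
            raise ValidationError("G_b must be > 0")

    @classmethod
    def from_free(cls, k_x1, k_21, G_b, V_p, Q_20, D=0.0) -> "GlycemiaParams":
        """Build from the five free parameters, deriving k_12 and k_g."""
        k_12, k_g = derive_equilibrium_rates(k_x1, k_21, G_b, V_p, Q_20)
        return cls(k_x1=k_x1, k_21=k_21, k_12=k_12, k_g=k_g,
                   G_b=G_b, V_p=V_p, Q_20=Q_20, D=D)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("k_x1", "k_21", "k_12", "k_g", "G_b", "V_p", "Q_20", "D")}


@dataclass(frozen=True)
class TimeSeries:
    """Sampled observations: times in min, values in mM or mmol/min."""

    times: np.ndarray
    values: np.ndarray
    kind: str = "glycemia"  # "glycemia" (mM) or "urine_loss" (mmol/min)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValidationError("times and values must be 1-D of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(v)):
            raise ValidationError("times and values must be finite")
        if np.any(v < 0):
            raise ValidationError("values must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size


class GlycemiaCurve:
    """Continuous plasma glucose concentration C(t), mM, on [0, t_end].

    Either the closed-form two-compartment solution (``mode="model"``) or a
    piecewise-linear interpolant of samples (``mode="interpolated"``).
    Evaluation outside the domain is clamped to the boundary values.
    """

    def __init__(self, evaluate, t_end: float, mode: str):
        self._evaluate = evaluate
        self.t_end = float(t_end)
        self.mode = mode

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        c = np.maximum(self._evaluate(np.atleast_1d(t)), 0.0)
        return float(c[0]) if scalar else c


def _augmented_matrix(p: GlycemiaParams) -> np.ndarray:
    """3x3 system [[A, b], [0, 0]] so x(t) = expm(M t) @ (Q1_0, Q2_0, 1)."""
    return np.array([
        [-(p.k_x1 + p.k_21), p.k_12, p.k_g],
        [p.k_21, -p.k_12, 0.0],
        [0.0, 0.0, 0.0],
    ])


def solve_two_compartment(params: GlycemiaParams, t_end: float = 60.0) -> GlycemiaCurve:
    """Closed-form solution curve C(t) = Q1(t)/V_p.

    The constant-coefficient linear system with constant forcing is solved
    exactly through the augmented matrix exponential; when the augmented
    matrix is cleanly diagonalizable the eigendecomposition is vectorized
    over evaluation times, otherwise (coincident or zero rates, e.g. a
    subject with k_x1 = 0) expm is applied per time point.
    """
    M = _augmented_matrix(params)
    x0 = np.array([params.G_b * params.V_p + params.D, params.Q_20, 1.0])
    V_p = params.V_p

    eigvals, eigvecs = np.linalg.eig(M)
    use_eig = np.linalg.cond(eigvecs) < 1e8
    if use_eig:
        w = np.linalg.solve(eigvecs, x0)
        row = eigvecs[0]  # Q1 component

        def evaluate(t):
            # (n_t, 3) phases; real part: complex pairs cancel exactly
            phases = np.exp(np.outer(t, eigvals))
            return (phases * (row * w)).sum(axis=1).real / V_p
    else:
        def evaluate(t):
            out = np.empty(t.shape)
            for j, tj in enumerate(t):
                out[j] = (scipy.linalg.expm(M * tj) @ x0)[0]
            return out / V_p

    return GlycemiaCurve(evaluate, t_end, mode="model")


def with_baseline(curve: GlycemiaCurve, baseline: float) -> GlycemiaCurve:
    """Clamp a curve to the pre-bolus baseline at t <= 0.

    The model curve jumps to the post-bolus peak at t = 0+, but the renal
    system starts at equilibrium under the *baseline* glycemia; driving
    curves handed to the glucose-loss simulators should therefore report
    G_b at t = 0.
    """
    def evaluate(tt):
        return np.where(tt <= 0, baseline, curve(tt))

    return GlycemiaCurve(evaluate, curve.t_end, mode=curve.mode)


def interpolate_samples(samples: TimeSeries, t_end: float | None = None) -> GlycemiaCurve:
    """Piecewise-linear glycemia curve through measured samples.

    Constant extrapolation at the boundary values outside the sampled
    interval.
    """
    if len(samples) < 2:
        raise InsufficientDataError("interpolation needs at least 2 samples")
    t, v = samples.times, samples.values
    if t_end is None:
        t_end = t[-1]

    def evaluate(tt):
        return np.interp(tt, t, v)

    return GlycemiaCurve(evaluate, t_end, mode="interpolated")
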