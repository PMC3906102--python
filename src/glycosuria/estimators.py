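"""Per-subject ordinary-least-squares model fitting.

Each model is exposed as a scikit-learn style regressor: ``fit(X, y)``
takes sampling times (min) and observations, ``predict(X)`` returns the
model curve at requested times, and the estimated parameters land in
trailing-underscore attributes.  The objective is the plain sum of
squared residuals, minimized by a derivative-free Nelder-Mead simplex on
transformed coordinates (log for positive parameters, scaled logit for
parameters with an upper bound such as the RTH slope S and the Hill
exponent), with seeded multi-start jitter to mitigate local minima and a
polishing loop of simplex restarts from the incumbent optimum.

Module-level ``fit_glycemia`` / ``fit_glucose_loss`` / ``ols_loss`` are
thin functional wrappers over the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (ConvergenceError, GridMismatchError,
                         InsufficientDataError, ValidationError)
from .glycemia import (GLUCOSE_MOLAR_MASS, GlycemiaCurve, GlycemiaParams,
                       TimeSeries, solve_two_compartment, with_baseline)
from .threshold import RTHParams, rth_influx, simulate_rth
from .tubule import (BladderParams, PTRParams, TubuleGeometry, default_dt,
                     simulate_ptr)

_PENALTY = 1e12


# ---------------------------------------------------------------------------
# parameter transforms

@dataclass(frozen=True)
class FreeParam:
    """One free parameter: bounds on the natural scale and its transform.

    ``transform`` is "log" (positive, generous box enforced by penalty)
    or "logit" (bounded in (0, upper], mapped through a scaled logistic).
    """

    name: str
    init: float
    lo: float
    hi: float
    transform: str = "log"

    def __post_init__(self):
        if self.transform not in ("log", "logit"):
            raise ValidationError(f"unknown transform {self.transform!r}")
        if not (0 < self.lo < self.hi and np.isfinite(self.hi)):
            raise ValidationError("bounds must satisfy 0 < lo < hi < inf")
        if not (self.lo <= self.init <= self.hi):
            raise ValidationError(
                f"initial value {self.init} outside [{self.lo}, {self.hi}]"
                f" for {self.name}")

    def to_opt(self, x: float) -> float:
        if self.transform == "log":
            return np.log(x)
        return np.log(x / (self.hi - x)) if x < self.hi else 36.0

    def from_opt(self, y: float) -> float:
        if self.transform == "log":
            return np.exp(np.clip(y, -700, 700))
        return self.hi / (1.0 + np.exp(-np.clip(y, -700, 700)))

    def penalty(self, x: float) -> float:
        """Distance outside the box (0 inside); logit is bounded by design."""
        if self.transform == "logit":
            return 0.0
        if x < self.lo:
            return 1.0 + self.lo / max(x, 1e-300)
        if x > self.hi:
            return 1.0 + x / self.hi
        return 0.0


@dataclass
class FitSpec:
    """Free-parameter list plus simplex settings for one fit."""

    params: list[FreeParam]
    n_restarts: int = 5
    jitter: float = 0.3
    maxfev: int = 2000
    xatol: float = 1e-10
    fatol: float = 1e-14
    polish_rounds: int = 4

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.params]

    def to_opt(self, values: dict) -> np.ndarray:
        return np.array([p.to_opt(values[p.name]) for p in self.params])

    def from_opt(self, y: np.ndarray) -> dict:
        return {p.name: p.from_opt(yi) for p, yi in zip(self.params, y)}


@dataclass
class FitResult:
    """Outcome of one OLS fit: parameters on the natural scale, the sum
    of squared residuals, and optimizer diagnostics."""

    model: str
    params: dict
    loss: float
    converged: bool
    n_fev: int
    residuals: np.ndarray
    predicted: np.ndarray
    times: np.ndarray
    seed: int | None = None
    extras: dict = field(default_factory=dict)


def ols_loss(observed: TimeSeries, predicted: TimeSeries) -> float:
    """Sum of squared residuals between two series on the same grid."""
    if len(observed) != len(predicted) or not np.allclose(
            observed.times, predicted.times, rtol=0, atol=1e-9):
        raise GridMismatchError("observed and predicted time grids differ")
    r = observed.values - predicted.values
    return float(r @ r)


def _minimize_multistart(objective, spec: FitSpec, y0: np.ndarray,
                         rng: np.random.Generator):
    """Seeded multi-start Nelder-Mead plus restart-polishing from the best."""
    opts = dict(xatol=spec.xatol, fatol=spec.fatol, maxfev=spec.maxfev,
                adaptive=True)
    best = None
    n_fev = 0
    for r in range(spec.n_restarts):
        y_init = y0 if r == 0 else y0 + rng.normal(0.0, spec.jitter, y0.size)
        res = minimize(objective, y_init, method="Nelder-Mead", options=opts)
        n_fev += res.nfev
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success)
    for _ in range(spec.polish_rounds):
        res = minimize(objective, best.x, method="Nelder-Mead", options=opts)
        n_fev += res.nfev
        improved = res.fun < best.fun - max(1e-16, 1e-10 * abs(best.fun))
        if res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
        if not improved:
            break
    return best, n_fev, converged


def _validate_times(X) -> np.ndarray:
    t = np.asarray(X, dtype=float)
    if t.ndim == 2 and t.shape[1] == 1:
        t = t[:, 0]
    if t.ndim != 1:
        raise ValidationError("X must be a 1-D array of times (or a column)")
    if np.any(~np.isfinite(t)):
        raise ValidationError("times must be finite")
    return t


# ---------------------------------------------------------------------------
# glycemia fitting

class TwoCompartmentGlycemia(RegressorMixin, BaseEstimator):
    """OLS fit of the two-compartment IVGTT glycemia model.

    Five free parameters (k_x1, k_21, G_b, Q_20, V_p); the exchange rate
    k_12 and net input k_g are tied to them by the baseline equilibrium
    relations.  A sample at t = 0 is treated as the pre-bolus baseline and
    compared against G_b rather than the post-bolus curve.

    Parameters
    ----------
    dose : IV glucose bolus D, mmol.
    n_restarts, jitter, seed : multi-start control.

    Attributes (after fit)
    ----------------------
    params_ : GlycemiaParams at the optimum (including derived k_12, k_g).
    curve_ : GlycemiaCurve of the fitted model (post-bolus branch).
    loss_ : sum of squared residuals, mM^2.
    result_ : full FitResult.
    """

    _MIN_SAMPLES = 5

    def __init__(self, dose: float, n_restarts: int = 5, jitter: float = 0.3,
                 seed: int = 0, maxfev: int = 3000, xatol: float = 1e-10,
                 fatol: float = 1e-14, t_end: float | None = None):
        self.dose = dose
        self.n_restarts = n_restarts
        self.jitter = jitter
        self.seed = seed
        self.maxfev = maxfev
        self.xatol = xatol
        self.fatol = fatol
        self.t_end = t_end

    def _spec(self, t, y) -> FitSpec:
        g_b0 = float(y[np.argmin(t)]) if t.min() <= 0 else float(np.min(y))
        g_b0 = min(max(g_b0, 0.5), 40.0)
        v_p0 = min(max(self.dose / max(np.max(y) - g_b0, 1e-3), 1.0), 60.0)
        params = [
            FreeParam("k_x1", 0.03, 1e-8, 10.0),
            FreeParam("k_21", 0.1, 1e-8, 10.0),
            FreeParam("G_b", g_b0, 0.1, 50.0),
            FreeParam("Q_20", g_b0 * v_p0, 0.1, 1e4),
            FreeParam("V_p", v_p0, 0.5, 100.0),
        ]
        return FitSpec(params, n_restarts=self.n_restarts, jitter=self.jitter,
                       maxfev=self.maxfev, xatol=self.xatol, fatol=self.fatol)

    def _predict_values(self, p: GlycemiaParams, t: np.ndarray,
                        t_end: float) -> np.ndarray:
        curve = solve_two_compartment(p, t_end=t_end)
        pred = curve(t)
        pred = np.where(t <= 0, p.G_b, pred)
        return pred

    def fit(self, X, y):
        t = _validate_times(X)
        y = np.asarray(y, dtype=float)
        if y.shape != t.shape:
            raise ValidationError("X and y must have matching length")
        if t.size < self._MIN_SAMPLES:
            raise InsufficientDataError(
                f"glycemia fit needs >= {self._MIN_SAMPLES} samples, got {t.size}")
        t_end = self.t_end if self.t_end is not None else float(t.max())
        spec = self._spec(t, y)
        rng = np.random.default_rng(self.seed)

        def objective(yv):
            if not np.all(np.isfinite(yv)) or np.max(np.abs(yv)) > 40:
                return _PENALTY
            vals = spec.from_opt(yv)
            pen = sum(p.penalty(vals[p.name]) for p in spec.params)
            if pen > 0:
                return _PENALTY * pen
            try:
                p = GlycemiaParams.from_free(D=self.dose, **vals)
                pred = self._predict_values(p, t, t_end)
            except (ValidationError, FloatingPointError):
                return _PENALTY
            if not np.all(np.isfinite(pred)):
                return _PENALTY
            r = y - pred
            return float(r @ r)

        y0 = spec.to_opt({p.name: p.init for p in spec.params})
        best, n_fev, converged = _minimize_multistart(objective, spec, y0, rng)
        vals = spec.from_opt(best.x)
        self.params_ = GlycemiaParams.from_free(D=self.dose, **vals)
        self.curve_ = solve_two_compartment(self.params_, t_end=t_end)
        pred = self._predict_values(self.params_, t, t_end)
        self.loss_ = float(best.fun)
        self.result_ = FitResult(
            model="glycemia", params=self.params_.as_dict(),
            loss=self.loss_, converged=converged, n_fev=n_fev,
            residuals=y - pred, predicted=pred, times=t, seed=self.seed)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        t = _validate_times(X)
        return self._predict_values(self.params_, t, max(self.curve_.t_end,
                                                         float(t.max(initial=0.0))))


# ---------------------------------------------------------------------------
# glucose-loss fitting

class _GlucoseLossRegressor(RegressorMixin, BaseEstimator):
    """Shared machinery for fitting a glucose-loss model to urine samples.

    ``curve`` is the continuous driving glycemia; ``baseline`` the
    pre-bolus glycemia used to initialize tubule and bladder at
    equilibrium (defaults to curve(0), which is already the baseline for
    interpolated curves)."""

    _MODEL = ""

    def __init__(self, curve: GlycemiaCurve, rho: float, u_flow: float,
                 baseline: float | None = None, n_restarts: int = 5,
                 jitter: float = 0.3, seed: int = 0, maxfev: int = 2000,
                 xatol: float = 1e-9, fatol: float = 1e-13):
        self.curve = curve
        self.rho = rho
        self.u_flow = u_flow
        self.baseline = baseline
        self.n_restarts = n_restarts
        self.jitter = jitter
        self.seed = seed
        self.maxfev = maxfev
        self.xatol = xatol
        self.fatol = fatol

    def _free_params(self) -> list[FreeParam]:  # pragma: no cover - abstract
        raise NotImplementedError

    def _predict_values(self, vals: dict, t: np.ndarray,
                        t_end: float) -> np.ndarray:
        raise NotImplementedError

    def _finalize(self, vals: dict):
        raise NotImplementedError

    def fit(self, X, y):
        t = _validate_times(X)
        y = np.asarray(y, dtype=float)
        if y.shape != t.shape:
            raise ValidationError("X and y must have matching length")
        spec = FitSpec(self._free_params(), n_restarts=self.n_restarts,
                       jitter=self.jitter, maxfev=self.maxfev,
                       xatol=self.xatol, fatol=self.fatol)
        if t.size < len(spec.params):
            raise InsufficientDataError(
                f"{self._MODEL} fit needs >= {len(spec.params)} samples, "
                f"got {t.size}")
        t_end = float(t.max())
        rng = np.random.default_rng(self.seed)

        def objective(yv):
            if not np.all(np.isfinite(yv)) or np.max(np.abs(yv)) > 40:
                return _PENALTY
            vals = spec.from_opt(yv)
            pen = sum(p.penalty(vals[p.name]) for p in spec.params)
            if pen > 0:
                return _PENALTY * pen
            try:
                pred = self._predict_values(vals, t, t_end)
            except (ValidationError, ConvergenceError, FloatingPointError):
                return _PENALTY
            if not np.all(np.isfinite(pred)):
                return _PENALTY
            r = y - pred
            return float(r @ r)

        y0 = spec.to_opt({p.name: p.init for p in spec.params})
        best, n_fev, converged = _minimize_multistart(objective, spec, y0, rng)
        vals = spec.from_opt(best.x)
        self._finalize(vals)
        pred = self._predict_values(vals, t, t_end)
        self.loss_ = float(best.fun)
        self.t_end_ = t_end
        self.result_ = FitResult(
            model=self._MODEL, params=dict(vals), loss=self.loss_,
            converged=converged, n_fev=n_fev, residuals=y - pred,
            predicted=pred, times=t, seed=self.seed)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        t = _validate_times(X)
        return self._predict_values(self.result_.params, t,
                                    max(self.t_end_, float(t.max(initial=0.0))))

    @property
    def _baseline_value(self) -> float:
        return float(self.curve(0.0)) if self.baseline is None else self.baseline


class PTRRegressor(_GlucoseLossRegressor):
    """Fit the progressive-tubular-reabsorption model to urinary loss data.

    Free parameters: k_T (apparent threshold, mM), G_half (mM), Hill
    exponent nu (bounded (0, 20]), filtrate velocity phi (cm/min) and
    bladder volume V_B (L).  Geometry (L = 1.5 cm, N = 10, taper 90) and
    the subject's GFR and urine flow are fixed inputs.

    Attributes after fit: ``ptr_params_``, ``bladder_``, ``tmax_``
    (mmol/min), ``tintub_`` (min), ``loss_``, ``result_``.
    """

    _MODEL = "ptr"

    def __init__(self, curve: GlycemiaCurve, rho: float, u_flow: float,
                 baseline: float | None = None, n_restarts: int = 5,
                 jitter: float = 0.3, seed: int = 0, maxfev: int = 2000,
                 xatol: float = 1e-9, fatol: float = 1e-13,
                 dt_frac: float = 0.25, geometry: TubuleGeometry | None = None):
        super().__init__(curve, rho, u_flow, baseline, n_restarts, jitter,
                         seed, maxfev, xatol, fatol)
        self.dt_frac = dt_frac
        self.geometry = geometry

    def _geom(self) -> TubuleGeometry:
        return self.geometry if self.geometry is not None else TubuleGeometry(
            rho=self.rho)

    def _free_params(self):
        return [
            FreeParam("k_T", 10.0, 1e-3, 1e3),
            FreeParam("G_half", 0.8, 1e-4, 1e3),
            FreeParam("nu", 2.0, 1e-6, 20.0, transform="logit"),
            FreeParam("phi", 1.0, 0.02, 6.0),
            FreeParam("V_B", 0.05, 1e-4, 50.0),
        ]

    def _predict_values(self, vals, t, t_end):
        params = PTRParams(k_T=vals["k_T"], G_half=vals["G_half"],
                           nu=vals["nu"], phi=vals["phi"])
        geom = self._geom()
        bladder = BladderParams(V_B=vals["V_B"], U_flow=self.u_flow)
        sim = simulate_ptr(params, geom, bladder, self._driving_curve(),
                           t_end, dt=default_dt(params, geom, self.dt_frac))
        return sim.loss_at(t)

    def _driving_curve(self) -> GlycemiaCurve:
        """Driving curve whose value at 0 is the pre-bolus baseline, so the
        equilibrium initialization is taken at baseline glycemia."""
        if self.baseline is None:
            return self.curve
        return with_baseline(self.curve, self.baseline)

    def _finalize(self, vals):
        self.ptr_params_ = PTRParams(k_T=vals["k_T"], G_half=vals["G_half"],
                                     nu=vals["nu"], phi=vals["phi"])
        self.bladder_ = BladderParams(V_B=vals["V_B"], U_flow=self.u_flow)
        self.tmax_ = self.ptr_params_.tmax(self.rho)
        self.tintub_ = self.ptr_params_.tintub(self._geom())


class RTHRegressor(_GlucoseLossRegressor):
    """Fit the renal-threshold model to urinary loss data.

    Free parameters: threshold T (mM), bladder volume V_B (L) and, when
    ``fix_s`` is False, the slope S bounded in (0, 10].

    Attributes after fit: ``rth_params_``, ``loss_``, ``result_``.
    """

    _MODEL = "rth"

    def __init__(self, curve: GlycemiaCurve, rho: float, u_flow: float,
                 baseline: float | None = None, fix_s: bool = True,
                 n_restarts: int = 5, jitter: float = 0.3, seed: int = 0,
                 maxfev: int = 2000, xatol: float = 1e-9, fatol: float = 1e-13,
                 dt: float = 0.05):
        super().__init__(curve, rho, u_flow, baseline, n_restarts, jitter,
                         seed, maxfev, xatol, fatol)
        self.fix_s = fix_s
        self.dt = dt

    def _free_params(self):
        params = [FreeParam("T", 8.0, 0.01, 100.0)]
        if not self.fix_s:
            params.append(FreeParam("S", 1.0, 1e-6, 10.0, transform="logit"))
        params.append(FreeParam("V_B", 0.05, 1e-4, 50.0))
        return params

    def _rth_params(self, vals) -> RTHParams:
        return RTHParams(T=vals["T"], S=1.0 if self.fix_s else vals["S"],
                         rho=self.rho,
                         bladder=BladderParams(V_B=vals["V_B"],
                                               U_flow=self.u_flow))

    def _predict_values(self, vals, t, t_end):
        params = self._rth_params(vals)
        B0 = rth_influx(self._baseline_value, params) / params.bladder.alpha2
        sim = simulate_rth(params, self.curve, t_end, dt=self.dt, B0=B0)
        return np.interp(t, sim.times, sim.values)

    def _finalize(self, vals):
        self.rth_params_ = self._rth_params(vals)


# ---------------------------------------------------------------------------
# functional wrappers

def fit_glycemia(samples: TimeSeries, D: float, **kwargs) -> FitResult:
    """Fit the two-compartment model to glycemia samples (dose D, mmol)."""
    est = TwoCompartmentGlycemia(dose=D, **kwargs)
    est.fit(samples.times, samples.values)
    return est.result_


def fit_glucose_loss(model: str, urine: TimeSeries, C: GlycemiaCurve,
                     rho: float, u_flow: float, baseline: float | None = None,
                     **kwargs) -> FitResult:
    """Fit a glucose-loss model ("ptr", "rth_fixedS" or "rth_freeS") to
    observed urinary loss driven by the glycemia curve C."""
    if model == "ptr":
        est = PTRRegressor(C, rho, u_flow, baseline=baseline, **kwargs)
    elif model in ("rth_fixedS", "rth"):
        est = RTHRegressor(C, rho, u_flow, baseline=baseline, fix_s=True,
                           **kwargs)
    elif model == "rth_freeS":
        est = RTHRegressor(C, rho, u_flow, baseline=baseline, fix_s=False,
                           **kwargs)
    else:
        raise ValidationError(f"unknown model tag {model!r}")
    est.fit(urine.times, urine.values)
    result = est.result_
    if model == "ptr":
        result.extras.update(tmax=est.tmax_, tintub=est.tintub_)
    return result


def derived_quantities(rth_fixed: dict, rth_free: dict, ptr: dict,
                       subjects) -> dict:
    """Cohort-level transport summaries from per-subject fit tables.

    Arguments mirror the reference-table layout: dicts keyed by glycemia
    mode ("interpolated"/"fitted") of per-subject frames with columns
    ``T``/``loss`` (RTH) and ``tmax``/``loss`` (PTR); ``subjects`` must
    carry ``gfr_l_min``.  Returns per-mode mean/SD of the RTH maximal
    transport T*rho and the PTR T^max, in mmol/min and mg/min, plus the
    PTR/RTH(free-S) mean-loss ratio.
    """
    gfr = subjects["gfr_l_min"]
    out = {}
    for mode in ("interpolated", "fitted"):
        transport = rth_fixed[mode]["T"] * gfr
        transport_free = rth_free[mode]["T"] * gfr
        tmax = ptr[mode]["tmax"]
        out[mode] = {
            "per_subject_rth_transport_mmol_min": transport.to_dict(),
            "per_subject_rth_transport_mg_min":
                (transport * GLUCOSE_MOLAR_MASS).to_dict(),
            "per_subject_ptr_tmax_mmol_min": tmax.to_dict(),
            "per_subject_ptr_tmax_mg_min":
                (tmax * GLUCOSE_MOLAR_MASS).to_dict(),
            "rth_fixedS_transport_mmol_min": float(transport.mean()),
            "rth_fixedS_transport_sd": float(transport.std(ddof=1)),
            "rth_fixedS_transport_mg_min":
                float(transport.mean() * GLUCOSE_MOLAR_MASS),
            "rth_freeS_transport_mmol_min": float(transport_free.mean()),
            "ptr_tmax_mmol_min": float(tmax.mean()),
            "ptr_tmax_sd": float(tmax.std(ddof=1)),
            "ptr_tmax_mg_min": float(tmax.mean() * GLUCOSE_MOLAR_MASS),
            "loss_ratio_ptr_over_rth_freeS":
                float(ptr[mode]["loss"].mean() / rth_free[mode]["loss"].mean()),
        }
    return out
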