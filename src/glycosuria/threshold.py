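"""Renal Threshold Hypothesis (RTH) model of urinary glucose loss.

The classical description: below a threshold glycemia T every filtered
glucose molecule is reabsorbed, above it the excess spills into urine at
rate S * rho * (C - T), with slope S = 1 under the strict hypothesis
(all supra-threshold glucose excreted).  To make it directly comparable
with the progressive-reabsorption model, the same first-order bladder
delay compartment is appended:

    dB/dt = S rho (C(t) - T)+  -  alpha2 B,      loss(t) = alpha2 B(t)

Its structural failure modes — zero predicted loss below threshold, and
loss tracking glycemia with no tubular transit delay — are what the
tubule model is measured against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .exceptions import ValidationError
from .glycemia import GlycemiaCurve, TimeSeries
from .tubule import BladderParams


@dataclass(frozen=True)
class RTHParams:
    """Threshold T (mM), slope S (dimensionless, 1 under the strict
    hypothesis, estimation bound (0, 10]), GFR rho (L/min), and the
    bladder delay compartment."""

    T: float
    S: float
    rho: float
    bladder: BladderParams

    def __post_init__(self):
        if not (np.isfinite(self.T) and self.T >= 0):
            raise ValidationError("T must be finite and >= 0")
        if not (0 <= self.S <= 10):
            raise ValidationError("S must lie in [0, 10]")
        if not (np.isfinite(self.rho) and self.rho > 0):
            raise ValidationError("rho must be finite and > 0")

    def as_dict(self) -> dict:
        return {"T": self.T, "S": self.S, "rho": self.rho,
                "V_B": self.bladder.V_B, "U_flow": self.bladder.U_flow}


def rth_influx(C_t, params: RTHParams):
    """Glucose spill rate into the bladder: S * rho * max(C - T, 0), mmol/min."""
    C_t = np.asarray(C_t, dtype=float)
    if np.any(C_t < 0):
        raise ValidationError("plasma glucose concentration must be >= 0")
    rate = params.S * params.rho * np.maximum(C_t - params.T, 0.0)
    return float(rate) if rate.ndim == 0 else rate


def simulate_rth(
    params: RTHParams,
    C: GlycemiaCurve,
    t_end: float,
    dt: float = 0.05,
    B0: float | None = None,
) -> TimeSeries:
    """Urinary loss rate alpha2*B(t) on a uniform grid of step dt.

    The bladder starts at baseline equilibrium B(0) = influx(C(0))/alpha2
    (zero when baseline glycemia is below threshold) unless ``B0`` is
    given.  Each step applies the exact exponential solution of the
    linear bladder ODE with the influx held at its left-endpoint value,
    so constant-glycemia runs are exact to rounding.
    """
    if t_end <= 0:
        raise ValidationError("t_end must be > 0")
    if t_end > C.t_end + 1e-9:
        raise ValidationError(
            f"glycemia curve defined on [0, {C.t_end}], requested t_end={t_end}")
    a2 = params.bladder.alpha2
    n_steps = max(1, int(np.ceil(t_end / dt - 1e-9)))
    dt = t_end / n_steps
    t_grid = np.arange(n_steps + 1) * dt
    u = rth_influx(C(t_grid[:-1]), params)
    if B0 is None:
        B0 = rth_influx(float(C(0.0)), params) / a2
    q = np.exp(-a2 * dt)
    p = (1.0 - q) / a2
    # linear recurrence B[k+1] = q B[k] + p u[k], vectorized as an IIR filter
    B = np.empty(n_steps + 1)
    B[0] = B0
    B[1:] = lfilter([p], [1.0, -q], u, zi=[q * B0])[0]
    return TimeSeries(times=t_grid, values=np.maximum(a2 * B, 0.0),
                      kind="urine_loss")
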