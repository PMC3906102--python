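"""Cohort summaries and phase-space (hysteresis) exports.

Cohort tables report, per parameter, the mean, sample standard deviation
and a CV% figure.  The CV% convention used throughout is the
standard-error based 100*SD/(mean*sqrt(n)) — the convention recovered by
matching the published summary rows exactly; note this differs from the
textbook 100*SD/mean.

Phase-space exports pair urinary glucose loss with the concurrent
glycemia.  A tubular transit delay makes the trajectory sweep a
counter-clockwise loop (glycemia rises before glycosuria reacts); the
signed enclosed area (shoelace formula, positive = counter-clockwise) is
reported as a scalar hysteresis statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, ValidationError
from .glycemia import GlycemiaCurve, TimeSeries


@dataclass(frozen=True)
class CohortSummary:
    """Mean, sample SD (n-1 denominator) and CV% = 100*SD/(mean*sqrt(n))."""

    mean: float
    sd: float
    cv_pct: float
    n: int


def summarize_cohort(values) -> CohortSummary:
    """Summary row for one parameter across the cohort (needs n >= 2)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise InsufficientDataError("cohort summary needs >= 2 values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    cv = 100.0 * sd / (mean * np.sqrt(v.size)) if mean != 0 else np.inf
    return CohortSummary(mean=mean, sd=sd, cv_pct=cv, n=v.size)


def cohort_table(df: pd.DataFrame) -> pd.DataFrame:
    """Append mean / SD / CV% rows to a per-subject parameter table."""
    out = df.copy()
    summaries = {c: summarize_cohort(df[c].to_numpy()) for c in df.columns}
    out.loc["mean"] = {c: s.mean for c, s in summaries.items()}
    out.loc["SD"] = {c: s.sd for c, s in summaries.items()}
    out.loc["CV%"] = {c: s.cv_pct for c, s in summaries.items()}
    return out


def shoelace_area(x, y) -> float:
    """Signed area of the closed polygon through (x_i, y_i), in traversal
    order; positive for counter-clockwise loops."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D of equal length")
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def phase_space_export(glycemia, urine: TimeSeries) -> tuple[pd.DataFrame, float]:
    """Pair urinary loss with concurrent glycemia for phase-plane plots.

    ``glycemia`` is a GlycemiaCurve or a glycemia TimeSeries (interpolated
    linearly at the urine sample times).  Returns the ordered
    (time, C, loss) table and the signed loop area.
    """
    t = urine.times
    if isinstance(glycemia, GlycemiaCurve):
        if t.size and t[-1] > glycemia.t_end + 1e-9:
            raise ValidationError("urine times extend past the glycemia domain")
        c = glycemia(t)
    elif isinstance(glycemia, TimeSeries):
        if t.size and (t[0] < glycemia.times[0] - 1e-9
                       or t[-1] > glycemia.times[-1] + 1e-9):
            raise ValidationError("urine times extend past the glycemia samples")
        c = np.interp(t, glycemia.times, glycemia.values)
    else:
        raise ValidationError("glycemia must be a GlycemiaCurve or TimeSeries")
    table = pd.DataFrame({
        "time_min": t,
        "glycemia_mM": c,
        "urine_loss_mmol_min": urine.values,
    })
    return table, shoelace_area(c, urine.values)
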