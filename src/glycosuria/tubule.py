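"""Progressive Tubular Reabsorption (PTR) model of urinary glucose loss.

An idealized aggregate tubule (the glucose-reabsorbing proximal segments
of all nephrons pooled into one) receives ultrafiltrate at the glomerular
filtration rate rho.  Glucose advects along the tubule at constant
velocity phi while a saturable Hill-type transporter removes it; water
reabsorption shrinks the cross-section exponentially (from the ~180 L/day
of ultrafiltrate down to the ~2 L/day of urine), concentrating the
remaining glucose and driving more distal reabsorption.  Whatever reaches
the end of the tubule enters a first-order "bladder" delay compartment
(collecting duct + pelvis + ureter + bladder + catheter) whose outflow is
the measured urinary glucose loss rate.

The advection PDE is discretized as a chain of N serial segments, each
washed out in time W_T = (L/phi)/N, updated explicitly with step fraction
alpha = dt/W_T <= 1 (advect, then reabsorb, reabsorption clipped at the
available mass).  Axial diffusion is neglected.  Per-segment maximal
transport is T^max/N with T^max = k_T * rho, k_T being the apparent
"glucose concentration threshold" equivalent of the transport maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .exceptions import ConvergenceError, StabilityError, ValidationError
from .glycemia import GlycemiaCurve


def tmax_from_kt(k_T: float, rho: float) -> float:
    """Whole-tubule maximal reabsorption rate T^max = k_T * rho (mmol/min)."""
    if k_T < 0 or rho < 0:
        raise ValidationError("k_T and rho must be >= 0")
    return k_T * rho


def kt_from_tmax(tmax: float, rho: float) -> float:
    """Apparent concentration threshold k_T = T^max / rho (mM)."""
    if rho <= 0:
        raise ValidationError("rho must be > 0 to invert T^max = k_T*rho")
    if tmax < 0:
        raise ValidationError("T^max must be >= 0")
    return tmax / rho


@dataclass(frozen=True)
class TubuleGeometry:
    """Aggregate-tubule geometry and filtration.

    L: reabsorptive length, cm (half of a standard 3 cm human nephron).
    N: discretization segments.
    taper_ratio: inlet/outlet flow ratio (180 L/day filtrate vs 2 L/day
    urine); the cross-section decays exponentially to match.
    rho: glomerular filtration rate, L/min.
    """

    rho: float
    L: float = 1.5
    N: int = 10
    taper_ratio: float = 90.0

    def __post_init__(self):
        if not (np.isfinite(self.rho) and self.rho > 0):
            raise ValidationError("rho must be finite and > 0")
        if self.L <= 0:
            raise ValidationError("L must be > 0")
        if int(self.N) != self.N or self.N < 1:
            raise ValidationError("N must be an integer >= 1")
        if self.taper_ratio < 1:
            raise ValidationError("taper_ratio must be >= 1")

    @property
    def lam(self) -> float:
        """Exponential taper rate, 1/cm."""
        return np.log(self.taper_ratio) / self.L


@dataclass(frozen=True)
class PTRParams:
    """Transport parameters of the PTR model.

    k_T: apparent concentration threshold, mM (T^max = k_T * rho).
    G_half: concentration at half-maximal reabsorption, mM.
    nu: Hill steepness exponent.
    phi: filtrate velocity, cm/min.
    """

    k_T: float
    G_half: float
    nu: float
    phi: float

    def __post_init__(self):
        for name in ("G_half", "nu", "phi"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be finite and > 0, got {v}")
        if not (np.isfinite(self.k_T) and self.k_T >= 0):
            # k_T = 0 is the no-reabsorption limit, useful as a control
            raise ValidationError(f"k_T must be finite and >= 0, got {self.k_T}")

    def tmax(self, rho: float) -> float:
        return tmax_from_kt(self.k_T, rho)

    def w_t(self, geom: TubuleGeometry) -> float:
        """Single-segment wash-out time, min."""
        return (geom.L / self.phi) / geom.N

    def tintub(self, geom: TubuleGeometry) -> float:
        """Total filtrate transit time through the tubule, min (= N*W_T)."""
        return geom.L / self.phi

    def as_dict(self) -> dict:
        return {"k_T": self.k_T, "G_half": self.G_half,
                "nu": self.nu, "phi": self.phi}


@dataclass(frozen=True)
class BladderParams:
    """Delay-compartment volume (L) and urine flow (L/min)."""

    V_B: float
    U_flow: float

    def __post_init__(self):
        if not (np.isfinite(self.V_B) and self.V_B > 0):
            raise ValidationError("V_B must be finite and > 0")
        if not (np.isfinite(self.U_flow) and self.U_flow > 0):
            raise ValidationError("U_flow must be finite and > 0")

    @property
    def alpha2(self) -> float:
        """Bladder-to-urine transfer rate, 1/min."""
        return self.U_flow / self.V_B


@dataclass(frozen=True)
class TaperProfile:
    """Segment fluid volumes/flows from the exponential cross-section taper."""

    volumes: np.ndarray      # L, at segment midpoints
    flows: np.ndarray        # L/min, at segment midpoints
    inlet_flow: float        # rho, L/min (z = 0)
    outlet_flow: float       # rho / taper_ratio, L/min (z = L)
    z_mid: np.ndarray        # cm


def taper_profile(geom: TubuleGeometry, phi: float) -> TaperProfile:
    """Per-segment volumes V_i = F(z_i) * W_T at midpoints z_i.

    Constant velocity means flow is proportional to cross-section, so
    F(z) = rho * exp(-lam z) with F(0) = rho and F(L) = rho/taper_ratio.
    """
    if phi <= 0:
        raise ValidationError("phi must be > 0")
    w_t = (geom.L / phi) / geom.N
    z_mid = (np.arange(geom.N) + 0.5) * geom.L / geom.N
    flows = geom.rho * np.exp(-geom.lam * z_mid)
    return TaperProfile(
        volumes=flows * w_t,
        flows=flows,
        inlet_flow=geom.rho,
        outlet_flow=geom.rho / geom.taper_ratio,
        z_mid=z_mid,
    )


@dataclass
class TubuleState:
    """Per-segment glucose masses (mmol) and fluid volumes (L)."""

    masses: np.ndarray
    volumes: np.ndarray

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.masses.shape != self.volumes.shape:
            raise ValidationError("masses and volumes must have the same shape")
        if np.any(self.masses < 0):
            raise ValidationError("segment masses must be >= 0")
        if np.any(self.volumes <= 0):
            raise ValidationError("segment volumes must be > 0")

    @property
    def concentrations(self) -> np.ndarray:
        """Per-segment glucose concentrations, mM."""
        return self.masses / self.volumes


def default_dt(params: PTRParams, geom: TubuleGeometry, frac: float = 0.25) -> float:
    """Default step: a quarter of the segment wash-out time (alpha = 0.25)."""
    return params.w_t(geom) * frac


def step_tubule(
    state: TubuleState,
    params: PTRParams,
    geom: TubuleGeometry,
    C_t: float,
    dt: float,
) -> tuple[TubuleState, dict]:
    """Advance the tubule one explicit step under plasma glucose C_t.

    Sub-steps: advection (mass fraction alpha = dt/W_T moves one segment
    downstream, rho*C_t*dt enters segment 1, the last segment sheds at
    rate m_N/W_T into the bladder), then per-segment saturable removal
    (T^max/N) * c^nu/(G_half^nu + c^nu) * dt clipped at the available
    mass.  Returns the new state and a bookkeeping dict (inflow, outflow
    and reabsorbed masses over the step).
    """
    w_t = params.w_t(geom)
    alpha = dt / w_t
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    if alpha > 1 + 1e-12:
        raise StabilityError(
            f"dt/W_T = {alpha:.4g} > 1: explicit advection is unstable")
    m = state.masses.copy()
    out_mass, reab = _kernels.step(
        m, state.volumes, alpha, dt, params.tmax(geom.rho) / geom.N,
        params.G_half, params.nu, geom.rho * C_t * dt)
    new_state = TubuleState(masses=m, volumes=state.volumes)
    return new_state, {
        "inflow_mass": geom.rho * C_t * dt,
        "outflow_mass": out_mass,
        "reabsorbed_mass": reab,
    }


def tubule_steady_state(
    params: PTRParams,
    geom: TubuleGeometry,
    G_b: float,
    dt: float | None = None,
    tol: float = 1e-10,
    max_steps: int = 2_000_000,
    window_tol: float = 1e-6,
) -> tuple[TubuleState, float, dict]:
    """Tubule fixed point under constant baseline glycemia G_b.

    Ultrafiltrate at concentration G_b passes along the (initially empty)
    tubule until the end-segment outflow no longer varies between steps
    (relative change < tol, scaled by alpha = dt/W_T so the criterion is a
    drift bound per transit rather than per step).  Very steep Hill
    exponents can leave the map
    on a small limit cycle around the fixed point; such runs are accepted
    when the transit-averaged outflow stabilizes to ``window_tol`` and
    the cycle-mean rates are reported.  Returns (state, steady outflow
    rate mmol/min, diagnostics).
    """
    if G_b < 0:
        raise ValidationError("G_b must be >= 0")
    if dt is None:
        dt = default_dt(params, geom)
    w_t = params.w_t(geom)
    alpha = dt / w_t
    if alpha > 1 + 1e-12:
        raise StabilityError(f"dt/W_T = {alpha:.4g} > 1")
    prof = taper_profile(geom, params.phi)
    # warm-up spanning several transit times so the relative check is not
    # fooled by the slow early fill
    min_steps = int(10 * geom.N / alpha)
    m, out_rate, reab_rate, n_iter, converged = _kernels.steady_state(
        prof.volumes, alpha, dt, params.tmax(geom.rho) / geom.N,
        params.G_half, params.nu, geom.rho * G_b * dt,
        tol, max_steps, min_steps, window_tol)
    diagnostics = {
        "iterations": int(n_iter),
        "outflow_rate": float(out_rate),
        "reabsorption_rate": float(reab_rate),
        "dt": dt,
    }
    if not converged:
        raise ConvergenceError(
            f"tubule steady state did not converge in {max_steps} steps",
            diagnostics)
    return TubuleState(masses=m, volumes=prof.volumes), float(out_rate), diagnostics


@dataclass
class PTRSimResult:
    """Simulated PTR output on the integration grid.

    ``loss`` is the urinary glucose loss rate alpha2*B(t) (mmol/min);
    ``outflow`` the tubule-to-bladder rate; ``bladder`` the bladder
    glucose content B(t) (mmol); ``reabsorbed_cum`` cumulative reabsorbed
    mass.  ``mass_residual`` is the relative global balance error
    |inflow - (reabsorbed + d(tubule) + d(bladder) + loss)| / inflow.
    """

    times: np.ndarray
    loss: np.ndarray
    outflow: np.ndarray
    bladder: np.ndarray
    reabsorbed_cum: np.ndarray
    mass_residual: float
    steady_state_iterations: int
    final_state: TubuleState

    def loss_at(self, t) -> np.ndarray:
        """Loss rate linearly interpolated at requested times."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.loss)


def simulate_ptr(
    params: PTRParams,
    geom: TubuleGeometry,
    bladder: BladderParams,
    C: GlycemiaCurve,
    t_end: float,
    dt: float | None = None,
) -> PTRSimResult:
    """Run the PTR model driven by a continuous glycemia curve.

    The tubule starts at its steady state under C(0) and the bladder at
    equilibrium B(0) = outflow_ss/alpha2; each bladder substep uses the
    exact one-step exponential solution with the step's constant tubule
    outflow.
    """
    if t_end <= 0:
        raise ValidationError("t_end must be > 0")
    if t_end > C.t_end + 1e-9:
        raise ValidationError(
            f"glycemia curve defined on [0, {C.t_end}], requested t_end={t_end}")
    if dt is None:
        dt = default_dt(params, geom)
    w_t = params.w_t(geom)
    if dt / w_t > 1 + 1e-12:
        raise StabilityError(f"dt/W_T = {dt / w_t:.4g} > 1")
    n_steps = max(1, int(np.ceil(t_end / dt - 1e-9)))
    dt = t_end / n_steps  # align the grid with t_end, never increasing alpha
    alpha = dt / w_t

    state0, out_ss, ss_diag = tubule_steady_state(
        params, geom, float(C(0.0)), dt=dt)
    B0 = out_ss / bladder.alpha2

    t_grid = np.arange(n_steps + 1) * dt
    C_grid = C(t_grid[:-1])
    m = state0.masses.copy()
    (loss_rate, outflow_rate, bladder_content, reab_cum,
     inflow_total, reab_total, loss_total) = _kernels.run(
        m, state0.volumes, alpha, dt, params.tmax(geom.rho) / geom.N,
        params.G_half, params.nu, bladder.alpha2, B0, C_grid, geom.rho)

    d_tubule = m.sum() - state0.masses.sum()
    d_bladder = bladder_content[-1] - B0
    residual = inflow_total - (reab_total + d_tubule + d_bladder + loss_total)
    rel_residual = abs(residual) / max(inflow_total, 1e-300)

    return PTRSimResult(
        times=t_grid,
        loss=loss_rate,
        outflow=outflow_rate,
        bladder=bladder_content,
        reabsorbed_cum=reab_cum,
        mass_residual=float(rel_residual),
        steady_state_iterations=ss_diag["iterations"],
        final_state=TubuleState(masses=m, volumes=state0.volumes),
    )
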