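"""Numba inner loops for the discretized tubule.

The tubule update is inherently sequential in time (thousands of small
steps per simulation, thousands of simulations per fit), so the hot loop
is compiled.  All physics lives here in one place: the Python-level
``step_tubule`` wraps ``step`` for a single step and ``simulate_ptr``
drives ``run``.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def step(m, vols, alpha, dt, tmax_per_seg, g_half, nu, inflow_mass):
    """One explicit step: advect, then saturable reabsorption.

    ``m`` is modified in place.  Returns (outflow mass to bladder,
    reabsorbed mass) over the step.
    """
    n = m.shape[0]
    out_mass = m[n - 1] * alpha
    for i in range(n - 1, 0, -1):
        m[i] = m[i] * (1.0 - alpha) + m[i - 1] * alpha
    m[0] = m[0] * (1.0 - alpha) + inflow_mass
    reab = 0.0
    cap = tmax_per_seg * dt
    for i in range(n):
        if m[i] <= 0.0:
            continue
        c = m[i] / vols[i]
        # Hill term written as 1/(1 + (g_half/c)^nu): overflow of the ratio
        # cleanly yields r -> 0, underflow yields r -> cap.
        r = cap / (1.0 + (g_half / c) ** nu)
        if r > m[i]:
            r = m[i]
        m[i] -= r
        reab += r
        if m[i] < 1e-60:  # flush sub-physical residue; avoids denormal crawl
            reab += m[i]
            m[i] = 0.0
    return out_mass, reab


@njit(cache=True)
def steady_state(vols, alpha, dt, tmax_per_seg, g_half, nu, inflow_mass,
                 tol, max_steps, min_steps, window_tol):
    """Fixed point of the step operator under constant inflow.

    Converged when successive end-segment outflow rates agree to relative
    ``tol`` (after ``min_steps`` warm-up steps covering several transit
    times).  A steep Hill term (nearly binary at c = G_half) can trap the
    discrete map in a small limit cycle around the fixed point; those runs
    are accepted once the outflow averaged over a full transit time is
    stable to relative ``window_tol``, and the cycle-mean rates are
    returned.  Returns (masses, outflow rate, reabsorption rate, steps,
    converged flag).
    """
    n = vols.shape[0]
    m = np.zeros(n)
    prev = -1.0
    out_rate = 0.0
    reab_rate = 0.0
    k = 0
    window = int(round(n / alpha))  # steps per tubule transit
    if window < 1:
        window = 1
    win_out = 0.0
    win_reab = 0.0
    prev_mean = -1.0
    prev_reab_mean = 0.0
    for k in range(max_steps):
        out_mass, reab = step(m, vols, alpha, dt, tmax_per_seg, g_half, nu,
                              inflow_mass)
        out_rate = out_mass / dt
        reab_rate = reab / dt
        if k >= min_steps:
            scale = out_rate if out_rate > 1e-300 else 1e-300
            # per-step change shrinks with dt, so normalize by alpha to
            # keep the criterion a drift-per-transit bound
            if abs(out_rate - prev) <= tol * scale * alpha:
                return m, out_rate, reab_rate, k + 1, True
        prev = out_rate
        win_out += out_rate
        win_reab += reab_rate
        if (k + 1) % window == 0:
            mean_out = win_out / window
            mean_reab = win_reab / window
            if k >= min_steps and prev_mean >= 0.0:
                scale = mean_out if mean_out > 1e-300 else 1e-300
                if abs(mean_out - prev_mean) <= window_tol * scale:
                    return m, mean_out, mean_reab, k + 1, True
            prev_mean = mean_out
            prev_reab_mean = mean_reab
            win_out = 0.0
            win_reab = 0.0
    return m, out_rate, reab_rate, k + 1, False


@njit(cache=True)
def run(m, vols, alpha, dt, tmax_per_seg, g_half, nu, alpha2, B0, C_grid, rho):
    """Full simulation from a prepared initial state.

    ``C_grid[k]`` is plasma glucose at the left endpoint of step k (the
    inflow over the step is rho*C*dt).  The bladder substep is the exact
    solution of dB/dt = u - alpha2*B with the step's constant tubule
    outflow rate u.  Returns time series sampled at the n_steps+1 grid
    points plus exact mass bookkeeping totals.
    """
    n_steps = C_grid.shape[0]
    W_T = dt / alpha
    decay = np.exp(-alpha2 * dt)
    loss_rate = np.empty(n_steps + 1)
    outflow_rate = np.empty(n_steps + 1)
    bladder = np.empty(n_steps + 1)
    reab_cum = np.empty(n_steps + 1)
    B = B0
    loss_rate[0] = alpha2 * B
    outflow_rate[0] = m[m.shape[0] - 1] / W_T
    bladder[0] = B
    reab_cum[0] = 0.0
    inflow_total = 0.0
    reab_total = 0.0
    loss_total = 0.0
    for k in range(n_steps):
        inflow_mass = rho * C_grid[k] * dt
        out_mass, reab = step(m, vols, alpha, dt, tmax_per_seg, g_half, nu,
                              inflow_mass)
        u = out_mass / dt
        B_new = B * decay + (u / alpha2) * (1.0 - decay)
        if B_new < 1e-60:  # flush sub-physical residue
            loss_total += out_mass - (B_new - B) + B_new
            B = 0.0
        else:
            loss_total += out_mass - (B_new - B)  # integral of alpha2*B
            B = B_new
        inflow_total += inflow_mass
        reab_total += reab
        loss_rate[k + 1] = alpha2 * B
        outflow_rate[k + 1] = m[m.shape[0] - 1] / W_T
        bladder[k + 1] = B
        reab_cum[k + 1] = reab_total
    return (loss_rate, outflow_rate, bladder, reab_cum,
            inflow_total, reab_total, loss_total)
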