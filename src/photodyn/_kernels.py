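"""Compiled inner loops for the two-state integration.

The stomatal conductance equation is linear with piecewise-constant
coefficients under zero-order-hold inputs, so it is advanced with its
exact exponential solution.  The intercellular CO₂ balance is stiff
(effective relaxation rate ~50 s⁻¹ against a 2 s sampling grid) and is
advanced with backward-Euler substeps solved by a safeguarded Newton
iteration; backward Euler is L-stable, so large substeps damp onto the
quasi-equilibrium branch that the exact solution also tracks.

Everything here is private; the public surface lives in simulate.py.
"""

import math

import numpy as np
from numba import njit

CI_FLOOR = 1e-6


@njit(cache=True)
def _gross_assim(x, Vcmax, keff, gs, J):
    """Gross FvCB sink S(x) = min(Wc, Wj) * (1 - gs/x) and its derivative."""
    wc = Vcmax * x / (x + keff)
    wj = J / (4.0 + 8.0 * gs / x)
    if wc <= wj:
        s = Vcmax * (x - gs) / (x + keff)
        ds = Vcmax * (keff + gs) / ((x + keff) * (x + keff))
    else:
        den = 4.0 * x + 8.0 * gs
        s = J * (x - gs) / den
        ds = J * 12.0 * gs / (den * den)
    return s, ds


@njit(cache=True)
def _balance(x, g, ca, Rd, Vcmax, keff, gs, J):
    """Mass-balance bracket H(x) = g(ca − x) + Rd − S(x) and derivative."""
    s, ds = _gross_assim(x, Vcmax, keff, gs, J)
    return g * (ca - x) + Rd - s, -g - ds


@njit(cache=True)
def _solve_ci_balance(x0, g, ca, Rd, Vcmax, keff, gs, J):
    """Root of H(x) = 0 (H strictly decreasing) by safeguarded Newton."""
    lo = CI_FLOOR
    hi = ca + (Rd + 5.0) / g + 10.0 * gs
    x = min(max(x0, lo), hi)
    for _ in range(100):
        h, dh = _balance(x, g, ca, Rd, Vcmax, keff, gs, J)
        if h > 0.0:
            lo = x
        else:
            hi = x
        step = -h / dh
        x_new = x + step
        if x_new <= lo or x_new >= hi:
            x_new = 0.5 * (lo + hi)
        if abs(x_new - x) < 1e-12 * max(1.0, x):
            return x_new
        x = x_new
    return x


@njit(cache=True)
def _backward_euler_ci(c_prev, h, pf, g, ca, Rd, Vcmax, keff, gs, J):
    """One backward-Euler substep of the ci balance, safeguarded Newton.

    Solves x − c_prev − h·pf·H(x) = 0 where H is the balance bracket;
    F is strictly increasing (F' = 1 + h·pf·(g + S') ≥ 1).
    """
    lo = CI_FLOOR
    hi = max(c_prev, ca) + (Rd + 5.0) / g + 10.0 * gs
    x = min(max(c_prev, lo), hi)
    for _ in range(100):
        hval, dh = _balance(x, g, ca, Rd, Vcmax, keff, gs, J)
        f = x - c_prev - h * pf * hval
        df = 1.0 - h * pf * dh
        if f < 0.0:
            lo = x
        else:
            hi = x
        x_new = x - f / df
        if x_new <= lo or x_new >= hi:
            x_new = 0.5 * (lo + hi)
        if abs(x_new - x) < 1e-12 * max(1.0, x):
            return x_new
        x = x_new
    return x


@njit(cache=True)
def integrate_fast(t, G, ca, keff, gs, J, pf, ku, kd, Vcmax, Rd,
                   g0, c0, n_sub, linear):
    """Advance (gtc, ci) over the sampling grid.

    Inputs are per-sample arrays of the precomputed drivers: stomatal
    target G, ambient ca, effective Michaelis constant keff =
    Kc(1 + Oi/Ko), compensation point gs = Γ*, electron transport J,
    and mass-balance prefactor pf = R·Tl/(d·Pa).  ``linear`` selects
    linear interpolation of drivers inside each interval instead of
    zero-order hold.
    """
    n = t.shape[0]
    gtc = np.empty(n)
    ci = np.empty(n)
    g = g0
    c = max(c0, CI_FLOOR)
    gtc[0] = g
    ci[0] = c
    for i in range(n - 1):
        dt = t[i + 1] - t[i]
        h = dt / n_sub
        for s in range(n_sub):
            if linear:
                frac = (s + 0.5) / n_sub
                Gi = G[i] + (G[i + 1] - G[i]) * frac
                cai = ca[i] + (ca[i + 1] - ca[i]) * frac
                keffi = keff[i] + (keff[i + 1] - keff[i]) * frac
                gsi = gs[i] + (gs[i + 1] - gs[i]) * frac
                Ji = J[i] + (J[i + 1] - J[i]) * frac
                pfi = pf[i] + (pf[i + 1] - pf[i]) * frac
            else:
                Gi = G[i]
                cai = ca[i]
                keffi = keff[i]
                gsi = gs[i]
                Ji = J[i]
                pfi = pf[i]
            k = ku if Gi >= g else kd
            g = Gi + (g - Gi) * math.exp(-h / k)
            c = _backward_euler_ci(c, h, pfi, g, cai, Rd, Vcmax, keffi, gsi, Ji)
            if c < CI_FLOOR:
                c = CI_FLOOR
        gtc[i + 1] = g
        ci[i + 1] = c
    return gtc, ci


@njit(cache=True)
def integrate_qss(t, G, ca, keff, gs, J, ku, kd, Vcmax, Rd, g0, c0):
    """Quasi-steady-state mode: exact gtc relaxation, algebraic ci.

    The fast ci balance is solved to equilibrium at every output step
    instead of being integrated; used as a cross-check of the stiff
    integration.
    """
    n = t.shape[0]
    gtc = np.empty(n)
    ci = np.empty(n)
    g = g0
    c = max(c0, CI_FLOOR)
    gtc[0] = g
    ci[0] = c
    for i in range(n - 1):
        dt = t[i + 1] - t[i]
        Gi = G[i]
        k = ku if Gi >= g else kd
        g = Gi + (g - Gi) * math.exp(-dt / k)
        c = _solve_ci_balance(c, g, ca[i], Rd, Vcmax, keff[i], gs[i], J[i])
        gtc[i + 1] = g
        ci[i + 1] = c
    return gtc, ci
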