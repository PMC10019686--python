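"""Core equations of the dynamic leaf photosynthesis model.

Steady-state photosynthesis follows the Farquhar–von Caemmerer–Berry
(FvCB) scheme without the triose-phosphate limitation: the gross
carboxylation rate is the minimum of a Rubisco-limited rate Wc and an
electron-transport-limited rate Wj, and net assimilation is

    An = min(Wc, Wj) * (1 - Γ*/ci) - Rd .

Mesophyll conductance is taken as infinite, so the chloroplast CO₂
mole fraction equals the intercellular one (cc = ci) throughout.

The dynamics couple two states: total stomatal conductance to CO₂
diffusion g_tc relaxes exponentially toward a light/CO₂-dependent
target G with an asymmetric pair of time constants (ku when opening,
kd when closing), and the intercellular CO₂ mole fraction ci obeys a
mass balance between Fick influx g_tc(ca − ci), respiration, and the
FvCB sink.

All functions accept scalars or numpy arrays (broadcasting) and raise
on out-of-domain inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters

WC_LIMITED = "Wc"
WJ_LIMITED = "Wj"


@dataclass(frozen=True)
class EnvironmentSample:
    """One record of the environmental drivers.

    t in s, irradiance I in µmol m⁻² s⁻¹, leaf temperature Tl in K,
    ambient CO₂ mole fraction ca in µmol mol⁻¹.
    """

    t: float
    I: float
    Tl: float
    ca: float

    def __post_init__(self) -> None:
        if self.I < 0:
            raise ValueError("irradiance must be nonnegative")
        if not (263.0 <= self.Tl <= 323.0):
            raise ValueError(f"leaf temperature {self.Tl} K outside [263, 323] K")
        if self.ca <= 0:
            raise ValueError("ca must be positive")


@dataclass(frozen=True)
class LeafState:
    """Dynamic state: conductance gtc (mol m⁻² s⁻¹) and ci (µmol mol⁻¹)."""

    gtc: float
    ci: float

    def __post_init__(self) -> None:
        if self.gtc <= 0:
            raise ValueError("gtc must be positive")
        if self.ci <= 0:
            raise ValueError("ci must be positive")


def temperature_response(Tl, c, dHa, R1=0.008314):
    """Arrhenius-type temperature scaling exp(c − dHa / (R1·Tl)).

    Used for Γ* (µmol mol⁻¹), Ko (kPa) and Kc (µmol mol⁻¹); strictly
    increasing in leaf temperature for positive activation energy dHa
    (kJ mol⁻¹, with R1 in kJ mol⁻¹ K⁻¹).
    """
    Tl = np.asarray(Tl, dtype=float)
    if np.any(Tl <= 0):
        raise ValueError("leaf temperature must be positive (K)")
    out = np.exp(c - dHa / (R1 * Tl))
    return out.item() if out.ndim == 0 else out


def gamma_star(Tl, params: ModelParameters):
    """CO₂ compensation point Γ* (µmol mol⁻¹) at leaf temperature Tl."""
    return temperature_response(Tl, params.c1, params.dHa1, params.R1)


def ko(Tl, params: ModelParameters):
    """Michaelis constant of Rubisco for O₂, Ko (kPa)."""
    return temperature_response(Tl, params.c2, params.dHa2, params.R1)


def kc(Tl, params: ModelParameters):
    """Michaelis constant of Rubisco for CO₂, Kc (µmol mol⁻¹)."""
    return temperature_response(Tl, params.c3, params.dHa3, params.R1)


def electron_transport(I, Jmax, theta, gamma):
    """Potential electron transport rate J(I), µmol m⁻² s⁻¹.

    Non-rectangular hyperbola: the smaller root of
    γJ² − (Jmax + θI)J + JmaxθI = 0, i.e.

        J = [Jmax + θI − sqrt((Jmax + θI)² − 4Jmaxγ θI)] / (2γ) .

    J(0) = 0, J is nondecreasing in I and saturates at Jmax.
    """
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise ValueError("irradiance must be nonnegative")
    b = Jmax + theta * I
    disc = b * b - 4.0 * Jmax * gamma * theta * I
    out = (b - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * gamma)
    return out.item() if out.ndim == 0 else out


def _check_ci(ci) -> np.ndarray:
    ci = np.asarray(ci, dtype=float)
    if np.any(ci <= 0):
        raise ValueError("ci must be positive")
    return ci


def rubisco_limited_rate(ci, Tl, params: ModelParameters):
    """Rubisco-limited carboxylation rate Wc (µmol m⁻² s⁻¹).

    Wc = Vcmax·ci / (ci + Kc(Tl)·(1 + Oi/Ko(Tl))), assuming RuBP in
    excess and cc = ci.
    """
    ci = _check_ci(ci)
    keff = kc(Tl, params) * (1.0 + params.Oi / ko(Tl, params))
    out = params.Vcmax * ci / (ci + keff)
    return out.item() if out.ndim == 0 else out


def transport_limited_rate(ci, Tl, I, params: ModelParameters):
    """Electron-transport-limited carboxylation rate Wj (µmol m⁻² s⁻¹).

    Wj = J(I) / (4 + 8·Γ*(Tl)/ci); 4 and 8 electrons per carboxylation
    and oxygenation respectively.
    """
    ci = _check_ci(ci)
    J = electron_transport(I, params.Jmax, params.theta, params.gamma)
    out = J / (4.0 + 8.0 * gamma_star(Tl, params) / ci)
    return out.item() if out.ndim == 0 else out


def steady_state_assimilation(ci, Tl, I, params: ModelParameters):
    """Steady-state FvCB net assimilation and the limiting process.

    Returns ``(An, limitation)`` where An = min(Wc, Wj)(1 − Γ*/ci) − Rd
    and limitation is "Wc" or "Wj" (ties reported as "Wc"). For array
    inputs the limitation is an array of those strings.
    """
    ci = _check_ci(ci)
    wc = rubisco_limited_rate(ci, Tl, params)
    wj = transport_limited_rate(ci, Tl, I, params)
    gs = gamma_star(Tl, params)
    an = np.minimum(wc, wj) * (1.0 - gs / ci) - params.Rd
    limitation = np.where(np.less_equal(wc, wj), WC_LIMITED, WJ_LIMITED)
    if np.ndim(an) == 0:
        return float(an), str(limitation)
    return an, limitation


def fick_assimilation(gtc, ca, ci):
    """Net CO₂ flux into the leaf by Fick's law: An = gtc·(ca − ci)."""
    gtc = np.asarray(gtc, dtype=float)
    if np.any(gtc <= 0):
        raise ValueError("gtc must be positive")
    out = gtc * (np.asarray(ca, dtype=float) - np.asarray(ci, dtype=float))
    return out.item() if out.ndim == 0 else out


def stomatal_target(I, ca, params: ModelParameters):
    """Steady-state conductance target G(I, ca), mol m⁻² s⁻¹.

    Saturating-linear in irradiance, G = min(gmin + alpha·I, gmax),
    with the parameter triple of the ca regime nearest to ``ca``.
    """
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise ValueError("irradiance must be nonnegative")
    regime = params.stomatal_regime(float(np.asarray(ca).flat[0]))
    out = np.minimum(regime.gmin + regime.alpha * I, regime.gmax)
    return out.item() if out.ndim == 0 else out


def stomatal_rhs(gtc, I, ca, params: ModelParameters):
    """Right-hand side of the stomatal conductance ODE.

    dgtc/dt = (G − gtc)/ku when the conductance is rising (G ≥ gtc),
    (G − gtc)/kd when it is falling.  Because both time constants are
    positive this branch choice is equivalent to conditioning on the
    sign of dgtc/dt itself, and the right-hand side is continuous at
    the switch (both branches vanish at gtc = G).
    """
    gtc = np.asarray(gtc, dtype=float)
    if np.any(gtc <= 0):
        raise ValueError("gtc must be positive")
    G = stomatal_target(I, ca, params)
    k = np.where(np.greater_equal(G, gtc), params.ku, params.kd)
    out = (G - gtc) / k
    return out.item() if out.ndim == 0 else out


def ci_rhs(state: LeafState, env: EnvironmentSample, params: ModelParameters):
    """Right-hand side of the intercellular CO₂ mass balance.

    dci/dt = (R·Tl/(d·Pa)) · [gtc(ca − ci) + Rd − min(Wc, Wj)(1 − Γ*/ci)]

    in µmol mol⁻¹ s⁻¹.  Zero exactly when Fick influx plus respiration
    balances the FvCB sink.
    """
    an_fvcb, _ = steady_state_assimilation(state.ci, env.Tl, env.I, params)
    prefactor = params.R * env.Tl / (params.d * params.Pa)
    # bracket = gtc(ca - ci) + Rd - min(Wc, Wj)(1 - Γ*/ci) = Fick An - FvCB An
    return prefactor * (fick_assimilation(state.gtc, env.ca, state.ci) - an_fvcb)
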