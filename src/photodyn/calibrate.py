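"""A-priori steady-state calibration from gas-exchange response curves.

Three curve families parameterise the model before any dynamic
fitting: CO₂-response (A/ci) curves at saturating light give the
maximum carboxylation rate Vcmax and day respiration Rd from the
Rubisco-limited region; light-response curves give the electron
transport parameters (Jmax, θ, γ) of the non-rectangular hyperbola;
and steady-state conductance-versus-irradiance data give the
saturating-linear stomatal target triple (gmin, gmax, alpha) per
ambient CO₂ regime.

Replicates are fitted individually and pooled; the pooled fit is the
headline estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import model
from .params import ModelParameters, StomatalTargetParams

#: default upper edge of the Rubisco-limited region in an A/ci curve
ACI_CI_CUT = 300.0  # umol mol-1


@dataclass
class SteadyStateCurve:
    """One replicate of a steady-state response curve.

    ``kind`` is ``aci`` (x = ci, y = An), ``light_response`` (x = I,
    y = An, optional concurrent ``ci``) or ``conductance`` (x = I,
    y = gtc).  Points are sorted by abscissa on construction.
    """

    kind: str
    x: np.ndarray
    y: np.ndarray
    replicate: int = 0
    Tl: float = 298.15
    ca: float = 400.0
    ci: np.ndarray | None = None  # concurrent ci for light_response curves

    def __post_init__(self) -> None:
        if self.kind not in ("aci", "light_response", "conductance"):
            raise ValueError(f"unknown curve kind {self.kind!r}")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.size != self.y.size:
            raise ValueError("abscissa and ordinate lengths differ")
        if self.x.size < 5:
            raise ValueError("a steady-state curve needs at least 5 points")
        order = np.argsort(self.x, kind="stable")
        self.x = self.x[order]
        self.y = self.y[order]
        if self.ci is not None:
            self.ci = np.asarray(self.ci, dtype=float)[order]
        if np.any(np.diff(np.unique(self.x)) <= 0):  # pragma: no cover
            raise ValueError("abscissa must be monotone after sorting")


@dataclass
class CalibrationFit:
    """Pooled estimates with per-replicate diagnostics."""

    estimates: dict[str, float]
    per_replicate: list[dict[str, float]] = field(default_factory=list)
    residual_rms: float = float("nan")

    @property
    def spread(self) -> dict[str, float]:
        """Across-replicate standard deviation per parameter."""
        if not self.per_replicate:
            return {}
        keys = self.per_replicate[0].keys()
        return {
            k: float(np.std([r[k] for r in self.per_replicate], ddof=1))
            if len(self.per_replicate) > 1 else 0.0
            for k in keys
        }


def _fit_aci_single(ci: np.ndarray, an: np.ndarray, Tl: float,
                    params: ModelParameters, ci_cut: float) -> dict[str, float]:
    mask = ci <= ci_cut
    if mask.sum() < 4:
        raise ValueError(
            f"only {int(mask.sum())} points at ci <= {ci_cut}; "
            "need at least 4 in the Rubisco-limited region"
        )
    ci_r, an_r = ci[mask], an[mask]
    gs = model.gamma_star(Tl, params)
    keff = model.kc(Tl, params) * (1.0 + params.Oi / model.ko(Tl, params))

    # An = Vcmax (ci - Γ*)/(ci + Keff) - Rd is linear in (Vcmax, Rd)
    basis = (ci_r - gs) / (ci_r + keff)
    A = np.column_stack([basis, -np.ones_like(basis)])
    coef, *_ = np.linalg.lstsq(A, an_r, rcond=None)
    return {"Vcmax": float(coef[0]), "Rd": float(coef[1])}


def fit_aci(curves: list[SteadyStateCurve], *, params: ModelParameters | None = None,
            ci_cut: float = ACI_CI_CUT) -> CalibrationFit:
    """Estimate (Vcmax, Rd) from A/ci curves at saturating light.

    Fits An = Vcmax·(ci − Γ*)/(ci + Kc(1 + Oi/Ko)) − Rd by least
    squares over the Rubisco-limited region ci ≤ ``ci_cut``; the
    temperature responses are evaluated from ``params`` at each
    curve's leaf temperature.  Points above the cut never enter the
    fit.
    """
    params = params or ModelParameters()
    if not curves:
        raise ValueError("no curves supplied")
    per_rep = [
        _fit_aci_single(c.x, c.y, c.Tl, params, ci_cut) for c in curves
    ]
    ci_all = np.concatenate([c.x for c in curves])
    an_all = np.concatenate([c.y for c in curves])
    # pooled fit assumes a common leaf temperature across replicates
    Tl_pool = float(np.mean([c.Tl for c in curves]))
    pooled = _fit_aci_single(ci_all, an_all, Tl_pool, params, ci_cut)
    gs = model.gamma_star(Tl_pool, params)
    keff = model.kc(Tl_pool, params) * (1.0 + params.Oi / model.ko(Tl_pool, params))
    mask = ci_all <= ci_cut
    pred = pooled["Vcmax"] * (ci_all[mask] - gs) / (ci_all[mask] + keff) - pooled["Rd"]
    rms = float(np.sqrt(np.mean((pred - an_all[mask]) ** 2)))
    return CalibrationFit(estimates=pooled, per_replicate=per_rep, residual_rms=rms)


def _light_response_residuals(theta_vec, curves, params):
    Jmax, th, ga = theta_vec
    res = []
    for c in curves:
        ci = c.ci
        if ci is None:
            raise ValueError(
                "light_response curve lacks concurrent ci readings; supply ci"
            )
        gs = model.gamma_star(c.Tl, params)
        keff = model.kc(c.Tl, params) * (1.0 + params.Oi / model.ko(c.Tl, params))
        J = model.electron_transport(c.x, Jmax, th, ga)
        wc = params.Vcmax * ci / (ci + keff)
        wj = J / (4.0 + 8.0 * gs / ci)
        an = np.minimum(wc, wj) * (1.0 - gs / ci) - params.Rd
        res.append(an - c.y)
    return np.concatenate(res)


def fit_light_response(curves: list[SteadyStateCurve], *,
                       params: ModelParameters | None = None,
                       x0: tuple[float, float, float] | None = None) -> CalibrationFit:
    """Estimate the electron-transport parameters (Jmax, theta, gamma).

    Fits the full steady-state assimilation model (with Vcmax and Rd
    held at their a-priori values from ``params``) to An-versus-I
    curves, using each curve's concurrent ci readings.  Pooling curves
    from both ambient CO₂ regimes is recommended: under 400 ppm the
    high-irradiance points are Rubisco-limited and constrain Jmax only
    weakly.  Bounds: gamma in (0, 1], theta > 0.
    """
    params = params or ModelParameters()
    if not curves:
        raise ValueError("no curves supplied")
    an_max = max(float(np.max(c.y)) for c in curves)
    if x0 is None:
        x0 = (max(4.5 * (an_max + params.Rd), 20.0), 0.4, 0.85)
    lb = [1.0, 1e-3, 1e-3]
    ub = [2000.0, 5.0, 1.0]
    sol = least_squares(
        _light_response_residuals, x0, bounds=(lb, ub),
        args=(curves, params), xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not sol.success:
        raise RuntimeError(
            f"light-response fit failed: {sol.message}; residual norm {sol.cost:.3g}"
        )
    est = {"Jmax": float(sol.x[0]), "theta": float(sol.x[1]), "gamma": float(sol.x[2])}
    per_rep = []
    for c in curves:
        single = least_squares(
            _light_response_residuals, sol.x, bounds=(lb, ub),
            args=([c], params), xtol=1e-12, ftol=1e-12,
        )
        per_rep.append({"Jmax": float(single.x[0]), "theta": float(single.x[1]),
                        "gamma": float(single.x[2])})
    rms = float(np.sqrt(np.mean(_light_response_residuals(sol.x, curves, params) ** 2)))
    return CalibrationFit(estimates=est, per_replicate=per_rep, residual_rms=rms)


def _fit_target_single(I: np.ndarray, g: np.ndarray) -> dict[str, float]:
    x0 = (float(g.min()), float(g.max()), max((g.max() - g.min()) / max(I.max(), 1.0), 1e-6))

    def resid(theta):
        gmin, gmax, alpha = theta
        return np.minimum(gmin + alpha * I, gmax) - g

    sol = least_squares(resid, x0, bounds=([0.0, 0.0, 0.0], [5.0, 5.0, 1.0]),
                        xtol=1e-14, ftol=1e-14)
    gmin, gmax, alpha = sol.x
    if gmin > gmax:  # degenerate constant data
        gmin = gmax = float(np.mean(g))
        alpha = 0.0
    return {"gmin": float(gmin), "gmax": float(gmax), "alpha": float(alpha)}


def fit_stomatal_target(curves: list[SteadyStateCurve],
                        expected_regimes: tuple[int, ...] = (400, 800),
                        ) -> dict[int, StomatalTargetParams]:
    """Fit the saturating-linear conductance target per ca regime.

    Curves are grouped by their nearest expected regime; each group is
    pooled into one (gmin, gmax, alpha) triple.  A warning is issued
    when only one of the expected regimes is represented.
    """
    import warnings

    if not curves:
        raise ValueError("no curves supplied")
    groups: dict[int, list[SteadyStateCurve]] = {}
    for c in curves:
        if c.kind != "conductance":
            raise ValueError("fit_stomatal_target expects conductance curves")
        regime = min(expected_regimes, key=lambda r: abs(r - c.ca))
        groups.setdefault(regime, []).append(c)
    if len(groups) < len(expected_regimes):
        warnings.warn(
            f"only regimes {sorted(groups)} supplied of expected "
            f"{sorted(expected_regimes)}; returning a partial result"
        )
    out: dict[int, StomatalTargetParams] = {}
    for regime, grp in sorted(groups.items()):
        I = np.concatenate([c.x for c in grp])
        g = np.concatenate([c.y for c in grp])
        est = _fit_target_single(I, g)
        out[regime] = StomatalTargetParams(**est)
    return out
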