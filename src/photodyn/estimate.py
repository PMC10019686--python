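"""Estimation of the dynamic parameters (ku, kd, c3) from gas exchange.

The three parameters are inferred by minimising a weighted sum of
squared residuals over the measured conductance, intercellular CO₂
and net assimilation series,

    O = Σ [0.2 (gtc − gtc,m)² + 0.2 (ci − ci,m)² + 0.6 (An − An,m)²] / N ,

with the simulation initialised from the first measured record.  The
weights favour accurate prediction of An.  The default optimiser is a
seeded, bounded differential-evolution search with a population of
300 candidate triples; confidence intervals come from the profile
likelihood, re-optimising the remaining free parameters along a grid
and thresholding at O_min · (1 + F₀.₉₅(1, N−3)/(N−3)).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import differential_evolution, minimize

from ._kernels import integrate_fast
from .model import LeafState
from .params import ModelParameters
from .simulate import EnvironmentTrace, SimulationResult, _precompute

logger = logging.getLogger(__name__)

#: default search box for the free parameter triple
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "ku": (10.0, 1000.0),
    "kd": (50.0, 3000.0),
    "c3": (37.5, 38.5),
}
#: residual weights for (gtc, ci, An)
DEFAULT_WEIGHTS = (0.2, 0.2, 0.6)


@dataclass
class GasExchangeDataset:
    """An environment trace with aligned measured outputs.

    ``gtc_m`` in mol m⁻² s⁻¹, ``ci_m`` in µmol mol⁻¹, ``An_m`` in
    µmol m⁻² s⁻¹.
    """

    trace: EnvironmentTrace
    gtc_m: np.ndarray
    ci_m: np.ndarray
    An_m: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gtc_m = np.asarray(self.gtc_m, dtype=float)
        self.ci_m = np.asarray(self.ci_m, dtype=float)
        self.An_m = np.asarray(self.An_m, dtype=float)
        for name in ("gtc_m", "ci_m", "An_m"):
            arr = getattr(self, name)
            if arr.shape != self.trace.t.shape:
                raise ValueError(f"measured column {name} misaligned with trace")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"measured column {name} contains missing values")

    @property
    def N(self) -> int:
        return len(self.trace)

    def initial_state(self) -> LeafState:
        return LeafState(gtc=float(self.gtc_m[0]), ci=float(self.ci_m[0]))

    def to_frame(self) -> pd.DataFrame:
        frame = self.trace.to_frame()
        frame["gtc_m"] = self.gtc_m
        frame["ci_m"] = self.ci_m
        frame["An_m"] = self.An_m
        return frame


@dataclass
class ProfileResult:
    """Profile likelihood of one parameter: grid, objective, interval."""

    param: str
    grid: np.ndarray
    objective: np.ndarray
    threshold: float
    interval: tuple[float, float]
    open_lower: bool = False
    open_upper: bool = False


@dataclass
class FitResult:
    """Outcome of a global fit of the free parameter triple."""

    estimates: dict[str, float]
    objective: float
    bounds: dict[str, tuple[float, float]]
    seed: int | None
    population: int
    nfev: int
    nit: int
    success: bool
    message: str
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    profiles: dict[str, ProfileResult] = field(default_factory=dict)

    def to_json(self, path=None, **extra) -> str:
        payload = {
            "estimates": self.estimates,
            "objective": self.objective,
            "bounds": self.bounds,
            "seed": self.seed,
            "population": self.population,
            "nfev": self.nfev,
            "nit": self.nit,
            "success": self.success,
            "message": self.message,
            "intervals": {k: list(v) for k, v in self.intervals.items()},
            **extra,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _make_objective(dataset: GasExchangeDataset, fixed: ModelParameters,
                    free_names: tuple[str, ...],
                    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
                    normalised: bool = False, n_sub: int = 10):
    """Build a fast objective over the named free parameters.

    Drivers that do not depend on the free triple are precomputed once;
    only the effective Michaelis constant (through c3) is rebuilt per
    call.  ``normalised`` rescales each channel's residuals by the
    variance of its measured series (off by default: the literal
    weighted objective is the reference behaviour).
    """
    trace = dataset.trace
    G, gs, keff0, J, pf = _precompute(trace, fixed)
    ko_arr = np.exp(fixed.c2 - fixed.dHa2 / (fixed.R1 * trace.Tl))
    kc_base = np.exp(-fixed.dHa3 / (fixed.R1 * trace.Tl)) * (1.0 + fixed.Oi / ko_arr)
    init = dataset.initial_state()
    w_g, w_c, w_a = weights
    if normalised:
        w_g = w_g / max(np.var(dataset.gtc_m), 1e-12)
        w_c = w_c / max(np.var(dataset.ci_m), 1e-12)
        w_a = w_a / max(np.var(dataset.An_m), 1e-12)
    n = dataset.N

    def objective_vec(theta: np.ndarray) -> float:
        values = dict(zip(free_names, theta))
        if "k" in values:  # symmetric single time constant
            values["ku"] = values["kd"] = values.pop("k")
        ku = values.get("ku", fixed.ku)
        kd = values.get("kd", fixed.kd)
        c3 = values.get("c3", fixed.c3)
        keff = math.exp(c3) * kc_base if "c3" in free_names or "c3" in values else keff0
        try:
            gtc, ci = integrate_fast(
                trace.t, G, trace.ca, keff, gs, J, pf,
                ku, kd, fixed.Vcmax, fixed.Rd, init.gtc, init.ci, n_sub, False,
            )
        except Exception as exc:  # pragma: no cover - defensive sentinel
            logger.warning("simulation failed during objective evaluation: %s", exc)
            return math.inf
        an = gtc * (trace.ca - ci)
        if not (np.all(np.isfinite(an)) and np.all(np.isfinite(ci))):
            logger.warning("non-finite trajectory at theta=%s", values)
            return math.inf
        o = (
            w_g * np.sum((gtc - dataset.gtc_m) ** 2)
            + w_c * np.sum((ci - dataset.ci_m) ** 2)
            + w_a * np.sum((an - dataset.An_m) ** 2)
        ) / n
        return float(o)

    return objective_vec


def objective(params_free: tuple[float, float, float], dataset: GasExchangeDataset,
              fixed: ModelParameters, *, weights=DEFAULT_WEIGHTS,
              normalised: bool = False, n_sub: int = 10) -> float:
    """Weighted sum-of-squares objective for a (ku, kd, c3) triple."""
    fun = _make_objective(dataset, fixed, ("ku", "kd", "c3"), weights,
                          normalised, n_sub)
    return fun(np.asarray(params_free, dtype=float))


def fit(dataset: GasExchangeDataset, *, bounds: dict[str, tuple[float, float]] | None = None,
        fixed: ModelParameters | None = None, seed: int | None = None,
        population: int = 300, maxiter: int = 40, tol: float = 0.01,
        symmetric: bool = False, weights=DEFAULT_WEIGHTS,
        normalised: bool = False, n_sub: int = 10) -> FitResult:
    """Global fit of the free dynamic parameters.

    Uses differential evolution (seeded, bounded, population-based)
    with total population ``population``; deterministic given the
    seed.  ``symmetric=True`` constrains ku = kd (a single time
    constant), for comparing against the asymmetric model.
    """
    if dataset.N <= 100:
        raise ValueError(f"need more than 100 records to fit, got {dataset.N}")
    fixed = fixed or ModelParameters()
    user_bounds = dict(DEFAULT_BOUNDS)
    if bounds:
        user_bounds.update(bounds)
    if symmetric:
        lo = min(user_bounds["ku"][0], user_bounds["kd"][0])
        hi = max(user_bounds["ku"][1], user_bounds["kd"][1])
        names: tuple[str, ...] = ("k", "c3")
        box = [(lo, hi), user_bounds["c3"]]
        used_bounds = {"k": (lo, hi), "c3": user_bounds["c3"]}
    else:
        names = ("ku", "kd", "c3")
        box = [user_bounds[p] for p in names]
        used_bounds = {p: user_bounds[p] for p in names}
    fun = _make_objective(dataset, fixed, names, weights, normalised, n_sub)
    popsize = max(math.ceil(population / len(names)), 5)
    result = differential_evolution(
        fun, box, seed=seed, popsize=popsize, maxiter=maxiter, tol=tol,
        polish=True, init="latinhypercube",
    )
    if not np.isfinite(result.fun):
        raise RuntimeError("objective was non-finite everywhere in the search box")
    estimates = dict(zip(names, (float(v) for v in result.x)))
    return FitResult(
        estimates=estimates, objective=float(result.fun), bounds=used_bounds,
        seed=seed, population=popsize * len(names), nfev=int(result.nfev),
        nit=int(result.nit), success=bool(result.success), message=str(result.message),
    )


def profile_threshold(o_min: float, N: int, n_free: int = 3, level: float = 0.95) -> float:
    """Objective cut-off for a profile-likelihood confidence interval.

    Standard weighted-SSE likelihood-ratio rule:
    O ≤ O_min · (1 + F_level(1, N − n_free) / (N − n_free)).
    """
    q = stats.f.ppf(level, 1, N - n_free)
    return o_min * (1.0 + q / (N - n_free))


def profile_likelihood(dataset: GasExchangeDataset, param: str,
                       grid: np.ndarray, *, fixed: ModelParameters | None = None,
                       fit_result: FitResult | None = None,
                       bounds: dict[str, tuple[float, float]] | None = None,
                       level: float = 0.95, weights=DEFAULT_WEIGHTS,
                       n_sub: int = 10) -> ProfileResult:
    """Profile the objective along one parameter.

    For each grid value the remaining two free parameters are
    re-optimised (Nelder–Mead within the search box, warm-started
    from the neighbouring grid point).  Returns the profile and the
    interval where it stays below the likelihood-ratio threshold; if
    the profile never crosses the threshold on a side, that endpoint
    is flagged open and a warning is logged.
    """
    if param not in ("ku", "kd", "c3"):
        raise ValueError(f"unknown free parameter {param!r}")
    fixed = fixed or ModelParameters()
    user_bounds = dict(DEFAULT_BOUNDS)
    if bounds:
        user_bounds.update(bounds)
    others = tuple(p for p in ("ku", "kd", "c3") if p != param)
    grid = np.sort(np.asarray(grid, dtype=float))

    if fit_result is not None:
        center = {**fit_result.estimates}
    else:
        center = {"ku": fixed.ku, "kd": fixed.kd, "c3": fixed.c3}
    box = [user_bounds[p] for p in others]

    profile = np.empty(grid.size)
    start_idx = int(np.argmin(np.abs(grid - center.get(param, grid[grid.size // 2]))))

    def conditional(value: float, x0: np.ndarray) -> tuple[float, np.ndarray]:
        fixed_at = fixed.replace(**{param: float(value)})
        fun = _make_objective(dataset, fixed_at, others, weights, False, n_sub)
        res = minimize(fun, x0, method="Nelder-Mead", bounds=box,
                       options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 400})
        return float(res.fun), np.asarray(res.x)

    x0 = np.asarray([center[p] for p in others], dtype=float)
    # sweep outward from the estimate in both directions, warm-starting
    for indices in (range(start_idx, grid.size), range(start_idx - 1, -1, -1)):
        xw = x0.copy()
        for i in indices:
            profile[i], xw = conditional(grid[i], xw)

    o_min = float(profile.min())
    if fit_result is not None and fit_result.objective < o_min:
        o_min = fit_result.objective
    thr = profile_threshold(o_min, dataset.N, 3, level)
    inside = profile <= thr

    def _cross(i_out: int, i_in: int) -> float:
        o0, o1 = profile[i_out], profile[i_in]
        if o0 == o1:
            return float(grid[i_in])
        w = (thr - o1) / (o0 - o1)
        return float(grid[i_in] + w * (grid[i_out] - grid[i_in]))

    idx = np.flatnonzero(inside)
    if idx.size == 0:
        raise RuntimeError("profile lies entirely above the threshold; widen the grid")
    lo_i, hi_i = int(idx[0]), int(idx[-1])
    open_lower = lo_i == 0 and profile[0] <= thr
    open_upper = hi_i == grid.size - 1 and profile[-1] <= thr
    lower = float(grid[0]) if open_lower else _cross(lo_i - 1, lo_i)
    upper = float(grid[-1]) if open_upper else _cross(hi_i + 1, hi_i)
    if open_lower or open_upper:
        logger.warning(
            "profile of %s does not cross the threshold inside the grid "
            "(open lower=%s, upper=%s)", param, open_lower, open_upper)
    return ProfileResult(
        param=param, grid=grid, objective=profile, threshold=thr,
        interval=(lower, upper), open_lower=open_lower, open_upper=open_upper,
    )


def goodness(dataset: GasExchangeDataset, result: SimulationResult) -> dict[str, float]:
    """Root-mean-square errors and R² per measured channel.

    RMSE = sqrt(Σ(x − x_m)²/N); R² = 1 − SS_res/SS_tot.
    """
    if result.t.shape != dataset.trace.t.shape:
        raise ValueError("simulation and dataset are not aligned")
    out: dict[str, float] = {}
    for name, sim, meas in (
        ("An", result.An, dataset.An_m),
        ("gtc", result.gtc, dataset.gtc_m),
        ("ci", result.ci, dataset.ci_m),
    ):
        res = sim - meas
        ss_tot = float(np.sum((meas - meas.mean()) ** 2))
        if ss_tot == 0.0:
            raise ValueError(f"measured {name} series has zero variance; R2 undefined")
        out[f"RMSE_{name}"] = float(np.sqrt(np.mean(res**2)))
        out[f"R2_{name}"] = 1.0 - float(np.sum(res**2)) / ss_tot
    return out
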