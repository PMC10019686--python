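"""Synthetic environment traces, gas-exchange datasets, and curves.

The generators emulate the statistical structure of greenhouse and
climate-chamber gas-exchange campaigns: a six-hour September day with
irradiance fluctuating in a 200–400 µmol m⁻² s⁻¹ band punctuated by
three smooth high-light excursions reaching ~1193 µmol m⁻² s⁻¹, a
chamber pattern alternating between 50 and 500 µmol m⁻² s⁻¹ every
minute, and the steady-state CO₂- and light-response designs used for
a-priori calibration.  All generators are pure functions of their
spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimate import GasExchangeDataset
from .calibrate import SteadyStateCurve
from .params import ModelParameters
from .simulate import EnvironmentTrace, simulate, steady_state_solve

#: CO₂ step sequence of the A/ci protocol (ppm set points, measurement order)
ACI_CA_DESIGN = (400, 300, 200, 100, 50, 400, 400, 500, 600, 800, 1000, 1200)
#: irradiance steps of the light-response protocol (µmol m⁻² s⁻¹)
LIGHT_I_DESIGN = (0, 50, 100, 200, 400, 600, 800, 1000, 1200)
ACI_REPLICATES = 8
LIGHT_REPLICATES = 6


@dataclass(frozen=True)
class PeakWindow:
    """One smooth high-light excursion: start/end (s) and peak irradiance."""

    start: float
    end: float
    peak: float


@dataclass(frozen=True)
class IrradianceProfileSpec:
    """Specification of a synthetic irradiance profile.

    Modes: ``greenhouse_day`` (fluctuating baseline plus peak
    excursions), ``chamber_fluctuating`` (square wave between two
    levels), ``step`` (single step up then down), ``constant``.
    """

    mode: str = "greenhouse_day"
    duration: float = 21600.0  # s, six-hour daytime window
    dt: float = 2.0  # s, instrument logging cadence
    baseline: tuple[float, float] = (200.0, 400.0)
    # default peak windows: three excursions at 30-70, 105-170 and 335-360 min
    peaks: tuple[PeakWindow, ...] = (
        PeakWindow(1800.0, 4200.0, 1000.0),
        PeakWindow(6300.0, 10200.0, 1100.0),
        PeakWindow(20100.0, 21600.0, 1193.0),
    )
    peak_max: float = 1193.0
    fluctuation_period: float = 120.0  # s, correlation scale of the baseline
    levels: tuple[float, float] = (50.0, 500.0)  # chamber / step levels
    switch_period: float = 60.0  # s, chamber switching period
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")
        for p in self.peaks:
            if not (0 <= p.start < p.end):
                raise ValueError("peak window must have 0 <= start < end")
            if p.peak < 0:
                raise ValueError("peak irradiance must be nonnegative")

    def active_peaks(self) -> tuple[PeakWindow, ...]:
        """Peak windows intersecting the duration, clamped to it."""
        out = []
        for p in self.peaks:
            if p.start < self.duration:
                out.append(PeakWindow(p.start, min(p.end, self.duration), p.peak))
        return tuple(out)


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian measurement-noise magnitudes for the three channels.

    Fixture settings of plausible infrared-gas-analyser magnitude, not
    claims about any particular instrument.
    """

    sigma_An: float = 0.5  # umol m-2 s-1
    sigma_gtc: float = 0.005  # mol m-2 s-1
    sigma_ci: float = 3.0  # umol mol-1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_An, self.sigma_gtc, self.sigma_ci) < 0:
            raise ValueError("noise magnitudes must be nonnegative")


def _smooth_noise(rng: np.random.Generator, n: int, dt: float,
                  period: float) -> np.ndarray:
    """Low-pass-filtered standard noise, rescaled to unit span [0, 1]."""
    raw = rng.standard_normal(n + 1)
    width = max(int(period / dt), 1)
    kernel = np.exp(-0.5 * np.linspace(-3, 3, 2 * width + 1) ** 2)
    kernel /= kernel.sum()
    sm = np.convolve(np.concatenate([raw, raw[: 2 * width]]), kernel, mode="same")[:n]
    lo, hi = sm.min(), sm.max()
    if hi - lo < 1e-12:
        return np.full(n, 0.5)
    return (sm - lo) / (hi - lo)


def _irradiance(spec: IrradianceProfileSpec) -> tuple[np.ndarray, np.ndarray]:
    t = np.arange(0.0, spec.duration + spec.dt / 2, spec.dt)
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "constant":
        return t, np.full_like(t, spec.levels[1])
    if spec.mode == "step":
        I = np.where(
            (t >= spec.duration / 3) & (t < 2 * spec.duration / 3),
            spec.levels[1], spec.levels[0],
        )
        return t, I.astype(float)
    if spec.mode == "chamber_fluctuating":
        phase = np.floor(t / spec.switch_period).astype(int) % 2
        return t, np.where(phase == 0, spec.levels[0], spec.levels[1]).astype(float)
    if spec.mode == "greenhouse_day":
        lo, hi = spec.baseline
        base = lo + (hi - lo) * _smooth_noise(rng, t.size, spec.dt,
                                              spec.fluctuation_period)
        I = base.copy()
        peaks = spec.active_peaks()
        for p in peaks:
            inside = (t >= p.start) & (t <= p.end)
            phase = (t[inside] - p.start) / (p.end - p.start)
            envelope = np.sin(np.pi * phase) ** 2
            wobble = 0.9 + 0.1 * _smooth_noise(rng, int(inside.sum()), spec.dt,
                                               spec.fluctuation_period / 2)
            I[inside] = base[inside] + (p.peak - base[inside]) * envelope * wobble
        # pin the highest excursion to the specified daily maximum
        if peaks and I.max() > hi:
            target = max(p.peak for p in peaks)
            mask = I > hi
            I[mask] = hi + (I[mask] - hi) * (target - hi) / (I.max() - hi)
        return t, np.clip(I, 0.0, None)
    raise ValueError(f"unknown irradiance mode {spec.mode!r}")


def generate_environment(spec: IrradianceProfileSpec, *, Tl_mean: float = 296.0,
                         Tl_amplitude: float = 1.5, Tl_light_coupling: float = 0.0015,
                         ca: float = 400.0) -> EnvironmentTrace:
    """Synthetic environment trace at the given CO₂ set point.

    Leaf temperature drifts sinusoidally around ``Tl_mean`` (K) with
    the given amplitude, warmed slightly under high light via
    ``Tl_light_coupling`` (K per µmol m⁻² s⁻¹, applied to I − 300 and
    smoothed over five minutes).
    """
    t, I = _irradiance(spec)
    Tl = Tl_mean + Tl_amplitude * np.sin(2 * np.pi * (t / max(spec.duration, 1.0) - 0.25))
    if Tl_light_coupling:
        width = min(max(int(300.0 / spec.dt), 1), I.size)
        kernel = np.ones(width) / width
        excess = np.convolve(I - 300.0, kernel, mode="same")
        Tl = Tl + Tl_light_coupling * excess
    return EnvironmentTrace(
        t=t, I=I, Tl=Tl, ca=np.full_like(t, float(ca)),
        label=f"synthetic:{spec.mode}", ca_regime=int(round(ca / 100) * 100),
    )


def generate_gas_exchange(trace: EnvironmentTrace, params: ModelParameters,
                          noise: NoiseSpec | None = None) -> GasExchangeDataset:
    """Forward-simulated dataset with additive Gaussian channel noise.

    The simulation starts from the model's own steady state under the
    first sample; the generating parameter set and noise spec are kept
    in ``metadata`` as ground truth.
    """
    noise = noise or NoiseSpec(sigma_An=0.0, sigma_gtc=0.0, sigma_ci=0.0)
    result = simulate(trace, params)
    rng = np.random.default_rng(noise.seed)
    n = len(trace)
    gtc_m = result.gtc + noise.sigma_gtc * rng.standard_normal(n)
    ci_m = result.ci + noise.sigma_ci * rng.standard_normal(n)
    an_m = result.An + noise.sigma_An * rng.standard_normal(n)
    return GasExchangeDataset(
        trace=trace, gtc_m=gtc_m, ci_m=ci_m, An_m=an_m,
        metadata={
            "truth": {"ku": params.ku, "kd": params.kd, "c3": params.c3},
            "noise": {"sigma_An": noise.sigma_An, "sigma_gtc": noise.sigma_gtc,
                      "sigma_ci": noise.sigma_ci, "seed": noise.seed},
        },
    )


def generate_steady_state_curves(kind: str, params: ModelParameters, *,
                                 design: tuple[float, ...] | None = None,
                                 replicates: int | None = None,
                                 Tl: float = 298.15, ca: float = 400.0,
                                 I: float = 1800.0, sigma: float = 0.0,
                                 seed: int = 0) -> list[SteadyStateCurve]:
    """Steady-state calibration curves evaluated on the protocol designs.

    ``aci``: An versus ci with ca stepped through the CO₂ protocol at
    saturating light; ``light_response``: An (and concurrent ci)
    versus I at fixed ca; ``conductance``: steady-state gtc versus I.
    Noise ``sigma`` is in the units of the ordinate.
    """
    from .model import EnvironmentSample  # local import to avoid cycle noise

    rng = np.random.default_rng(seed)
    curves: list[SteadyStateCurve] = []
    if kind == "aci":
        design = tuple(design or ACI_CA_DESIGN)
        replicates = replicates or ACI_REPLICATES
        for rep in range(replicates):
            ci_vals, an_vals = [], []
            for ca_step in design:
                st = steady_state_solve(
                    EnvironmentSample(t=0.0, I=I, Tl=Tl, ca=float(ca_step)), params
                )
                ci_vals.append(st.ci)
                an_vals.append(st.gtc * (ca_step - st.ci))
            y = np.asarray(an_vals) + sigma * rng.standard_normal(len(design))
            curves.append(SteadyStateCurve(
                kind="aci", x=np.asarray(ci_vals), y=y,
                replicate=rep, Tl=Tl, ca=float(np.mean(design))))
        return curves
    if kind == "light_response":
        design = tuple(design or LIGHT_I_DESIGN)
        replicates = replicates or LIGHT_REPLICATES
        for rep in range(replicates):
            ci_vals, an_vals = [], []
            for I_step in design:
                st = steady_state_solve(
                    EnvironmentSample(t=0.0, I=float(I_step), Tl=Tl, ca=ca), params
                )
                ci_vals.append(st.ci)
                an_vals.append(st.gtc * (ca - st.ci))
            y = np.asarray(an_vals) + sigma * rng.standard_normal(len(design))
            curves.append(SteadyStateCurve(
                kind="light_response", x=np.asarray(design, dtype=float), y=y,
                replicate=rep, Tl=Tl, ca=ca, ci=np.asarray(ci_vals)))
        return curves
    if kind == "conductance":
        design = tuple(design or LIGHT_I_DESIGN)
        replicates = replicates or LIGHT_REPLICATES
        regime = params.stomatal_regime(ca)
        for rep in range(replicates):
            I_arr = np.asarray(design, dtype=float)
            g = np.minimum(regime.gmin + regime.alpha * I_arr, regime.gmax)
            y = g + sigma * rng.standard_normal(I_arr.size)
            curves.append(SteadyStateCurve(
                kind="conductance", x=I_arr, y=y, replicate=rep, Tl=Tl, ca=ca))
        return curves
    raise ValueError(f"unknown curve kind {kind!r}")
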