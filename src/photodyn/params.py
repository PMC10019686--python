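"""Model parameters: constants, free parameters, and configuration I/O.

The parameter set follows the mixed-unit convention standard in leaf
gas-exchange work: conductances in mol m⁻² s⁻¹, CO₂ mole fractions
(ci, ca) and the Michaelis constant for CO₂ (Kc) and the compensation
point (Γ*) in µmol mol⁻¹, the Michaelis constant for O₂ (Ko) and the
O₂ partial pressure (Oi) in kPa, and assimilation rates in
µmol m⁻² s⁻¹.  Fick's law then yields An in µmol m⁻² s⁻¹ directly.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path


@dataclass(frozen=True)
class StomatalTargetParams:
    """Saturating-linear steady-state conductance target for one ca regime.

    G(I) = min(gmin + alpha * I, gmax), in mol m⁻² s⁻¹.
    """

    gmin: float  # mol m-2 s-1, conductance in darkness
    gmax: float  # mol m-2 s-1, conductance ceiling
    alpha: float  # mol umol-1, initial slope of G versus irradiance

    def __post_init__(self) -> None:
        if not (self.gmin <= self.gmax):
            raise ValueError(f"gmin ({self.gmin}) must not exceed gmax ({self.gmax})")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")


@dataclass(frozen=True)
class ModelParameters:
    """All constants and free parameters of the dynamic photosynthesis model.

    Defaults are the tomato parameter set: the three dynamically
    estimated parameters (ku, kd, c3), the a-priori calibrated FvCB
    constants (Vcmax, Rd, Jmax, theta, gamma), Arrhenius temperature
    scalings for Γ*, Ko and Kc, physical constants, and the per-ca
    steady-state stomatal target parameters.
    """

    # Dynamic (estimated) parameters
    ku: float = 179.4  # s, time constant for increases in g_tc
    kd: float = 830.3  # s, time constant for decreases in g_tc
    c3: float = 37.96  # -, scaling constant of the Kc Arrhenius response

    # FvCB / electron-transport parameters
    Vcmax: float = 99.25  # umol m-2 s-1, maximum carboxylation rate
    Rd: float = 1.0  # umol m-2 s-1, mitochondrial (day) respiration
    Jmax: float = 190.68  # umol m-2 s-1, maximum potential electron transport
    theta: float = 0.41  # -, initial slope of J versus I
    gamma: float = 0.9  # -, convexity of the non-rectangular hyperbola

    # Arrhenius scalings: X(Tl) = exp(c - dHa / (R1 * Tl))
    c1: float = 19.02  # -, scaling constant of Gamma* (umol mol-1)
    dHa1: float = 37.83  # kJ mol-1, activation energy of Gamma*
    c2: float = 12.3772  # -, scaling constant of Ko (kPa)
    dHa2: float = 23.72  # kJ mol-1, activation energy of Ko
    dHa3: float = 79.43  # kJ mol-1, activation energy of Kc (umol mol-1)
    R1: float = 0.008314  # kJ mol-1 K-1, gas constant (Arrhenius form)

    # Physical constants
    R: float = 8.314  # m3 Pa mol-1 K-1, gas constant (mass balance form)
    d: float = 0.0001  # m, effective leaf thickness
    Pa: float = 101325.0  # Pa, atmospheric pressure
    Oi: float = 21.0  # kPa, partial pressure of O2 in air

    # Steady-state stomatal conductance targets per ca regime (ppm keys)
    stomatal: dict[int, StomatalTargetParams] = field(
        default_factory=lambda: {
            400: StomatalTargetParams(gmin=0.1, gmax=0.325, alpha=0.00033),
            800: StomatalTargetParams(gmin=0.165, gmax=0.29, alpha=0.00017),
        }
    )

    def __post_init__(self) -> None:
        if self.ku <= 0 or self.kd <= 0:
            raise ValueError("time constants ku, kd must be positive")
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must be in (0, 1]")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        for name in ("dHa1", "dHa2", "dHa3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"activation energy {name} must be positive")
        if not self.stomatal:
            raise ValueError("at least one stomatal target regime is required")

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def stomatal_regime(self, ca: float) -> StomatalTargetParams:
        """Stomatal target parameters for the regime nearest to ``ca`` (ppm)."""
        if not math.isfinite(ca) or ca <= 0:
            raise ValueError(f"ca must be positive and finite, got {ca}")
        key = min(self.stomatal, key=lambda k: abs(k - ca))
        return self.stomatal[key]

    # -- configuration I/O ---------------------------------------------------

    @classmethod
    def from_dict(cls, cfg: dict) -> "ModelParameters":
        scalars: dict[str, float] = {}
        for section in ("dynamic", "fvcb", "temperature", "physical"):
            scalars.update(cfg.get(section, {}))
        # also accept a flat layout
        for key, val in cfg.items():
            if isinstance(val, (int, float)):
                scalars[key] = val
        known = {f.name for f in dataclasses.fields(cls)} - {"stomatal"}
        unknown = set(scalars) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        stomatal = {}
        for regime, triple in cfg.get("stomatal_target", {}).items():
            stomatal[int(regime)] = StomatalTargetParams(**triple)
        kwargs: dict = {k: float(v) for k, v in scalars.items()}
        if stomatal:
            kwargs["stomatal"] = stomatal
        return cls(**kwargs)

    @classmethod
    def from_toml(cls, path: str | Path) -> "ModelParameters":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    @classmethod
    def default(cls) -> "ModelParameters":
        """The packaged default parameter set (identical to the dataclass defaults)."""
        ref = resources.files("photodyn").joinpath("data/default_params.toml")
        with resources.as_file(ref) as path:
            return cls.from_toml(path)

    def to_dict(self) -> dict:
        return {
            "dynamic": {"ku": self.ku, "kd": self.kd, "c3": self.c3},
            "fvcb": {
                "Vcmax": self.Vcmax,
                "Rd": self.Rd,
                "Jmax": self.Jmax,
                "theta": self.theta,
                "gamma": self.gamma,
            },
            "temperature": {
                "c1": self.c1,
                "dHa1": self.dHa1,
                "c2": self.c2,
                "dHa2": self.dHa2,
                "dHa3": self.dHa3,
                "R1": self.R1,
            },
            "physical": {"R": self.R, "d": self.d, "Pa": self.Pa, "Oi": self.Oi},
            "stomatal_target": {
                str(k): dataclasses.asdict(v) for k, v in self.stomatal.items()
            },
        }

    def to_toml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(dumps_toml(self.to_dict()))


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def _toml_key(k: str) -> str:
    return k if k.isidentifier() else f'"{k}"'


def dumps_toml(cfg: dict) -> str:
    """Serialise a nested dict of scalars to TOML text (sections of scalars)."""
    sections: list[tuple[tuple[str, ...], dict]] = []

    def walk(path: tuple[str, ...], table: dict) -> None:
        scalars = {k: v for k, v in table.items() if not isinstance(v, dict)}
        if scalars or not path:
            sections.append((path, scalars))
        for k, v in table.items():
            if isinstance(v, dict):
                walk((*path, k), v)

    walk((), cfg)
    chunks: list[str] = []
    for path, scalars in sections:
        lines = [] if not path else [f"[{'.'.join(_toml_key(p) for p in path)}]"]
        lines += [f"{_toml_key(k)} = {_toml_value(v)}" for k, v in scalars.items()]
        if lines:
            chunks.append("\n".join(lines))
    return "\n\n".join(chunks) + "\n"
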