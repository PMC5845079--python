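"""Model constants and scenario configuration.

All physical quantities live in a single kg-um-min unit system:
lengths in micrometres, time in minutes, mass in kilograms.  Energy
densities (strain energy per unit volume) therefore carry units of
kg.um/min^2, elastic moduli kg/(um.min^2), and diffusivities um^2/min.

The default traction force is the *calibrated* value ``F_CALIBRATED``:
the force for which the derived strain-energy amplitude

    M0 = F^2 / (2 pi^2 E_s R^4)

reproduces the printed detection threshold 1.99e-54 kg.um/min^2 at
attenuation ratio lambda = E_s/E_c = 10, sensing range d_hat = 30 um and
cell radius R = 2.5 um.  The literature table's (10-25)e2 and the
figure-level F = 10 are selectable overrides but are mutually
inconsistent with that threshold and with the ~0.03 two-cell
equilibrium stimulus; the calibrated value is the only internally
consistent choice.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ModelParams",
    "ScenarioConfig",
    "ConfigError",
    "F_CALIBRATED",
    "M0_CALIBRATED",
    "strain_energy_amplitude",
    "load_params",
    "serialize_params",
    "echo_config",
]

#: Strain-energy amplitude that reproduces the printed detection
#: threshold 1.99e-54 = M0 * exp(-lambda * d_hat / R) with lambda=10,
#: d_hat=30 um, R=2.5 um (exponent -120).
M0_CALIBRATED = 1.99e-54 / math.exp(-120.0)

_R_DEFAULT = 2.5
_ES_DEFAULT = 5e-5

#: Calibrated traction force (kg.um/min^2): F* = sqrt(M0 * 2 pi^2 E_s R^4).
F_CALIBRATED = math.sqrt(M0_CALIBRATED * 2.0 * math.pi**2 * _ES_DEFAULT * _R_DEFAULT**4)


class ConfigError(ValueError):
    """Raised for unparsable or physically invalid configuration."""


def strain_energy_amplitude(F: float, E_s: float, R: float) -> float:
    """Strain-energy density amplitude M0 = F^2 / (2 pi^2 E_s R^4)."""
    if R <= 0 or E_s <= 0:
        raise ConfigError("R and E_s must be strictly positive")
    return F**2 / (2.0 * math.pi**2 * E_s * R**4)


@dataclass(frozen=True)
class ModelParams:
    """Physical constants of the cell-based model (kg-um-min units).

    Attributes
    ----------
    R : float
        Epithelial/cancer cell radius, um.
    R_t : float
        T-cell radius, um.
    F : float
        Cell traction force, kg.um/min^2 (default: calibrated value).
    E_s : float
        Substrate elastic modulus, kg/(um.min^2).
    E_c : float
        Cell elastic modulus, kg/(um.min^2).
    beta : float
        Mobility / chemotactic coefficient, 1/min.
    mu : float
        Cell-substrate friction coefficient, dimensionless.
    D : float
        Cell diffusivity (variance rate of the random walk), um^2/min.
    D_c : float
        Chemokine diffusivity, um^2/min.
    gamma : float
        Chemokine secretion rate per cancer cell, 1/min.
    """

    R: float = _R_DEFAULT
    R_t: float = 2.0
    F: float = F_CALIBRATED
    E_s: float = _ES_DEFAULT
    E_c: float = 0.5e-5
    beta: float = 1.0
    mu: float = 0.2
    D: float = 0.005
    D_c: float = 0.001
    gamma: float = 10.0

    def __post_init__(self) -> None:
        for name in ("R", "R_t", "F", "E_s", "E_c", "beta", "mu", "D", "D_c", "gamma"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise ConfigError(f"parameter {name!r} is not a finite number: {value!r}")
            if value <= 0:
                raise ConfigError(f"parameter {name!r} must be strictly positive, got {value}")

    @property
    def M0(self) -> float:
        """Derived strain-energy amplitude, kg.um/min^2."""
        return strain_energy_amplitude(self.F, self.E_s, self.R)

    @property
    def lambda_att(self) -> float:
        """Signal attenuation ratio lambda = E_s / E_c (dimensionless)."""
        return self.E_s / self.E_c

    @property
    def alpha(self) -> float:
        """Mobility constant alpha = beta R^3 / (mu F), um^3.min/kg-equivalent."""
        return self.beta * self.R**3 / (self.mu * self.F)


_IMMUNITY_LEVELS = ("strong", "weak", "none")


@dataclass
class ScenarioConfig:
    """Scenario switches: geometry, immunity, anisotropy and run control."""

    islet_radius: float = 35.0          # um, inner boundary of the stroma
    stroma_thickness: float = 15.0      # um
    k: float = 0.0                      # radial attenuation constant
    immunity: str = "strong"            # strong | weak | none
    n_tcells_weak: int = 10             # N_w; N_s = 2 N_w when defaulted
    n_tcells_strong: int | None = None  # defaults to 2 * n_tcells_weak
    t_end: float = 400.0                # min
    dt_max: float = 0.1                 # min
    dt_min: float = 0.02                # min, clock floor (caps guard stability)
    seed: int = 0
    packing_factor: float = 0.9         # lattice spacing / (2R)
    division_cap_epithelial: int = 50   # somatic division budget, in [50, 100]
    totals_include_tcells: bool = True  # denominator of the cancer fraction
    d_hat: float = 30.0                 # um, sensing range / neighbour cutoff
    epsilon: float = 0.0                # runtime detection cutoff (default 0)
    tcell_death_prob: float = 0.2       # T-cell death risk per engulfment
    seed_cancer_time: float | None = None  # optional deterministic first mutation
    snapshot_times: tuple[float, ...] = (0, 10, 60, 120, 150, 180, 200, 300, 400)
    early_exit: bool = False            # stop at absorbing population states

    def __post_init__(self) -> None:
        if self.immunity not in _IMMUNITY_LEVELS:
            raise ConfigError(f"immunity must be one of {_IMMUNITY_LEVELS}, got {self.immunity!r}")
        if self.k < 0:
            raise ConfigError(f"k must be non-negative, got {self.k}")
        for name in ("islet_radius", "stroma_thickness", "t_end", "dt_max", "packing_factor"):
            value = getattr(self, name)
            if name == "t_end":
                if value < 0:
                    raise ConfigError("t_end must be non-negative")
            elif value <= 0:
                raise ConfigError(f"{name} must be strictly positive, got {value}")
        if self.n_tcells_strong is None:
            self.n_tcells_strong = 2 * self.n_tcells_weak
        if self.n_tcells_weak < 0 or self.n_tcells_strong < 0:
            raise ConfigError("T-cell counts must be non-negative")

    @property
    def outer_radius(self) -> float:
        """Outer boundary of the stromal annulus, um."""
        return self.islet_radius + self.stroma_thickness

    @property
    def n_tcells(self) -> int:
        """Number of T cells recruited under the configured immunity."""
        if self.immunity == "none":
            return 0
        if self.immunity == "strong":
            return int(self.n_tcells_strong)
        return int(self.n_tcells_weak)


_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}
_SCENARIO_FIELDS = {f.name for f in dataclasses.fields(ScenarioConfig)}


def load_params(source: str | Path | Mapping[str, Any] | None = None,
                ) -> tuple[ModelParams, ScenarioConfig]:
    """Load (ModelParams, ScenarioConfig) from YAML text, a file path or a mapping.

    Unknown keys raise :class:`ConfigError` naming the field; missing keys
    take the documented defaults.  An empty source yields all defaults.
    """
    if source is None:
        data: dict[str, Any] = {}
    elif isinstance(source, Mapping):
        data = dict(source)
    else:
        if isinstance(source, Path):
            text = source.read_text()
        elif "\n" not in source and Path(source).is_file():
            text = Path(source).read_text()
        else:
            text = source
        try:
            parsed = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"could not parse configuration: {exc}") from exc
        data = parsed or {}
        if not isinstance(data, dict):
            raise ConfigError("configuration must be a mapping of field names to values")

    unknown = set(data) - _PARAM_FIELDS - _SCENARIO_FIELDS
    if unknown:
        raise ConfigError(f"unknown configuration field(s): {sorted(unknown)}")

    pkw = {k: v for k, v in data.items() if k in _PARAM_FIELDS}
    skw = {k: v for k, v in data.items() if k in _SCENARIO_FIELDS}
    if "snapshot_times" in skw:
        skw["snapshot_times"] = tuple(skw["snapshot_times"])
    return ModelParams(**pkw), ScenarioConfig(**skw)


def serialize_params(params: ModelParams, scenario: ScenarioConfig) -> dict[str, Any]:
    """Effective configuration as a plain dict, including derived fields."""
    out: dict[str, Any] = dataclasses.asdict(params)
    out.update(dataclasses.asdict(scenario))
    out["snapshot_times"] = list(scenario.snapshot_times)
    out["M0"] = params.M0
    out["lambda_att"] = params.lambda_att
    out["alpha"] = params.alpha
    return out


def echo_config(params: ModelParams, scenario: ScenarioConfig, outdir: str | Path) -> Path:
    """Write the full effective configuration as JSON into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "config.json"
    path.write_text(json.dumps(serialize_params(params, scenario), indent=2, sort_keys=True))
    return path
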