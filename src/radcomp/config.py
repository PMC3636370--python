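"""Domain types, configuration I/O and the bundled toy parameterization.

A model configuration describes one or more well-mixed coastal basin boxes,
the functional groups of the food web living in them, the diet matrix that
connects consumers to prey, the radionuclides to be traced, optional
parameter probability distributions for Monte Carlo runs, and a constant
point-source release term.

Units are fixed globally: time in years, activity in Bq, volume in m^3,
biomass in kgC.  Water concentrations are Bq m^-3, biota concentrations
Bq kgC^-1, so concentration ratios come out in m^3 kgC^-1.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

SCHEMA_VERSION = 1

SHAPES = ("sphere", "cylinder", "flat")
HABITATS = ("pelagic", "benthic", "infauna")
MODES = ("K", "Dlite")
SOURCE_MODES = ("water", "porewater")
DISTRIBUTIONS = ("lognormal", "normal", "uniform", "triangular", "fixed")

#: Abiotic state variables carried alongside the biotic groups.
ABIOTIC_STATE_VARIABLES = ("DIC", "PM")


class ConfigError(ValueError):
    """Raised when a configuration file violates the schema or an invariant."""


@dataclass
class Radionuclide:
    """Element-specific transport parameters.

    ``kd_organic`` / ``kd_inorganic`` are equilibrium partition coefficients
    to organic and inorganic particles (m^3 per kg dry particle).
    ``surface_affinity`` (m) is the volume of water whose dissolved activity
    is equilibrated per m^2 of organism surface; multiplied by a group's
    specific surface it yields the per-group adsorption coefficient.
    ``assimilation_efficiency`` is the fraction of ingested tracer retained
    by a consumer, either one value for all consumers or a mapping by group
    name.  ``decay_constant`` (y^-1) defaults to 0: for the long-lived
    nuclides this model targets, decay is negligible over the simulated
    horizon and is excluded unless explicitly enabled.
    """

    name: str
    kd_organic: float
    kd_inorganic: float
    surface_affinity: float
    assimilation_efficiency: float | dict[str, float] = 0.0
    decay_constant: float = 0.0

    def ae_for(self, group: str) -> float:
        if isinstance(self.assimilation_efficiency, Mapping):
            return float(self.assimilation_efficiency.get(group, 0.0))
        return float(self.assimilation_efficiency)


@dataclass
class FunctionalGroup:
    """One biotic compartment of the food web.

    ``carbon_density`` (kgC per m^3 of biovolume) converts the geometric
    surface-to-volume ratio to a surface per unit carbon;
    ``gill_area_specific`` (m^2 kgC^-1) adds the gill surface for fish.
    ``ingestion_rate`` and ``respiration_rate`` are specific carbon rates
    (y^-1); producers have ingestion 0 and consumers have their respiration
    computed as the balancing residual of the annual carbon budget.
    """

    name: str
    biomass: float
    carbon_fraction_fw: float
    carbon_density: float
    shape: str
    characteristic_dimension: float
    gill_area_specific: float = 0.0
    mortality_rate: float = 0.0
    egestion_fraction: float = 0.0
    habitat: str = "pelagic"
    ingestion_rate: float = 0.0
    respiration_rate: float = 0.0


@dataclass
class Basin:
    """A well-mixed basin box: water column plus a two-layer sediment.

    ``water_retention_time`` (y) expresses the basin's hydrodynamics as a
    bulk water turnover.  ``pm_concentration`` is suspended particulate
    matter (kg dry m^-3) split into organic/inorganic by
    ``pm_organic_fraction``.  The sediment has an active layer (thickness
    ``active_layer_depth``, porosity ``porosity``, dry solids density
    ``sediment_dry_density`` kg m^-3 of layer) exchanging with pore water
    and the water column, and a consolidated deep layer fed by burial.
    """

    name: str
    surface_area: float
    mean_depth: float
    water_retention_time: float
    volume: float | None = None
    pm_concentration: float = 0.0
    pm_organic_fraction: float = 0.5
    sedimentation_velocity: float = 0.0
    active_layer_depth: float = 0.0
    burial_rate: float = 0.0
    resuspension_rate: float = 0.0
    porewater_exchange_rate: float = 0.0
    porosity: float = 0.8
    sediment_dry_density: float = 250.0
    pm_carbon_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.volume is None:
            self.volume = self.surface_area * self.mean_depth

    @property
    def porewater_volume(self) -> float:
        return self.surface_area * self.active_layer_depth * self.porosity

    @property
    def sediment_solid_mass(self) -> float:
        return self.sediment_dry_density * self.surface_area * self.active_layer_depth

    @property
    def pm_mass(self) -> float:
        """Total suspended dry mass in the water column (kg)."""
        return self.pm_concentration * self.volume

    @property
    def pm_carbon_stock(self) -> float:
        """Carbon stock of the organic PM pool (kgC)."""
        return self.pm_mass * self.pm_organic_fraction * self.pm_carbon_fraction


@dataclass
class ParameterPDF:
    """A probability distribution attached to one scalar config parameter.

    ``target`` is a dotted path into the configuration; list elements are
    addressed by name, e.g. ``radionuclides.Cs135.kd_organic`` or
    ``groups.fish.biomass``.  ``parameters`` are distribution-specific:
    lognormal {median, gsd}, normal {mean, sd}, uniform {low, high},
    triangular {left, mode, right}, fixed {value}.  Optional ``bounds``
    truncate by rejection sampling.
    """

    target: str
    distribution: str
    parameters: dict[str, float]
    bounds: list[float] | None = None


@dataclass
class SourceTerm:
    """Constant release: ``rate`` Bq y^-1 into the water column (K mode)
    or the sediment pore water (D mode), optionally split over several
    basins via ``fractions`` (name -> fraction, summing to 1)."""

    rate: float
    mode: str = "water"
    basin: str | None = None
    fractions: dict[str, float] | None = None


@dataclass
class Exchange:
    """Directed water flow (m^3 y^-1) between two basin boxes; the special
    name ``boundary`` denotes the open sea (clean inflow, export sink)."""

    source: str
    target: str
    flow: float


@dataclass
class SimulationSettings:
    duration: float = 100.0
    output_step: float = 1.0


@dataclass
class AdsorptionSettings:
    """Kinetics of surface adsorption: first-order exchange with desorption
    rate ``k_off`` (y^-1) and attachment set by the equilibrium ratio.
    ``instantaneous`` switches to a quasi-instantaneous stiff limit."""

    k_off: float = 10.0
    instantaneous: bool = False


@dataclass
class CRSettings:
    """``water_basis``: 'dissolved' divides by the dissolved concentration
    only; 'total' includes PM-adsorbed activity in the denominator."""

    water_basis: str = "dissolved"


@dataclass
class ModelConfig:
    basins: list[Basin]
    groups: list[FunctionalGroup]
    diet: dict[str, dict[str, float]]
    radionuclides: list[Radionuclide]
    source: SourceTerm
    exchanges: list[Exchange] = field(default_factory=list)
    pdfs: list[ParameterPDF] = field(default_factory=list)
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    adsorption: AdsorptionSettings = field(default_factory=AdsorptionSettings)
    cr: CRSettings = field(default_factory=CRSettings)
    mode: str = "K"
    fixture: bool = False
    schema_version: int = SCHEMA_VERSION

    @property
    def basin(self) -> Basin:
        """The single (or first) basin."""
        return self.basins[0]

    @property
    def state_variables(self) -> list[str]:
        """Biotic and abiotic state variables besides the sediment layers."""
        return [g.name for g in self.groups] + list(ABIOTIC_STATE_VARIABLES)

    def group(self, name: str) -> FunctionalGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)

    def radionuclide(self, name: str) -> Radionuclide:
        for r in self.radionuclides:
            if r.name == name:
                return r
        raise KeyError(name)

    def copy(self) -> "ModelConfig":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# validation


def validate(config: ModelConfig) -> list[str]:
    """Check every type invariant; return human-readable violations.

    Violations are data, not exceptions: an empty list means the config is
    exactly the set accepted by :func:`load_config`.
    """
    v: list[str] = []

    names = [g.name for g in config.groups]
    if len(set(names)) != len(names):
        v.append("groups: names must be unique")
    rn_names = [r.name for r in config.radionuclides]
    if len(set(rn_names)) != len(rn_names):
        v.append("radionuclides: names must be unique")

    for b in config.basins:
        if b.surface_area <= 0:
            v.append(f"basin {b.name}: surface_area must be > 0")
        if b.mean_depth <= 0:
            v.append(f"basin {b.name}: mean_depth must be > 0")
        elif b.volume is not None and abs(
            b.volume - b.surface_area * b.mean_depth
        ) > 1e-9 * max(b.volume, 1.0):
            v.append(f"basin {b.name}: volume must equal surface_area * mean_depth")
        if b.water_retention_time <= 0:
            v.append(f"basin {b.name}: water_retention_time must be > 0")
        for rate in (
            "pm_concentration",
            "sedimentation_velocity",
            "active_layer_depth",
            "burial_rate",
            "resuspension_rate",
            "porewater_exchange_rate",
        ):
            if getattr(b, rate) < 0:
                v.append(f"basin {b.name}: {rate} must be >= 0")
        if not 0.0 <= b.pm_organic_fraction <= 1.0:
            v.append(f"basin {b.name}: pm_organic_fraction must be in [0, 1]")
        if not 0.0 < b.porosity <= 1.0:
            v.append(f"basin {b.name}: porosity must be in (0, 1]")

    for g in config.groups:
        if g.biomass <= 0:
            v.append(f"group {g.name}: biomass must be > 0")
        if not 0.0 < g.carbon_fraction_fw <= 1.0:
            v.append(f"group {g.name}: carbon_fraction_fw must be in (0, 1]")
        if g.carbon_density <= 0:
            v.append(f"group {g.name}: carbon_density must be > 0")
        if g.shape not in SHAPES:
            v.append(f"group {g.name}: shape must be one of {SHAPES}")
        if g.characteristic_dimension <= 0:
            v.append(f"group {g.name}: characteristic_dimension must be > 0")
        if not 0.0 <= g.egestion_fraction <= 1.0:
            v.append(f"group {g.name}: egestion_fraction must be in [0, 1]")
        if g.habitat not in HABITATS:
            v.append(f"group {g.name}: habitat must be one of {HABITATS}")
        if g.gill_area_specific < 0:
            v.append(f"group {g.name}: gill_area_specific must be >= 0")
        if g.mortality_rate < 0 or g.ingestion_rate < 0 or g.respiration_rate < 0:
            v.append(f"group {g.name}: rates must be >= 0")

    for r in config.radionuclides:
        if r.kd_organic < 0 or r.kd_inorganic < 0:
            v.append(f"radionuclide {r.name}: kd values must be >= 0")
        if r.surface_affinity < 0:
            v.append(f"radionuclide {r.name}: surface_affinity must be >= 0")
        if r.decay_constant < 0:
            v.append(f"radionuclide {r.name}: decay_constant must be >= 0")
        aes = (
            r.assimilation_efficiency.values()
            if isinstance(r.assimilation_efficiency, Mapping)
            else [r.assimilation_efficiency]
        )
        for ae in aes:
            if not 0.0 <= ae <= 1.0:
                v.append(
                    f"radionuclide {r.name}: assimilation_efficiency must be in [0, 1]"
                )
                break

    valid_prey = set(names) | {"PM"}
    for g in config.groups:
        row = config.diet.get(g.name, {})
        total = sum(row.values())
        if g.ingestion_rate > 0:
            if abs(total - 1.0) > 1e-9:
                v.append(f"diet row for consumer {g.name} sums to {total:g}, not 1")
        elif total != 0:
            v.append(f"diet row for non-consumer {g.name} must sum to 0")
        for prey, frac in row.items():
            if prey not in valid_prey:
                v.append(f"diet row for {g.name}: unknown prey {prey!r}")
            if frac < 0:
                v.append(f"diet row for {g.name}: negative fraction for {prey}")

    if config.source.rate <= 0:
        v.append("source: rate must be > 0")
    if config.source.mode not in SOURCE_MODES:
        v.append(f"source: mode must be one of {SOURCE_MODES}")
    if config.source.fractions is not None:
        basin_names = {b.name for b in config.basins}
        total = sum(config.source.fractions.values())
        if abs(total - 1.0) > 1e-9:
            v.append(f"source: fractions sum to {total:g}, not 1")
        for name in config.source.fractions:
            if name not in basin_names:
                v.append(f"source: unknown basin {name!r} in fractions")
    if config.mode not in MODES:
        v.append(f"mode must be one of {MODES}")
    if config.cr.water_basis not in ("dissolved", "total"):
        v.append("cr.water_basis must be 'dissolved' or 'total'")
    if config.adsorption.k_off <= 0:
        v.append("adsorption.k_off must be > 0")

    for p in config.pdfs:
        if p.distribution not in DISTRIBUTIONS:
            v.append(f"pdf {p.target}: distribution must be one of {DISTRIBUTIONS}")

    # Assimilated tracer is only released on death or consumption, so a
    # consumer with neither predators nor mortality accumulates without
    # bound at constant uptake.  Pure surface adsorbers desorb reversibly
    # and are exempt.
    predated = {prey for row in config.diet.values() for prey in row}
    for g in config.groups:
        if g.ingestion_rate > 0 and g.name not in predated and g.mortality_rate == 0:
            v.append(
                f"group {g.name}: no loss pathway (no predators, mortality 0); "
                "assimilated tracer would accumulate without bound"
            )

    return v


# ---------------------------------------------------------------------------
# YAML I/O


def _to_dict(config: ModelConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    # do not persist derived Basin.volume redundantly? keep it: round-trip equality
    return d


def _basin_from(d: dict[str, Any]) -> Basin:
    return Basin(**d)


def _config_from(d: dict[str, Any]) -> ModelConfig:
    try:
        return ModelConfig(
            basins=[_basin_from(b) for b in d["basins"]],
            groups=[FunctionalGroup(**g) for g in d["groups"]],
            diet={k: dict(row) for k, row in d.get("diet", {}).items()},
            radionuclides=[Radionuclide(**r) for r in d["radionuclides"]],
            source=SourceTerm(**d["source"]),
            exchanges=[Exchange(**e) for e in d.get("exchanges", [])],
            pdfs=[ParameterPDF(**p) for p in d.get("pdfs", [])],
            simulation=SimulationSettings(**d.get("simulation", {})),
            adsorption=AdsorptionSettings(**d.get("adsorption", {})),
            cr=CRSettings(**d.get("cr", {})),
            mode=d.get("mode", "K"),
            fixture=d.get("fixture", False),
            schema_version=d["schema_version"],
        )
    except KeyError as exc:
        raise ConfigError(f"missing required config field: {exc.args[0]}") from exc
    except TypeError as exc:
        raise ConfigError(f"schema violation: {exc}") from exc


def load_config(path: str | Path) -> ModelConfig:
    """Read and fully validate a YAML model configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: not a mapping")
    if "schema_version" not in raw:
        raise ConfigError(f"{path}: schema_version field is mandatory")
    if raw["schema_version"] != SCHEMA_VERSION:
        raise ConfigError(
            f"{path}: unsupported schema_version {raw['schema_version']}"
        )
    config = _config_from(raw)
    violations = validate(config)
    if violations:
        raise ConfigError("; ".join(violations))
    return config


def write_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration as YAML such that load(write(c)) == c."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# toy fixture


def make_toy_fixture(seed: int = 1) -> ModelConfig:
    """A Forsmark-like toy parameterization of a shallow coastal basin.

    The structure is fixed: one basin of 11.5 km^2 surface area, the eight
    state variables of the compartment food web (DIC, phytoplankton,
    benthophytes, zooplankton, fish, grazers, benthos, PM) plus the
    two-layer sediment, and the radionuclides Cs-135, Ni-59 and Th-230 with
    Th partitioning ten times stronger than Cs and Ni and zero Th
    assimilation.  The source releases 1 Bq y^-1.

    All other numeric values (biomasses, rates, Kd magnitudes) are
    plausible placeholder choices for a Baltic coastal bay, flagged
    ``fixture: true`` — they are illustrative, not site ground truth.
    The seed jitters biomasses and biological rates by +-10% so different
    seeds give different, still balanced, webs; equal seeds give identical
    configs.
    """
    rng = np.random.default_rng(seed)

    def j() -> float:
        # modest multiplicative jitter, kept away from balance-breaking sizes
        return float(rng.uniform(0.9, 1.1))

    basin = Basin(
        name="basin116",
        surface_area=11.5e6,  # m^2
        mean_depth=2.5,
        water_retention_time=0.05,  # ~18 days
        pm_concentration=2.0e-3,
        pm_organic_fraction=0.3,
        sedimentation_velocity=50.0,
        active_layer_depth=0.05,
        burial_rate=0.02,
        resuspension_rate=2.0,
        porewater_exchange_rate=5.0,
    )

    groups = [
        FunctionalGroup(
            name="phytoplankton",
            biomass=1.15e4 * j(),
            carbon_fraction_fw=0.05,
            carbon_density=120.0,
            shape="sphere",
            characteristic_dimension=5e-6,
            mortality_rate=20.0 * j(),
            habitat="pelagic",
            respiration_rate=30.0 * j(),
        ),
        FunctionalGroup(
            name="benthophytes",
            biomass=2.3e5 * j(),
            carbon_fraction_fw=0.08,
            carbon_density=40.0,
            shape="flat",
            characteristic_dimension=3e-4,
            mortality_rate=1.5 * j(),
            habitat="benthic",
            respiration_rate=2.0 * j(),
        ),
        FunctionalGroup(
            name="zooplankton",
            biomass=5.75e3 * j(),
            carbon_fraction_fw=0.06,
            carbon_density=100.0,
            shape="cylinder",
            characteristic_dimension=2.5e-4,
            mortality_rate=5.0 * j(),
            egestion_fraction=0.3,
            habitat="pelagic",
            ingestion_rate=25.0 * j(),
        ),
        FunctionalGroup(
            name="fish",
            biomass=1.15e4 * j(),
            carbon_fraction_fw=0.12,
            carbon_density=150.0,
            shape="cylinder",
            characteristic_dimension=1.5e-2,
            gill_area_specific=30.0,
            mortality_rate=0.4 * j(),
            egestion_fraction=0.25,
            habitat="pelagic",
            ingestion_rate=3.0 * j(),
        ),
        FunctionalGroup(
            name="grazers",
            biomass=2.3e4 * j(),
            carbon_fraction_fw=0.07,
            carbon_density=120.0,
            shape="cylinder",
            characteristic_dimension=2e-3,
            mortality_rate=1.0 * j(),
            egestion_fraction=0.4,
            habitat="benthic",
            ingestion_rate=8.0 * j(),
        ),
        FunctionalGroup(
            name="benthos",
            biomass=1.15e5 * j(),
            carbon_fraction_fw=0.06,
            carbon_density=130.0,
            shape="cylinder",
            characteristic_dimension=4e-3,
            mortality_rate=0.8 * j(),
            egestion_fraction=0.4,
            habitat="infauna",
            ingestion_rate=6.0 * j(),
        ),
    ]

    diet = {
        "zooplankton": {"phytoplankton": 0.9, "PM": 0.1},
        "fish": {"zooplankton": 0.7, "benthos": 0.3},
        "grazers": {"benthophytes": 1.0},
        "benthos": {"phytoplankton": 0.4, "PM": 0.6},
    }

    # Th is strongly particle reactive: Kd ten times the Cs/Ni values, and
    # it is not assimilated into tissue (surface adsorption only).
    radionuclides = [
        Radionuclide(
            name="Cs135",
            kd_organic=1.0,
            kd_inorganic=0.5,
            surface_affinity=1.0e-4,
            assimilation_efficiency=0.5,
        ),
        Radionuclide(
            name="Ni59",
            kd_organic=1.0,
            kd_inorganic=0.5,
            surface_affinity=0.8e-4,
            assimilation_efficiency=0.3,
        ),
        Radionuclide(
            name="Th230",
            kd_organic=10.0,
            kd_inorganic=5.0,
            surface_affinity=1.0e-3,
            assimilation_efficiency=0.0,
        ),
    ]

    pdfs = [
        ParameterPDF(
            target="radionuclides.Cs135.kd_organic",
            distribution="lognormal",
            parameters={"median": 1.0, "gsd": 2.0},
        ),
    ]

    config = ModelConfig(
        basins=[basin],
        groups=groups,
        diet=diet,
        radionuclides=radionuclides,
        source=SourceTerm(rate=1.0, mode="water", basin="basin116"),
        pdfs=pdfs,
        simulation=SimulationSettings(duration=100.0, output_step=1.0),
        mode="K",
        fixture=True,
    )
    violations = validate(config)
    if violations:  # pragma: no cover - fixture must always be valid
        raise ConfigError("toy fixture invalid: " + "; ".join(violations))
    return config


def make_adsorption_only_config(
    kd_organic: float = 1.0,
    surface_affinity: float = 1.0e-4,
    retention_time: float = 0.1,
    volume: float = 1.0e7,
) -> ModelConfig:
    """A minimal one-basin, one-group system with surface adsorption as the
    only uptake pathway (no PM, no sediment, no trophic transfer).

    At steady state the concentration ratio of the single group equals its
    adsorption coefficient exactly, which makes this configuration the
    closed-form reference for equilibrium and ensemble checks.
    """
    depth = 2.0
    area = volume / depth
    basin = Basin(
        name="box",
        surface_area=area,
        mean_depth=depth,
        water_retention_time=retention_time,
    )
    group = FunctionalGroup(
        name="plankton",
        biomass=1.0e3,
        carbon_fraction_fw=0.05,
        carbon_density=120.0,
        shape="sphere",
        characteristic_dimension=5e-6,
        mortality_rate=0.0,
        habitat="pelagic",
    )
    rn = Radionuclide(
        name="tracer",
        kd_organic=kd_organic,
        kd_inorganic=kd_organic / 2.0,
        surface_affinity=surface_affinity,
    )
    return ModelConfig(
        basins=[basin],
        groups=[group],
        diet={},
        radionuclides=[rn],
        source=SourceTerm(rate=1.0, mode="water", basin="box"),
        fixture=True,
    )
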