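"""Assembly of the linear radionuclide transport system.

All tracer processes are first order in the compartment activities, so a
scenario reduces to

    dA/dt = M A + s

with a Metzler matrix ``M`` (non-negative off-diagonals, guaranteeing
non-negative trajectories) over the live compartments -- dissolved water,
PM-adsorbed (organic and inorganic), each biotic group, the active
sediment layer and the pore water, per basin box -- plus terminal
accumulator rows for water exported across the open boundary and for
activity buried into the consolidated deep sediment.

Processes encoded per box:

1. constant source into the water column (K mode) or the sediment pore
   water (D mode);
2. advective export: water turnover ``1/retention_time`` for an isolated
   box, or the explicit exchange flows of a box network, applied to the
   dissolved and PM-adsorbed phases alike (suspended particles travel
   with the water);
3. kinetic adsorption-desorption between water and organic/inorganic PM
   with equilibrium ratio Kd x particle load;
4. kinetic adsorption onto biota surfaces with equilibrium
   ``group_kd x biomass / volume`` (infauna equilibrate with pore water);
5. trophic transfer at the carbon ingestion rates: a fraction AE
   (assimilation efficiency) of the tracer removed from the prey enters
   the consumer, the rest is egested to organic PM;
6. mortality and predation move tracer out of organisms at the carbon
   turnover rates (living tissue retains tracer; K mode adds a continuous
   feces efflux at the carbon egestion rate);
7. PM settling into the active sediment layer, resuspension back, burial
   to the deep layer, pore-water/active-layer partitioning via a
   particle-load-weighted sediment Kd, and pore-water/water-column
   exchange;
8. optional radioactive decay on every live compartment (off by default).

Rate coefficients are per year; activities in Bq.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .config import Basin, ConfigError, ModelConfig, Radionuclide
from .foodweb import PM, CarbonFluxMatrix, build_fluxes
from .geometry import group_kd

#: desorption rate used for the quasi-instantaneous equilibrium limit
INSTANTANEOUS_K_OFF = 1.0e5

BOUNDARY = "boundary"
EXPORTED = "exported"
DEEP_SUFFIX = "sediment_deep"


class AssemblyError(ConfigError):
    """Raised when a tracer system cannot be built from the configuration."""


@dataclass
class TracerState:
    """Activity (Bq) per compartment, live compartments then sinks."""

    values: np.ndarray
    compartments: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compartments),):
            raise ValueError("state dimension does not match compartment list")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.compartments.index(name)])

    @property
    def exported(self) -> float:
        return self[EXPORTED] if EXPORTED in self.compartments else 0.0

    @property
    def buried(self) -> float:
        return float(
            sum(
                self.values[i]
                for i, c in enumerate(self.compartments)
                if c.endswith(DEEP_SUFFIX)
            )
        )

    @property
    def total(self) -> float:
        """Inventory plus cumulative sinks (Bq)."""
        return float(self.values.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.compartments, name="activity_Bq")


@dataclass
class GroupInfo:
    """Per-box bookkeeping needed to read concentrations back out."""

    name: str
    box: str
    compartment: str
    biomass: float
    habitat: str
    kd: float
    carbon_fraction_fw: float


@dataclass
class TracerSystem:
    """Transfer matrix + source vector over the live compartments.

    ``matrix`` excludes the terminal accumulators; flows into them are in
    ``sink_matrix`` (one row per sink).  ``extended_matrix`` stacks both
    so the full state (live + sinks) can be integrated as one linear ODE.
    """

    matrix: np.ndarray
    source: np.ndarray
    sink_matrix: np.ndarray
    compartments: list[str]
    sinks: list[str]
    groups: list[GroupInfo] = field(default_factory=list)
    water: dict[str, str] = field(default_factory=dict)  # box -> water compartment
    porewater: dict[str, str] = field(default_factory=dict)
    pm: dict[str, tuple[str | None, str | None]] = field(default_factory=dict)
    volumes: dict[str, float] = field(default_factory=dict)
    porewater_volumes: dict[str, float] = field(default_factory=dict)
    radionuclide: str = ""
    mode: str = "K"
    decay_constant: float = 0.0
    water_basis: str = "dissolved"

    @property
    def n(self) -> int:
        return len(self.compartments)

    @property
    def all_compartments(self) -> list[str]:
        return self.compartments + self.sinks

    @property
    def conservative(self) -> bool:
        return self.decay_constant == 0.0

    def index(self, name: str) -> int:
        return self.compartments.index(name)

    @property
    def extended_matrix(self) -> np.ndarray:
        n, k = self.n, len(self.sinks)
        ext = np.zeros((n + k, n + k))
        ext[:n, :n] = self.matrix
        ext[n:, :n] = self.sink_matrix
        return ext

    @property
    def extended_source(self) -> np.ndarray:
        return np.concatenate([self.source, np.zeros(len(self.sinks))])

    def zero_state(self) -> TracerState:
        return TracerState(
            np.zeros(self.n + len(self.sinks)), self.all_compartments
        )

    def total_source_rate(self) -> float:
        return float(self.source.sum())

    def to_csv(self, path: str | Path) -> None:
        """Audit export: every nonzero rate (y^-1) and the source vector."""
        rows = []
        ext = self.extended_matrix
        names = self.all_compartments
        for i, dst in enumerate(names):
            for j, src in enumerate(names):
                if i != j and ext[i, j] != 0.0:
                    rows.append(
                        {"from": src, "to": dst, "rate_per_year": ext[i, j]}
                    )
        for j, src in enumerate(self.compartments):
            if self.source[j] != 0.0:
                rows.append(
                    {"from": "source", "to": src, "rate_per_year": self.source[j]}
                )
        pd.DataFrame(rows).to_csv(path, index=False)


def rhs(system: TracerSystem, state: TracerState | np.ndarray) -> np.ndarray:
    """Time derivative dA/dt = M A + s (Bq y^-1) over live + sink rows."""
    values = state.values if isinstance(state, TracerState) else np.asarray(state)
    n_ext = system.n + len(system.sinks)
    if values.shape != (n_ext,):
        raise ValueError(
            f"state dimension {values.shape} does not match system ({n_ext},)"
        )
    return system.extended_matrix @ values + system.extended_source


# ---------------------------------------------------------------------------
# assembly


class _Builder:
    def __init__(self, compartments: list[str], sinks: list[str]):
        self.names = compartments
        self.sinks = sinks
        self.idx = {c: i for i, c in enumerate(compartments)}
        self.sidx = {s: i for i, s in enumerate(sinks)}
        n = len(compartments)
        self.M = np.zeros((n, n))
        self.S = np.zeros((len(sinks), n))
        self.s = np.zeros(n)

    def add(self, rate: float, src: str, dst: str) -> None:
        if rate == 0.0:
            return
        if rate < 0:
            raise AssemblyError(f"negative rate {rate} for {src} -> {dst}")
        i, j = self.idx[dst], self.idx[src]
        if i == j:
            return  # self-loop: no net transfer
        self.M[i, j] += rate
        self.M[j, j] -= rate

    def add_sink(self, rate: float, src: str, sink: str) -> None:
        if rate == 0.0:
            return
        if rate < 0:
            raise AssemblyError(f"negative rate {rate} for {src} -> {sink}")
        j = self.idx[src]
        self.S[self.sidx[sink], j] += rate
        self.M[j, j] -= rate


def _source_fractions(config: ModelConfig) -> dict[str, float]:
    if config.source.fractions is not None:
        total = sum(config.source.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise AssemblyError(
                f"source fractions sum to {total:g}, not 1"
            )
        return dict(config.source.fractions)
    name = config.source.basin or config.basins[0].name
    return {name: 1.0}


def validate_water_balance(config: ModelConfig, rtol: float = 1e-6) -> None:
    """Check per-box inflow == outflow for an explicit exchange network."""
    if not config.exchanges:
        return
    inflow: dict[str, float] = {b.name: 0.0 for b in config.basins}
    outflow: dict[str, float] = {b.name: 0.0 for b in config.basins}
    known = set(inflow) | {BOUNDARY}
    for e in config.exchanges:
        if e.source not in known or e.target not in known:
            raise AssemblyError(f"exchange references unknown box: {e}")
        if e.flow < 0:
            raise AssemblyError(f"exchange flow must be >= 0: {e}")
        if e.target != BOUNDARY:
            inflow[e.target] += e.flow
        if e.source != BOUNDARY:
            outflow[e.source] += e.flow
    bad = [
        name
        for name in inflow
        if abs(inflow[name] - outflow[name])
        > rtol * max(inflow[name], outflow[name], 1.0)
    ]
    if bad:
        raise AssemblyError(
            "water budget unbalanced in boxes: "
            + ", ".join(
                f"{n} (in {inflow[n]:.6g}, out {outflow[n]:.6g})" for n in bad
            )
        )


def assemble(
    config: ModelConfig,
    radionuclide: str | Radionuclide,
    mode: str | None = None,
    fluxes: CarbonFluxMatrix | None = None,
) -> TracerSystem:
    """Build the tracer transport system for one radionuclide.

    ``mode`` "K" releases to the water column and adds the feces efflux;
    "Dlite" releases to pore water without it.  When omitted, the config's
    own mode is used.  Compartments that can never hold activity (no
    inflow and no source) are pruned, so a bare water-box scenario yields
    the one-dimensional system M = [-1/tau], s = [rate].
    """
    rn = (
        radionuclide
        if isinstance(radionuclide, Radionuclide)
        else config.radionuclide(radionuclide)
    )
    mode = mode or config.mode
    if mode not in ("K", "Dlite"):
        raise AssemblyError(f"unknown mode {mode!r}")
    source_target = "water" if mode == "K" else "porewater"

    if fluxes is None:
        fluxes = build_fluxes(config)
    validate_water_balance(config)

    boxes = config.basins
    multi = len(boxes) > 1
    total_area = sum(b.surface_area for b in boxes)
    k_off = (
        INSTANTANEOUS_K_OFF
        if config.adsorption.instantaneous
        else config.adsorption.k_off
    )

    def pfx(box: Basin, comp: str) -> str:
        return f"{box.name}.{comp}" if multi else comp

    # candidate compartments
    names: list[str] = []
    sinks: list[str] = [EXPORTED]
    for b in boxes:
        names.append(pfx(b, "water"))
        names.append(pfx(b, "pm_organic"))
        names.append(pfx(b, "pm_inorganic"))
        for g in config.groups:
            names.append(pfx(b, g.name))
        names.append(pfx(b, "sediment_active"))
        names.append(pfx(b, "porewater"))
        sinks.append(pfx(b, DEEP_SUFFIX))

    bld = _Builder(names, sinks)
    group_infos: list[GroupInfo] = []
    water_map: dict[str, str] = {}
    pw_map: dict[str, str] = {}
    pm_map: dict[str, tuple[str | None, str | None]] = {}
    volumes: dict[str, float] = {}
    pw_volumes: dict[str, float] = {}

    fractions = _source_fractions(config)
    bad = set(fractions) - {b.name for b in boxes}
    if bad:
        raise AssemblyError(f"source fractions reference unknown boxes: {bad}")

    for b in boxes:
        # sediment solids derive from settling PM; weight the organic and
        # inorganic partition coefficients by the box's PM composition
        kd_sed = (
            b.pm_organic_fraction * rn.kd_organic
            + (1.0 - b.pm_organic_fraction) * rn.kd_inorganic
        )
        w = pfx(b, "water")
        po = pfx(b, "pm_organic")
        pi = pfx(b, "pm_inorganic")
        sa = pfx(b, "sediment_active")
        pw = pfx(b, "porewater")
        deep = pfx(b, DEEP_SUFFIX)
        weight = b.surface_area / total_area

        water_map[b.name] = w
        pw_map[b.name] = pw
        pm_map[b.name] = (po, pi)
        volumes[b.name] = b.volume
        pw_volumes[b.name] = b.porewater_volume

        # (1) source
        frac = fractions.get(b.name, 0.0)
        if frac > 0:
            target = w if source_target == "water" else pw
            if source_target == "porewater" and b.porewater_volume <= 0:
                raise AssemblyError(
                    f"box {b.name}: pore-water source requires a sediment "
                    "active layer (active_layer_depth > 0)"
                )
            bld.s[bld.idx[target]] += config.source.rate * frac

        # (2) advective export / exchange, dissolved + PM phases
        if not config.exchanges:
            rate = 1.0 / b.water_retention_time
            for comp in (w, po, pi):
                bld.add_sink(rate, comp, EXPORTED)

        # (3) water <-> PM adsorption kinetics
        r_org = rn.kd_organic * b.pm_concentration * b.pm_organic_fraction
        r_inorg = rn.kd_inorganic * b.pm_concentration * (
            1.0 - b.pm_organic_fraction
        )
        bld.add(k_off * r_org, w, po)
        bld.add(k_off, po, w)
        bld.add(k_off * r_inorg, w, pi)
        bld.add(k_off, pi, w)

        # (4) water <-> biota surface adsorption
        for g in config.groups:
            comp = pfx(b, g.name)
            kd_g = group_kd(rn, g)
            biomass_b = g.biomass * weight
            if g.habitat == "infauna":
                if b.porewater_volume <= 0:
                    raise AssemblyError(
                        f"box {b.name}: infauna group {g.name} requires "
                        "a pore-water volume (active_layer_depth > 0)"
                    )
                ref, vref = pw, b.porewater_volume
            else:
                ref, vref = w, b.volume
            ratio = kd_g * biomass_b / vref
            bld.add(k_off * ratio, ref, comp)
            bld.add(k_off, comp, ref)
            group_infos.append(
                GroupInfo(
                    name=g.name,
                    box=b.name,
                    compartment=comp,
                    biomass=biomass_b,
                    habitat=g.habitat,
                    kd=kd_g,
                    carbon_fraction_fw=g.carbon_fraction_fw,
                )
            )

        # (5) trophic transfer + (6) mortality and K-mode feces efflux
        for c in config.groups:
            ccomp = pfx(b, c.name)
            for prey, dfrac in config.diet.get(c.name, {}).items():
                ae = rn.ae_for(c.name)
                if prey == PM:
                    if b.pm_carbon_stock <= 0:
                        raise AssemblyError(
                            f"box {b.name}: diet of {c.name} includes PM but "
                            "the PM carbon stock is zero"
                        )
                    # ingested PM tracer: assimilated part to the consumer,
                    # the egested remainder stays on PM
                    spec = fluxes.ingestion(c.name, PM) * weight / b.pm_carbon_stock
                    bld.add(spec * ae, po, ccomp)
                else:
                    p = config.group(prey)
                    spec = fluxes.ingestion(c.name, prey) / p.biomass
                    pcomp = pfx(b, prey)
                    bld.add(spec * ae, pcomp, ccomp)
                    bld.add(spec * (1.0 - ae), pcomp, po)
        for g in config.groups:
            comp = pfx(b, g.name)
            bld.add(g.mortality_rate, comp, po)
            if mode == "K" and g.ingestion_rate > 0:
                bld.add(g.egestion_fraction * g.ingestion_rate, comp, po)

        # (7) sediment dynamics
        if b.mean_depth > 0 and b.sedimentation_velocity > 0:
            settle = b.sedimentation_velocity / b.mean_depth
            bld.add(settle, po, sa)
            bld.add(settle, pi, sa)
        if b.resuspension_rate > 0:
            bld.add(b.resuspension_rate * b.pm_organic_fraction, sa, po)
            bld.add(
                b.resuspension_rate * (1.0 - b.pm_organic_fraction), sa, pi
            )
        bld.add_sink(b.burial_rate, sa, deep)
        if b.porewater_volume > 0:
            r_sed = kd_sed * b.sediment_solid_mass / b.porewater_volume
            bld.add(k_off * r_sed, pw, sa)
            bld.add(k_off, sa, pw)
            if b.porewater_exchange_rate > 0:
                q_pw = b.porewater_exchange_rate * b.porewater_volume
                bld.add(b.porewater_exchange_rate, pw, w)
                bld.add(q_pw / b.volume, w, pw)

    # between-box advection of dissolved and PM phases
    box_by_name = {b.name: b for b in boxes}
    for e in config.exchanges:
        if e.source == BOUNDARY:
            continue  # boundary water is clean
        src = box_by_name[e.source]
        rate = e.flow / src.volume
        src_comps = (water_map[src.name],) + tuple(
            c for c in pm_map[src.name] if c
        )
        if e.target == BOUNDARY:
            for comp in src_comps:
                bld.add_sink(rate, comp, EXPORTED)
        else:
            tgt = box_by_name[e.target]
            targets = (water_map[tgt.name],) + tuple(
                c for c in pm_map[tgt.name] if c
            )
            for comp, tcomp in zip(src_comps, targets):
                bld.add(rate, comp, tcomp)

    # (8) decay
    if rn.decay_constant > 0:
        for j in range(len(names)):
            bld.M[j, j] -= rn.decay_constant

    system = TracerSystem(
        matrix=bld.M,
        source=bld.s,
        sink_matrix=bld.S,
        compartments=list(names),
        sinks=list(sinks),
        groups=group_infos,
        water=water_map,
        porewater=pw_map,
        pm=pm_map,
        volumes=volumes,
        porewater_volumes=pw_volumes,
        radionuclide=rn.name,
        mode=mode,
        decay_constant=rn.decay_constant,
        water_basis=config.cr.water_basis,
    )
    system = _prune(system)
    _check_structure(system)
    return system


def _prune(system: TracerSystem) -> TracerSystem:
    """Drop compartments that can never hold activity (no inflow, no source).

    Removal is iterated to a fixed point: pruning one compartment may leave
    another without inflow.
    """
    keep = list(range(system.n))
    M, s = system.matrix, system.source
    changed = True
    while changed:
        changed = False
        for i in list(keep):
            inflow = sum(M[i, j] for j in keep if j != i)
            if inflow == 0.0 and s[i] == 0.0:
                keep.remove(i)
                changed = True
    if len(keep) == system.n:
        return system
    keep_arr = np.array(keep, dtype=int)
    kept_names = [system.compartments[i] for i in keep]
    dropped = set(system.compartments) - set(kept_names)
    return TracerSystem(
        matrix=M[np.ix_(keep_arr, keep_arr)],
        source=s[keep_arr],
        sink_matrix=system.sink_matrix[:, keep_arr],
        compartments=kept_names,
        sinks=system.sinks,
        groups=[g for g in system.groups if g.compartment not in dropped],
        water=system.water,
        porewater={k: v for k, v in system.porewater.items() if v not in dropped},
        pm={
            box: tuple(c if c not in dropped else None for c in pair)
            for box, pair in system.pm.items()
        },
        volumes=system.volumes,
        porewater_volumes=system.porewater_volumes,
        radionuclide=system.radionuclide,
        mode=system.mode,
        decay_constant=system.decay_constant,
        water_basis=system.water_basis,
    )


def _check_structure(system: TracerSystem) -> None:
    M = system.matrix
    off = M - np.diag(np.diag(M))
    if off.min() < 0:
        raise AssemblyError("transfer matrix is not Metzler")
    col = M.sum(axis=0) + system.sink_matrix.sum(axis=0)
    expected = -system.decay_constant
    scale = max(np.abs(M).max(), 1.0)
    if np.max(np.abs(col - expected)) > 1e-9 * scale:
        worst = system.compartments[int(np.argmax(np.abs(col - expected)))]
        raise AssemblyError(
            f"internal conservation violated in column {worst}"
        )


def trapped_compartments(system: TracerSystem) -> list[str]:
    """Live compartments with no path to an external sink (export, burial,
    decay); a nonempty result makes the steady-state problem singular."""
    if system.decay_constant > 0:
        return []
    g = nx.DiGraph()
    g.add_nodes_from(range(system.n))
    n = system.n
    for i in range(n):
        for j in range(n):
            if i != j and system.matrix[i, j] > 0:
                g.add_edge(j, i)
    sink_connected = {
        j for j in range(n) if system.sink_matrix[:, j].sum() > 0
    }
    trapped = []
    for j in range(n):
        if j in sink_connected:
            continue
        if not any(nx.has_path(g, j, t) for t in sink_connected):
            trapped.append(system.compartments[j])
    return trapped
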