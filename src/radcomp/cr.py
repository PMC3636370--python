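"""Concentration ratios (CR) of biota relative to the ambient water.

CR is the radionuclide concentration in the organism, normalized to its
carbon content (Bq kgC^-1), divided by the concentration in sea water
(Bq m^-3), giving units of m^3 kgC^-1.  Infauna live in the sediment and
are referenced to pore water instead of the overlying water column.

By default the denominator is the *dissolved* water concentration, since
the uptake laws are written against dissolved activity; a config flag
switches to the total (dissolved + PM-adsorbed) water basis.  Annual
averaging averages the instantaneous CR ratio itself (mean of ratios);
the ratio of time-means is available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .solvers import Trajectory
from .tracer import TracerState, TracerSystem

SEA_WATER = "sea water"
PORE_WATER = "pore water"


@dataclass(frozen=True)
class CRRecord:
    radionuclide: str
    group: str
    box: str
    cr: float  # m^3 per kgC
    reference_water: str
    window: float  # averaging window, years (0 = instantaneous)


def cr(biota_concentration: float, water_concentration: float) -> float:
    """CR (m^3 kgC^-1) = biota concentration (Bq kgC^-1) / water (Bq m^-3)."""
    if water_concentration <= 0:
        raise ValueError(
            f"water concentration must be > 0, got {water_concentration}"
        )
    return biota_concentration / water_concentration


def cr_fresh_weight(
    biota_concentration_fw: float,
    carbon_fraction_fw: float,
    water_concentration: float,
) -> float:
    """CR from a fresh-weight tissue concentration (Bq kg_fw^-1).

    Dividing by the carbon fraction (kgC per kg fresh weight) converts to
    the carbon basis before forming the ratio.
    """
    if carbon_fraction_fw <= 0:
        raise ValueError("carbon_fraction_fw must be > 0")
    return cr(biota_concentration_fw / carbon_fraction_fw, water_concentration)


def _water_concentration(
    system: TracerSystem, values: np.ndarray, box: str, habitat: str
) -> float:
    """Reference water concentration (Bq m^-3) for one box and habitat."""
    names = system.all_compartments
    idx = {c: i for i, c in enumerate(names)}
    if habitat == "infauna":
        comp = system.porewater.get(box)
        vol = system.porewater_volumes[box]
        if comp is None or vol <= 0:
            raise ValueError(f"box {box}: no pore water for infauna reference")
        return float(values[idx[comp]]) / vol
    conc = float(values[idx[system.water[box]]])
    if system.water_basis == "total":
        for pm_comp in system.pm.get(box, ()):
            if pm_comp is not None:
                conc += float(values[idx[pm_comp]])
    return conc / system.volumes[box]


def _records_from_values(
    system: TracerSystem, values: np.ndarray, window: float
) -> list[CRRecord]:
    names = system.all_compartments
    idx = {c: i for i, c in enumerate(names)}
    records = []
    for g in system.groups:
        biota_conc = float(values[idx[g.compartment]]) / g.biomass
        water_conc = _water_concentration(system, values, g.box, g.habitat)
        records.append(
            CRRecord(
                radionuclide=system.radionuclide,
                group=g.name,
                box=g.box,
                cr=cr(biota_conc, water_conc),
                reference_water=PORE_WATER if g.habitat == "infauna" else SEA_WATER,
                window=window,
            )
        )
    return records


def cr_from_state(
    system: TracerSystem,
    state: TracerState | Trajectory,
    averaging: str = "instantaneous",
    window: float = 1.0,
) -> pd.DataFrame:
    """CR table per (group, box) from a state or a trajectory.

    ``averaging='instantaneous'`` evaluates a single state (or the final
    state of a trajectory).  ``averaging='annual_mean'`` time-averages the
    instantaneous CR over the last ``window`` years of a trajectory by
    trapezoidal quadrature (mean of ratios).
    """
    if averaging == "instantaneous":
        values = (
            state.values
            if isinstance(state, TracerState)
            else state.values[-1]
        )
        records = _records_from_values(system, values, window=0.0)
    elif averaging == "annual_mean":
        if not isinstance(state, Trajectory):
            raise TypeError("annual_mean averaging requires a Trajectory")
        t_end = state.times[-1]
        if t_end - state.times[0] < window * (1 - 1e-9):
            raise ValueError(
                f"averaging window {window} y exceeds the trajectory span"
            )
        mask = state.times >= t_end - window * (1 + 1e-12)
        times = state.times[mask]
        per_time = [
            _records_from_values(system, state.values[i], window)
            for i in np.flatnonzero(mask)
        ]
        records = []
        for j, rec0 in enumerate(per_time[0]):
            crs = np.array([recs[j].cr for recs in per_time])
            mean = float(np.trapezoid(crs, times) / (times[-1] - times[0]))
            records.append(
                CRRecord(
                    radionuclide=rec0.radionuclide,
                    group=rec0.group,
                    box=rec0.box,
                    cr=mean,
                    reference_water=rec0.reference_water,
                    window=window,
                )
            )
    else:
        raise ValueError(f"unknown averaging {averaging!r}")
    return pd.DataFrame([r.__dict__ for r in records])


def cr_series(
    system: TracerSystem,
    trajectory: Trajectory,
    group: str,
    box: str | None = None,
    biomass_factor: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous CR time series (times, cr) for one group in one box.

    ``biomass_factor`` (same length as the trajectory) rescales the
    group's biomass per sample -- used for seasonally forced runs where
    the standing stock varies while the tracer inventory is tracked.
    """
    infos = [
        g
        for g in system.groups
        if g.name == group and (box is None or g.box == box)
    ]
    if not infos:
        raise KeyError(f"group {group!r} (box {box!r}) not in system")
    info = infos[0]
    factors = (
        np.ones_like(trajectory.times)
        if biomass_factor is None
        else np.asarray(biomass_factor, dtype=float)
    )
    comp_idx = trajectory.compartments.index(info.compartment)
    crs = np.empty(len(trajectory.times))
    for i in range(len(trajectory.times)):
        water_conc = _water_concentration(
            system, trajectory.values[i], info.box, info.habitat
        )
        if water_conc <= 0:
            # cold start: no activity has reached the water yet
            crs[i] = np.nan
        else:
            crs[i] = cr(
                trajectory.values[i, comp_idx] / (info.biomass * factors[i]),
                water_conc,
            )
    return trajectory.times, crs


def write_cr_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = ["radionuclide", "group", "box", "cr", "reference_water", "window"]
    table[cols].rename(columns={"cr": "cr_m3_per_kgC"}).to_csv(path, index=False)
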