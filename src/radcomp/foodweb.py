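"""Steady annual carbon fluxes of the basin food web.

The compartment model keeps biomasses constant through the simulation:
the food web is parameterized by annual rates, and the carbon budget of
every biotic compartment must close.  Ingestion is split over prey by the
diet matrix; an ``egestion_fraction`` of ingestion is returned to the
particulate pool (PM) as feces, mortality also routes to PM, and
respiration closes each consumer's budget as the balancing residual (it
must come out non-negative, otherwise the web is infeasible).  Producers
receive primary production from DIC sized exactly to balance their losses.
PM closes via bacterial degradation (to DIC), sedimentation and export;
the sediment closes via burial.

Respiration and degradation return carbon to the dissolved inorganic pool
and carry no tracer: radionuclides follow *organic* carbon only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ModelConfig, FunctionalGroup

#: Non-biotic carbon compartments appearing in the flux matrix.
DIC = "DIC"
PM = "PM"
SED = "SED"
EXPORT = "EXPORT"


class ImbalanceError(ValueError):
    """Raised when the configured rates cannot form a balanced annual web."""


@dataclass
class CarbonFluxMatrix:
    """Annual carbon fluxes (kgC y^-1), ``flux.loc[source, target]``."""

    flux: pd.DataFrame
    totals: pd.DataFrame  # per-group ingestion/egestion/respiration/mortality/production/predation_loss

    @property
    def compartments(self) -> list[str]:
        return list(self.flux.index)

    def ingestion(self, consumer: str, prey: str) -> float:
        """Carbon ingested by ``consumer`` from ``prey`` (kgC y^-1)."""
        return float(self.flux.loc[prey, consumer])

    def residuals(self, groups: list[str]) -> pd.Series:
        """Inflow minus outflow per biotic compartment (kgC y^-1)."""
        inflow = self.flux[groups].sum(axis=0)
        outflow = self.flux.loc[groups].sum(axis=1)
        return inflow - outflow

    def to_csv(self, path: str | Path) -> None:
        tidy = (
            self.flux.stack()
            .rename("kgC_per_year")
            .reset_index()
            .rename(columns={"level_0": "source", "level_1": "target"})
        )
        tidy = tidy[tidy["kgC_per_year"] != 0.0]
        tidy.to_csv(path, index=False)


def build_fluxes(config: ModelConfig) -> CarbonFluxMatrix:
    """Assemble the balanced annual carbon flux matrix for the first basin.

    Raises :class:`ImbalanceError` with a per-compartment report when the
    configured rates are infeasible (losses exceeding inputs).
    """
    basin = config.basin
    groups = config.groups
    names = [g.name for g in groups]
    comps = names + [DIC, PM, SED, EXPORT]
    flux = pd.DataFrame(0.0, index=comps, columns=comps)

    ingestion_total = {g.name: g.ingestion_rate * g.biomass for g in groups}

    # ingestion split by diet; egestion and mortality to PM
    for g in groups:
        I = ingestion_total[g.name]
        for prey, frac in config.diet.get(g.name, {}).items():
            flux.loc[prey, g.name] += I * frac
        flux.loc[g.name, PM] += g.egestion_fraction * I
        flux.loc[g.name, PM] += g.mortality_rate * g.biomass

    predation = {
        name: float(flux.loc[name, names].sum()) for name in names
    }

    problems: list[str] = []
    totals_rows = {}
    for g in groups:
        I = ingestion_total[g.name]
        E = g.egestion_fraction * I
        Mo = g.mortality_rate * g.biomass
        P = predation[g.name]
        if g.ingestion_rate > 0:
            # consumer: respiration balances the budget
            R = I - E - Mo - P
            if R < -1e-9 * max(I, 1.0):
                problems.append(
                    f"{g.name}: losses exceed ingestion "
                    f"(ingestion {I:.4g}, egestion {E:.4g}, mortality {Mo:.4g}, "
                    f"predation {P:.4g})"
                )
                R = 0.0
            flux.loc[g.name, DIC] += R
            production = 0.0
        else:
            # producer: primary production from DIC balances all losses
            R = g.respiration_rate * g.biomass
            flux.loc[g.name, DIC] += R
            production = Mo + P + R
            flux.loc[DIC, g.name] += production
        totals_rows[g.name] = {
            "ingestion": I,
            "egestion": E,
            "respiration": R,
            "mortality": Mo,
            "predation_loss": P,
            "production": production,
        }

    # PM budget: egestion + mortality in; grazing, sedimentation, export
    # out; bacterial degradation (to DIC) closes the residual.
    pm_in = float(flux.loc[:, PM].sum())
    pm_grazed = float(flux.loc[PM, names].sum())
    pm_stock = basin.pm_carbon_stock
    pm_sed = (
        basin.sedimentation_velocity / basin.mean_depth * pm_stock
        if basin.mean_depth > 0
        else 0.0
    )
    pm_export = pm_stock / basin.water_retention_time
    degradation = pm_in - pm_grazed - pm_sed - pm_export
    if degradation < -1e-9 * max(pm_in, 1.0):
        problems.append(
            f"PM: outflows exceed inputs (in {pm_in:.4g}, grazed {pm_grazed:.4g}, "
            f"sedimentation {pm_sed:.4g}, export {pm_export:.4g})"
        )
        degradation = 0.0
    flux.loc[PM, SED] += pm_sed
    flux.loc[PM, EXPORT] += pm_export
    flux.loc[PM, DIC] += degradation

    # sediment carbon closes via burial (counted as export row for carbon)
    flux.loc[SED, EXPORT] += pm_sed

    if problems:
        raise ImbalanceError("infeasible carbon balance: " + "; ".join(problems))

    totals = pd.DataFrame(totals_rows).T
    result = CarbonFluxMatrix(flux=flux, totals=totals)

    resid = result.residuals(names)
    gross = flux.to_numpy().sum()
    bad = resid[np.abs(resid.to_numpy()) > 1e-9 * max(gross, 1.0)]
    if len(bad):  # pragma: no cover - balanced by construction
        raise ImbalanceError(f"residual imbalance in {dict(bad)}")
    return result


def turnover_rate(group: FunctionalGroup, fluxes: CarbonFluxMatrix) -> float:
    """Specific carbon turnover (y^-1): (predation losses + mortality)/biomass.

    Accumulated tracer is retained in a living organism and leaves only
    when it dies or is eaten, so this is the tracer's only biotic loss
    pathway in D mode; K mode adds the feces efflux on top.
    """
    if group.biomass <= 0:
        raise ValueError(f"group {group.name}: biomass must be > 0")
    row = fluxes.totals.loc[group.name]
    return float((row["predation_loss"] + row["mortality"]) / group.biomass)
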