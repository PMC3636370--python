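"""Organism geometry and surface-adsorption scaling.

Passive adsorption of dissolved radionuclides onto organism surfaces is
proportional to the available surface area, so small organisms with a high
surface-to-volume (S:V) ratio show high partition coefficients.  S:V is
derived from the dominant morphology of each functional group, idealized
as a sphere, a cylinder (lateral surface only, the elongated-organism
approximation) or a flat lamina.  For fish the gill surface, supplied as a
per-group parameter, is added to the body surface.

The element-specific adsorption constant is the ``surface_affinity``
(units m): the equivalent volume of water whose dissolved activity is held
at equilibrium per square metre of surface.  The per-group adsorption
coefficient is then

    group_kd [m^3 kgC^-1] = surface_affinity [m] x specific_surface [m^2 kgC^-1]

which keeps the coefficient linear in both factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import FunctionalGroup, ModelConfig, Radionuclide


@dataclass(frozen=True)
class SurfaceModel:
    """Surface properties of one functional group."""

    group: str
    sv_ratio: float  # m^-1
    specific_surface: float  # m^2 per kgC, body + gills


def sv_ratio(shape: str, characteristic_dimension: float) -> float:
    """Surface-to-volume ratio (m^-1) of an idealized body.

    sphere of radius r -> 3/r; cylinder of radius r -> 2/r (ends ignored);
    flat lamina of thickness t -> 2/t (both faces).
    """
    if characteristic_dimension <= 0:
        raise ValueError(
            f"characteristic_dimension must be > 0, got {characteristic_dimension}"
        )
    if shape == "sphere":
        return 3.0 / characteristic_dimension
    if shape == "cylinder":
        return 2.0 / characteristic_dimension
    if shape == "flat":
        return 2.0 / characteristic_dimension
    raise ValueError(f"unknown shape {shape!r}")


def specific_surface(group: FunctionalGroup) -> float:
    """Adsorbing surface per unit carbon (m^2 kgC^-1), body plus gills.

    Dividing S:V (m^-1) by the carbon density (kgC per m^3 biovolume)
    converts geometric surface per volume into surface per carbon; the
    total adsorbing area of the group is ``specific_surface * biomass``.
    """
    sv = sv_ratio(group.shape, group.characteristic_dimension)
    return sv / group.carbon_density + group.gill_area_specific


def surface_model(group: FunctionalGroup) -> SurfaceModel:
    return SurfaceModel(
        group=group.name,
        sv_ratio=sv_ratio(group.shape, group.characteristic_dimension),
        specific_surface=specific_surface(group),
    )


def total_surface(group: FunctionalGroup) -> float:
    """Total adsorbing area of the group standing stock (m^2)."""
    return specific_surface(group) * group.biomass


def group_kd(radionuclide: Radionuclide, group: FunctionalGroup) -> float:
    """Equilibrium adsorption coefficient of a group (m^3 kgC^-1).

    At equilibrium the surface-adsorbed concentration (Bq kgC^-1) equals
    ``group_kd`` times the dissolved water concentration (Bq m^-3).
    """
    if radionuclide.surface_affinity < 0:
        raise ValueError("surface_affinity must be >= 0")
    return radionuclide.surface_affinity * specific_surface(group)


def sv_table(config: ModelConfig) -> pd.DataFrame:
    """Per-group S:V and adsorption coefficients, for inspection/export."""
    rows = []
    for g in config.groups:
        row = {
            "group": g.name,
            "shape": g.shape,
            "characteristic_dimension_m": g.characteristic_dimension,
            "sv_ratio_per_m": sv_ratio(g.shape, g.characteristic_dimension),
            "specific_surface_m2_per_kgC": specific_surface(g),
            "total_surface_m2": total_surface(g),
        }
        for r in config.radionuclides:
            row[f"kd_{r.name}_m3_per_kgC"] = group_kd(r, g)
        rows.append(row)
    return pd.DataFrame(rows)
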