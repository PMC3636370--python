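"""Seasonally forced multi-box run: bloom dilution and spatial gradients.

Runs the 5-box demonstration chain with the annual phytoplankton
forcing (winter floor, growing-season elevation, April bloom pulse) and
prints the heterogeneity statistics of the final year: the correlation
between phytoplankton biomass and its CR (negative: growth dilutes the
slowly equilibrating surface-adsorbed activity), the winter/summer CR
ratio, and the dissolved-concentration gradient down a chain whose
first box receives the whole release.
"""

import numpy as np

import radcomp as rc

chain = rc.make_chain_config()
run = rc.run_seasonal(chain, rc.SeasonalForcing(), years=3.0)

t, crs = run.cr_series("phytoplankton", box="basin118")
f = run.biomass_factors()
last = t >= t[-1] - 1.0
corr = np.corrcoef(f[last], crs[last])[0, 1]
het = rc.heterogeneity_summary(run, group="phytoplankton", box="basin118")

print("5-box chain, Cs-135, pore-water release split evenly, 3 forced years\n")
print(f"biomass-CR correlation over the final year : {corr:+.3f}")
print("  (negative: the bloom adds clean biomass faster than adsorption loads it)")
print(f"winter/summer CR ratio (Q1 / Q3)           : "
      f"{het['seasonal_ratio_winter_over_summer']:.2f}")
print(f"within-box CR percentiles (p5, p95)        : "
      f"{het['temporal_p5']:.3g}, {het['temporal_p95']:.3g} m^3/kgC")

source_chain = rc.make_chain_config(source_boxes=["basin116"])
system = rc.assemble(source_chain, "Cs135", mode="K")
steady = rc.solve_steady(system)
print("\ndissolved Cs-135 down the chain (release into basin116 water):")
for b in source_chain.basins:
    conc = steady[f"{b.name}.water"] / system.volumes[b.name]
    print(f"  {b.name}: {conc:.4g} Bq/m^3")
print("  (non-increasing with distance from the source box)")
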