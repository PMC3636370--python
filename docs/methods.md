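# Methods

## Model overview

`radcomp` traces a constant, trace-level radionuclide release (1 Bq y⁻¹ by
default) through a well-mixed coastal basin — or a network of basin boxes —
by riding the annual carbon flows of the ecosystem. The state is the
activity (Bq) in each compartment: dissolved water, PM-adsorbed activity
(organic and inorganic particles separately), each biotic functional group,
the active sediment layer, the sediment pore water, plus two terminal
accumulators (activity exported across the open boundary, activity buried
into consolidated deep sediment). Every process is first order in the
activities, so a scenario is a linear ODE system dA/dt = M·A + s with a
Metzler matrix M (non-negative off-diagonal rates), which guarantees
non-negative trajectories and makes the steady state a single linear solve.

Key modelling assumptions:

- **Radionuclides follow organic carbon.** Respiration and bacterial
  degradation return carbon to the DIC pool but carry no tracer; the DIC
  compartment therefore holds no activity.
- **Constant biomasses.** The food web is parameterized by annual rates and
  held at steady state; the tracer rides on those fluxes. The only
  exception is the seasonal multi-box mode, where the phytoplankton
  standing stock follows a prescribed annual forcing.
- **Retention in living tissue.** Assimilated tracer leaves an organism
  only through death or predation. The K release mode adds a continuous
  feces efflux at the carbon egestion rate; the D-lite mode does not.
  Elimination/excretion of assimilated tracer is zero in both modes, so
  the two modes differ in exactly two things: the source location (water
  column vs. sediment pore water) and the feces routing.
- **Kinetic adsorption.** Surface adsorption exchanges are first order
  with desorption rate `k_off` (default 10 y⁻¹) and an attachment rate set
  so the equilibrium ratio equals the relevant Kd product. This finite
  kinetics is what produces the loose coupling between water and plankton
  concentrations around bloom events; an "instantaneous" flag raises
  `k_off` to 10⁵ y⁻¹ as a quasi-instantaneous limit rather than switching
  to an algebraic constraint.
- **No decay by default.** The target nuclides (¹³⁵Cs, ⁵⁹Ni, ²³⁰Th) are
  long-lived relative to the simulated horizon; a per-nuclide decay
  constant is plumbed through and defaults to zero.
- **Clean boundary.** Water entering the basin (or the box network) from
  the open sea carries zero activity.

## Surface-scaled adsorption

Adsorption is proportional to surface area, so the surface-to-volume
ratio of the dominant morphology sets each group's affinity for the
dissolved phase: S:V = 3/r for spheres, 2/r for cylinders (lateral
surface only — the elongated-organism approximation), 2/t for flat
laminae. Dividing by the carbon density (kgC per m³ biovolume) converts
to a specific surface (m² kgC⁻¹); fish add a per-group gill area rather
than a computed allometry. The element-specific constant is a
`surface_affinity` (m): the equivalent water volume equilibrated per m²
of surface. The group adsorption coefficient is

    group_kd = surface_affinity × specific_surface   [m³ kgC⁻¹],

linear in both factors, and the kinetic attachment rate is
`k_off × group_kd × biomass / V_ref`, where the reference water volume is
the water column for pelagic/benthic groups and the pore water for
infauna. A single affinity is used for body and gill surfaces, and
adsorption is applied uniformly to all biota including benthophytes.

## Carbon web closure

The annual web must balance exactly. Ingestion is `ingestion_rate ×
biomass`, split over prey by the diet matrix; an `egestion_fraction` of
ingestion returns to PM, mortality routes to PM, and consumer
respiration closes each budget as the non-negative residual (an
infeasible web raises a per-compartment report). Producers receive
primary production from DIC sized to balance their losses; production is
a configured closure, not a nutrient model. The PM pool closes through
grazing, settling (`sedimentation_velocity / mean_depth`), export with
the water turnover and bacterial degradation as residual; the active
sediment layer closes through burial. Carbon resuspension is not
tracked in the carbon web (only tracer resuspension is modelled); the
balance checks hold to 1 part in 10⁹ of the gross flux.

## Sediment and pore water

The two-layer sediment has an active layer exchanging kinetically with
its pore water (equilibrium ratio `kd_sed × solid mass / pore-water
volume`, with `kd_sed` the PM-composition-weighted mean of the organic
and inorganic Kd) and a consolidated deep layer fed by first-order
burial. The deep layer is the "buried" accumulator — it has no return
path, and counting it separately from a burial sink would double-count
the balance. Pore water exchanges with the overlying water column as a
single first-order rate (no diffusion profile). Three parameters beyond
the basin geometry support this module: porosity (default 0.8), dry
solids density of the active layer (250 kg m⁻³) and the carbon fraction
of dry organic PM (0.4 kgC kg⁻¹); all are fixture-level choices typical
of organic-rich coastal deposits. PM-adsorbed activity is exported with
the water turnover and advected between boxes along with the dissolved
phase — suspended particles travel with the water that carries them.

## Concentration ratios

CR = (activity per kgC of the group) / (Bq m⁻³ of the reference water),
in m³ kgC⁻¹; infauna are referenced to pore water. The denominator uses
the *dissolved* concentration by default because all uptake laws are
written against dissolved activity; a config flag switches to the total
(dissolved + PM) basis. Annual averaging takes the time-mean of the
instantaneous ratio (mean of ratios) by trapezoidal quadrature; the
ratio of time-means differs in seasonal runs and can be formed from the
exported series when needed. At adsorption-only equilibrium CR equals
`group_kd` exactly, and CR is invariant to the source rate — both serve
as analytic anchors in the tests.

## Solvers

Kinetic adsorption rates exceed biological turnover by orders of
magnitude, so transients use the implicit BDF method with the exact
constant Jacobian, relative tolerance 10⁻⁸ and an absolute tolerance
scaled to the injected activity. The steady state is solved directly
(LU with one step of iterative refinement); singular systems are
detected beforehand by graph reachability — any compartment without a
path to export, burial or decay is named in the diagnostic. Compartments
that can never hold activity (no inflow and no source, e.g. the sediment
of a water-only scenario) are pruned before solving. Quasi-stationarity
is measured against the direct steady solution: the first time every
live compartment is within the threshold (default 1%), located by linear
interpolation between output samples; compartments whose steady value is
below 10⁻¹² of the largest are compared against that floor. Conservation
— cumulative input = inventory + export + burial — is verified at every
output time to 10⁻⁶ relative for decay-free runs.

## Monte Carlo ensembles

Parameter PDFs (lognormal parameterized by median and geometric standard
deviation, normal, uniform, triangular, fixed; optional truncation by
rejection) attach to dotted config paths. Each draw perturbs a deep copy,
re-solves the steady system per radionuclide and records a CR table;
draws that fail validation or solving are excluded and reported, and more
than 10% failures abort the ensemble. Summaries per radionuclide × group
are the median, geometric mean exp(mean(log x)) and the 5th/95th
percentiles with linear interpolation between order statistics — reported
as `p5`/`p95` (a 90% interquantile band), never as a confidence interval.
The geometric mean is suppressed (NaN, flagged) when any sample is
non-positive.

## Seasonal multi-box mode

The demonstration network is a chain of five boxes (named basin116…,
splitting the toy basin's area evenly) with unidirectional exchange
flows giving ~10-day per-box retention; the release enters the pore
water of the designated boxes (evenly split by default — the real
per-basin source distribution would come from groundwater modelling and
is not part of the fixture). The phytoplankton forcing is a periodic
multiplier with unit annual mean: a winter floor (0.4), a growing-season
sinusoid peaking in mid-July (amplitude 1.2) and an April bloom pulse
(amplitude 2.0, σ = 20 d). Two matrix entries scale with the multiplier:
the water→phytoplankton adsorption uptake (total surface tracks the
standing stock) and the biological losses out of phytoplankton (grazer
stocks follow the same season, so the specific loss rate scales with the
multiplier); desorption is physicochemical and does not scale. Growth
adds clean biomass — the tracer inventory is conserved while the
specific activity dilutes — which, combined with the finite adsorption
kinetics, reproduces the bloom decoupling: the biomass–CR correlation is
strongly negative and winter CRs come out roughly twice the summer
values under the default forcing. Winter and summer are the calendar
quarters Jan–Mar and Jul–Sep.

A property of the kinetics worth knowing: with the pore-water source,
the *dissolved* concentration is not monotone down the chain, because
resuspension loads PM above its water equilibrium near the source and
that excess desorbs downstream; the total (dissolved + PM) concentration
is monotone. With a water-column release the dissolved concentration
itself decreases monotonically with distance from the source box, and
that is the configuration the dilution demonstration uses.

## The toy parameterization and what passing tests show

`make_toy_fixture` fixes the structure — a 11.5 km² basin, the eight
state variables of the compartment web (DIC, phytoplankton, benthophytes,
zooplankton, fish, grazers, benthos, PM) plus the two-layer sediment,
Cs/Ni/Th with Th partitioning tenfold stronger and zero Th assimilation,
1 Bq y⁻¹ release — while biomasses and biological rates are plausible
Baltic coastal-bay placeholders jittered ±10% by the seed. The file
carries `fixture: true`: these rates are illustrative, not site data.
Carbon fractions and carbon densities per group are likewise assumptions.
Consequently the test suite demonstrates that the *machinery* is correct
(conservation, closed forms, analytic quantile recovery, mechanism signs)
— it does not validate the model against field CRs, whose reproduction
would require the site parameterization held in external reports. The
bundled measured CR table is for orientation in overlay plots only.

## Problem sizes used

Default runs are sized for interactive use: 100-year single-basin
transients at 1-year output (≈13 live compartments), 10⁴-draw ensembles
on the adsorption-only system, 2×10³-draw ensembles on the full fixture,
and 3–8 forced years of the 5-box chain (≈60 state variables) at
~2.5-day output. All complete in seconds on one core.

## Known limitations

- No hydrodynamic computation: exchange flows and retention times are
  inputs, not results.
- No redox/oxygen module; redox-dependent precipitation (sulfides,
  carbonates) is out of scope — the place to add it would be an extra
  first-order sink on pore water conditioned on a redox state.
- No nutrient model: primary production is a closure of the carbon
  budget, not a response to nutrient supply.
- The sediment Kd mixing rule (PM-composition-weighted) and the single
  pore-water exchange rate are simple parameterizations of processes
  that are depth-resolved in nature.
- Decay chains and ingrowth are not modelled; the decay flag removes
  activity without tracking daughters.
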