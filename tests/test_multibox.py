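"""Box networks, seasonal forcing and heterogeneity summaries."""

import numpy as np
import pytest

import radcomp as rc
from radcomp.config import Exchange, SourceTerm
from radcomp.tracer import AssemblyError


def two_box_config(exchange_flow, boundary_flow=None):
    """Two identical boxes A <-> B with symmetric exchange; boundary water
    flows in through A and out through B at ``boundary_flow``."""
    config = rc.make_chain_config(n_boxes=2)
    a, b = (x.name for x in config.basins)
    f = boundary_flow if boundary_flow is not None else config.basins[0].volume / (
        10.0 / 365.0
    )
    q = exchange_flow
    config.exchanges = [
        Exchange("boundary", a, f),
        Exchange(a, b, f + q),
        Exchange(b, a, q),
        Exchange(b, "boundary", f),
    ]
    return config


class TestBuildNetwork:
    def test_symmetric_boxes_have_identical_concentrations(self):
        config = rc.make_chain_config(n_boxes=2)
        a, b = (x.name for x in config.basins)
        q = config.basins[0].volume * 30.0
        # fully symmetric: both boxes exchange with each other and the
        # boundary in the same way, source split 50/50
        config.exchanges = [
            Exchange("boundary", a, q),
            Exchange("boundary", b, q),
            Exchange(a, b, q),
            Exchange(b, a, q),
            Exchange(a, "boundary", q),
            Exchange(b, "boundary", q),
        ]
        config.source = SourceTerm(
            rate=1.0, mode="porewater", fractions={a: 0.5, b: 0.5}
        )
        system = rc.build_network(config, "Cs135")
        steady = rc.solve_steady(system)
        for comp in ("water", "pm_organic", "sediment_active", "porewater"):
            assert steady[f"{a}.{comp}"] == pytest.approx(
                steady[f"{b}.{comp}"], rel=1e-9
            )

    def test_infinite_exchange_matches_merged_box(self):
        """Two boxes mixing much faster than any other process behave as
        one merged box of twice the volume."""
        config = rc.make_chain_config(n_boxes=2)
        boundary = config.basins[0].volume / (10.0 / 365.0)
        config = two_box_config(exchange_flow=boundary * 1e4, boundary_flow=boundary)
        config.source = SourceTerm(
            rate=1.0, mode="porewater",
            fractions={b.name: 0.5 for b in config.basins},
        )
        system = rc.build_network(config, "Cs135")
        steady = rc.solve_steady(system)
        conc = [
            steady[f"{b.name}.water"] / system.volumes[b.name]
            for b in config.basins
        ]

        merged = config.copy()
        mb = merged.basins[0]
        mb.surface_area *= 2.0  # two boxes' worth of area and volume
        mb.volume = None
        mb.__post_init__()
        mb.water_retention_time = mb.volume / boundary
        merged.basins = [mb]
        merged.exchanges = []
        merged.source = SourceTerm(rate=1.0, mode="porewater", basin=mb.name)
        msys = rc.assemble(merged, "Cs135", mode="Dlite")
        msteady = rc.solve_steady(msys)
        mconc = msteady["water"] / mb.volume
        assert conc[0] == pytest.approx(mconc, rel=0.01)
        assert conc[1] == pytest.approx(mconc, rel=0.01)

    def test_source_fractions_must_sum_to_one(self):
        config = rc.make_chain_config(n_boxes=2)
        names = [b.name for b in config.basins]
        config.source.fractions = {names[0]: 0.6, names[1]: 0.5}
        with pytest.raises(AssemblyError, match="fractions"):
            rc.build_network(config, "Cs135")

    def test_unbalanced_water_budget_names_box(self):
        config = rc.make_chain_config(n_boxes=2)
        config.exchanges[1].flow *= 1.5
        with pytest.raises(AssemblyError, match=config.basins[0].name):
            rc.build_network(config, "Cs135")

    def test_relabeling_boxes_permutes_results(self):
        """Reversing the chain relabels the steady state exactly."""
        config = rc.make_chain_config(n_boxes=3, source_boxes=["basin116"])
        steady = rc.solve_steady(rc.build_network(config, "Cs135"))

        flipped = config.copy()
        flipped.basins = list(reversed(flipped.basins))
        steady_f = rc.solve_steady(rc.build_network(flipped, "Cs135"))
        for b in config.basins:
            for comp in ("water", "porewater", "sediment_active"):
                name = f"{b.name}.{comp}"
                assert steady[name] == pytest.approx(steady_f[name], rel=1e-9)


class TestSeasonalForcing:
    def test_annual_mean_is_one(self):
        forcing = rc.SeasonalForcing()
        t = np.linspace(0, 1, 20_000, endpoint=False)
        assert np.mean(forcing.multiplier(t)) == pytest.approx(1.0, abs=1e-3)

    def test_multiplier_positive_and_periodic(self):
        forcing = rc.SeasonalForcing()
        t = np.linspace(0, 2, 1000)
        m = forcing.multiplier(t)
        assert (m > 0).all()
        assert forcing.multiplier(0.25) == pytest.approx(
            forcing.multiplier(1.25), rel=1e-12
        )

    def test_rejects_nonpositive_baseline(self):
        with pytest.raises(ValueError):
            rc.SeasonalForcing(baseline=0.0)


class TestRunSeasonal:
    def test_refuses_instantaneous_adsorption(self):
        config = rc.make_chain_config(n_boxes=2)
        config.adsorption.instantaneous = True
        with pytest.raises(AssemblyError, match="instantaneous"):
            rc.run_seasonal(config, rc.SeasonalForcing(), years=2.0)

    def test_constant_forcing_reduces_to_steady_network(self):
        config = rc.make_chain_config(n_boxes=2)
        run = rc.run_seasonal(config, rc.ConstantForcing(), years=8.0)
        steady = rc.solve_steady(run.system)
        live = run.trajectory.final.values[: run.system.n]
        np.testing.assert_allclose(
            live, steady.values[: run.system.n], rtol=2e-3
        )

    def test_bloom_decouples_biomass_and_cr(self):
        """Dilution by growth: phytoplankton CR drops when the standing
        stock blooms, so the biomass-CR correlation is negative."""
        config = rc.make_chain_config()
        run = rc.run_seasonal(config, rc.SeasonalForcing(), years=3.0)
        t, crs = run.cr_series("phytoplankton", box="basin117")
        f = run.biomass_factors()
        last = t >= t[-1] - 1.0
        corr = np.corrcoef(f[last], crs[last])[0, 1]
        assert corr < 0

    def test_fast_kinetics_restore_coupling(self):
        """In the fast-desorption limit the biota concentration tracks
        group_kd times the water concentration through the bloom."""
        config = rc.make_chain_config(n_boxes=2)
        config.adsorption.k_off = 1.0e5
        run = rc.run_seasonal(config, rc.SeasonalForcing(), years=3.0)
        t, crs = run.cr_series("phytoplankton", box="basin116")
        info = [
            g
            for g in run.system.groups
            if g.name == "phytoplankton" and g.box == "basin116"
        ][0]
        last = t >= t[-1] - 1.0
        np.testing.assert_allclose(crs[last], info.kd, rtol=0.01)

    def test_forced_run_conserves_activity(self):
        config = rc.make_chain_config(n_boxes=2)
        run = rc.run_seasonal(config, rc.SeasonalForcing(), years=2.0)
        totals = run.trajectory.values.sum(axis=1)
        expected = run.system.total_source_rate() * run.trajectory.times
        np.testing.assert_allclose(totals[1:], expected[1:], rtol=1e-6)


class TestHeterogeneity:
    def test_uniform_network_has_unit_spatial_range(self):
        config = rc.make_chain_config(n_boxes=2)
        a, b = (x.name for x in config.basins)
        q = config.basins[0].volume * 30.0
        config.exchanges = [
            Exchange("boundary", a, q),
            Exchange("boundary", b, q),
            Exchange(a, "boundary", q),
            Exchange(b, "boundary", q),
        ]
        config.source = SourceTerm(
            rate=1.0, mode="porewater", fractions={a: 0.5, b: 0.5}
        )
        run = rc.run_seasonal(config, rc.SeasonalForcing(), years=3.0)
        het = rc.heterogeneity_summary(run)
        assert het["spatial_range_factor"] == pytest.approx(1.0, rel=1e-6)

    def test_constant_forcing_gives_unit_seasonal_ratio(self):
        config = rc.make_chain_config(n_boxes=2)
        run = rc.run_seasonal(config, rc.ConstantForcing(), years=6.0)
        het = rc.heterogeneity_summary(run)
        assert het["seasonal_ratio_winter_over_summer"] == pytest.approx(
            1.0, rel=0.01
        )

    def test_chain_dissolved_concentration_non_increasing(self):
        """Dilution down a source-rooted chain, from the direct steady
        solve with the release into the water column of the first box."""
        config = rc.make_chain_config(source_boxes=["basin116"])
        system = rc.assemble(config, "Cs135", mode="K")
        steady = rc.solve_steady(system)
        conc = [
            steady[f"{b.name}.water"] / system.volumes[b.name]
            for b in config.basins
        ]
        assert all(
            a >= b * (1 - 1e-12) for a, b in zip(conc, conc[1:])
        )

    def test_incomplete_spinup_warns(self):
        """Fish turn over slowly, so two years leave their CR drifting."""
        config = rc.make_chain_config(n_boxes=2)
        run = rc.run_seasonal(config, rc.SeasonalForcing(), years=2.0)
        with pytest.warns(UserWarning, match="spin-up"):
            rc.heterogeneity_summary(run, group="fish")

    def test_box_summary_shape(self):
        config = rc.make_chain_config(n_boxes=2)
        run = rc.run_seasonal(config, rc.SeasonalForcing(), years=3.0)
        table = rc.box_summary(run)
        assert len(table) == 2
        assert "annual_mean_water_Bq_per_m3" in table.columns
        assert "cr_phytoplankton" in table.columns
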