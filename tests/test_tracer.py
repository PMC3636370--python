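"""Tracer system assembly: per-process rates, conservation, structure."""

import numpy as np
import pytest

import radcomp as rc
from radcomp.config import (
    Basin,
    FunctionalGroup,
    ModelConfig,
    Radionuclide,
    SourceTerm,
)
from radcomp.geometry import group_kd
from radcomp.tracer import AssemblyError, rhs, trapped_compartments
from conftest import random_metzler_system


def small_config():
    """One basin with PM, sediment and a two-link food chain; every
    process rate is reconstructed by hand in the oracle test below."""
    basin = Basin(
        name="b",
        surface_area=1e6,
        mean_depth=2.0,
        water_retention_time=0.1,
        pm_concentration=2e-5,
        pm_organic_fraction=0.4,
        sedimentation_velocity=10.0,
        active_layer_depth=0.05,
        burial_rate=0.05,
        resuspension_rate=1.0,
        porewater_exchange_rate=4.0,
        porosity=0.8,
        sediment_dry_density=200.0,
        pm_carbon_fraction=0.4,
    )
    producer = FunctionalGroup(
        name="producer",
        biomass=100.0,
        carbon_fraction_fw=0.05,
        carbon_density=100.0,
        shape="sphere",
        characteristic_dimension=1e-5,
        mortality_rate=2.0,
        habitat="pelagic",
    )
    consumer = FunctionalGroup(
        name="consumer",
        biomass=20.0,
        carbon_fraction_fw=0.1,
        carbon_density=120.0,
        shape="cylinder",
        characteristic_dimension=1e-3,
        mortality_rate=0.5,
        egestion_fraction=0.3,
        ingestion_rate=8.0,
        habitat="pelagic",
    )
    rn = Radionuclide(
        name="r",
        kd_organic=2.0,
        kd_inorganic=1.0,
        surface_affinity=1e-5,
        assimilation_efficiency=0.4,
    )
    return ModelConfig(
        basins=[basin],
        groups=[producer, consumer],
        diet={"consumer": {"producer": 0.5, "PM": 0.5}},
        radionuclides=[rn],
        source=SourceTerm(rate=1.0, mode="water", basin="b"),
    )


class TestAssemblyOracle:
    def test_entries_match_per_process_hand_assembly(self):
        """Every matrix entry equals the sum of the process rates that
        feed it, reconstructed process by process with scalar formulas."""
        config = small_config()
        b, rn = config.basin, config.radionuclides[0]
        system = rc.assemble(config, "r", mode="K")
        k_off = config.adsorption.k_off
        i = {c: n for n, c in enumerate(system.compartments)}
        M = system.matrix

        # water <-> PM kinetics
        assert M[i["pm_organic"], i["water"]] == pytest.approx(
            k_off * rn.kd_organic * b.pm_concentration * b.pm_organic_fraction
        )
        assert M[i["pm_inorganic"], i["water"]] == pytest.approx(
            k_off * rn.kd_inorganic * b.pm_concentration * (1 - b.pm_organic_fraction)
        )
        assert M[i["water"], i["pm_inorganic"]] == pytest.approx(k_off)

        # biota adsorption (pelagic: referenced to the water column)
        for g in config.groups:
            assert M[i[g.name], i["water"]] == pytest.approx(
                k_off * group_kd(rn, g) * g.biomass / b.volume
            )

        # trophic transfer: consumer eats half producer, half PM
        ingestion = config.group("consumer").ingestion_rate * 20.0
        spec_prod = ingestion * 0.5 / 100.0
        ae = rn.ae_for("consumer")
        assert M[i["consumer"], i["producer"]] == pytest.approx(spec_prod * ae)
        spec_pm = ingestion * 0.5 / b.pm_carbon_stock
        # pm_organic -> consumer: PM grazing only (assimilated part)
        assert M[i["consumer"], i["pm_organic"]] == pytest.approx(spec_pm * ae)
        # producer -> pm_organic: egested prey tracer + producer mortality
        assert M[i["pm_organic"], i["producer"]] == pytest.approx(
            spec_prod * (1 - ae) + 2.0
        )
        # consumer -> pm_organic: mortality + K-mode feces efflux
        assert M[i["pm_organic"], i["consumer"]] == pytest.approx(0.5 + 0.3 * 8.0)

        # water -> pm_organic also carries the desorption return
        assert M[i["water"], i["pm_organic"]] == pytest.approx(k_off)

        # sediment dynamics
        settle = b.sedimentation_velocity / b.mean_depth
        assert M[i["sediment_active"], i["pm_organic"]] == pytest.approx(settle)
        assert M[i["pm_organic"], i["sediment_active"]] == pytest.approx(
            b.resuspension_rate * b.pm_organic_fraction
        )
        kd_sed = (
            b.pm_organic_fraction * rn.kd_organic
            + (1 - b.pm_organic_fraction) * rn.kd_inorganic
        )
        assert M[i["sediment_active"], i["porewater"]] == pytest.approx(
            k_off * kd_sed * b.sediment_solid_mass / b.porewater_volume
        )
        assert M[i["porewater"], i["sediment_active"]] == pytest.approx(k_off)
        assert M[i["water"], i["porewater"]] == pytest.approx(
            b.porewater_exchange_rate
        )
        assert M[i["porewater"], i["water"]] == pytest.approx(
            b.porewater_exchange_rate * b.porewater_volume / b.volume
        )

        # export sink: dissolved and PM phases at the turnover rate
        row = system.sinks.index("exported")
        for comp in ("water", "pm_organic", "pm_inorganic"):
            assert system.sink_matrix[row, i[comp]] == pytest.approx(
                1.0 / b.water_retention_time
            )
        burial_row = system.sinks.index("sediment_deep")
        assert system.sink_matrix[burial_row, i["sediment_active"]] == pytest.approx(
            b.burial_rate
        )

        # source enters the water column in K mode
        assert system.source[i["water"]] == pytest.approx(1.0)
        assert system.source.sum() == pytest.approx(1.0)

    def test_modes_differ_only_in_source_and_feces(self):
        config = small_config()
        sys_k = rc.assemble(config, "r", mode="K")
        sys_d = rc.assemble(config, "r", mode="Dlite")
        assert sys_k.compartments == sys_d.compartments
        i = {c: n for n, c in enumerate(sys_k.compartments)}
        diff = sys_k.matrix - sys_d.matrix
        feces = 0.3 * 8.0  # egestion_fraction * ingestion_rate of the consumer
        expected = np.zeros_like(diff)
        expected[i["pm_organic"], i["consumer"]] = feces
        expected[i["consumer"], i["consumer"]] = -feces
        np.testing.assert_allclose(diff, expected, atol=1e-12)
        assert sys_d.source[i["porewater"]] == pytest.approx(1.0)
        assert sys_d.source[i["water"]] == 0.0


class TestStructure:
    def test_water_only_system_is_pure_turnover(self, water_only_config):
        system = rc.assemble(water_only_config, "tracer", mode="K")
        assert system.compartments == ["water"]
        np.testing.assert_allclose(system.matrix, [[-10.0]])  # 1/tau, tau=0.1
        np.testing.assert_allclose(system.source, [1.0])

    def test_metzler_and_conservation(self, toy_config):
        for mode in ("K", "Dlite"):
            system = rc.assemble(toy_config, "Cs135", mode=mode)
            off = system.matrix - np.diag(np.diag(system.matrix))
            assert off.min() >= 0.0
            col = system.matrix.sum(axis=0) + system.sink_matrix.sum(axis=0)
            np.testing.assert_allclose(
                col, 0.0, atol=1e-9 * np.abs(system.matrix).max()
            )

    def test_decay_appears_on_every_diagonal(self, toy_config):
        config = toy_config.copy()
        lam = 0.3
        config.radionuclide("Cs135").decay_constant = lam
        base = rc.assemble(toy_config, "Cs135", mode="K")
        decayed = rc.assemble(config, "Cs135", mode="K")
        np.testing.assert_allclose(
            np.diag(decayed.matrix), np.diag(base.matrix) - lam, rtol=1e-12
        )

    def test_unknown_radionuclide_rejected(self, toy_config):
        with pytest.raises(KeyError):
            rc.assemble(toy_config, "Pu239")

    def test_trapped_compartments_detected(self):
        """Sediment with no resuspension, burial or pore-water exchange
        traps the settling tracer; the diagnostic names the dead end."""
        config = small_config()
        b = config.basins[0]
        b.resuspension_rate = 0.0
        b.burial_rate = 0.0
        b.porewater_exchange_rate = 0.0
        system = rc.assemble(config, "r", mode="K")
        trapped = trapped_compartments(system)
        assert "sediment_active" in trapped
        assert "porewater" in trapped


class TestRhs:
    def test_zero_state_gives_source(self, toy_config):
        system = rc.assemble(toy_config, "Ni59")
        state = system.zero_state()
        np.testing.assert_allclose(rhs(system, state), system.extended_source)

    def test_steady_state_gives_zero_on_live_rows(self, toy_config):
        system = rc.assemble(toy_config, "Ni59")
        steady = rc.solve_steady(system)
        deriv = rhs(system, steady)
        scale = np.abs(system.matrix @ steady.values[: system.n]).max()
        np.testing.assert_allclose(deriv[: system.n], 0.0, atol=1e-9 * scale)

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(42)
        system = random_metzler_system(rng, n=5)
        state = rng.uniform(0, 3, size=system.n + 1)
        ext = system.extended_matrix
        s = system.extended_source
        expected = np.array(
            [
                sum(ext[i, j] * state[j] for j in range(len(state))) + s[i]
                for i in range(len(state))
            ]
        )
        np.testing.assert_allclose(
            rhs(system, state), expected, rtol=1e-12
        )

    def test_dimension_mismatch_rejected(self, toy_config):
        system = rc.assemble(toy_config, "Ni59")
        with pytest.raises(ValueError, match="dimension"):
            rhs(system, np.zeros(3))


class TestInvariants:
    def test_linearity_in_source(self, toy_config):
        """Activities are homogeneous of degree 1 in the source rate."""
        doubled = toy_config.copy()
        doubled.source.rate = 2.0
        a1 = rc.solve_steady(rc.assemble(toy_config, "Cs135"))
        a2 = rc.solve_steady(rc.assemble(doubled, "Cs135"))
        np.testing.assert_allclose(a2.values[:-2], 2.0 * a1.values[:-2], rtol=1e-10)

    def test_adsorption_equilibrium_reaches_group_kd(self, adsorption_config):
        """With all transport off except adsorption, the steady biota/water
        concentration ratio equals the group's adsorption coefficient."""
        system = rc.assemble(adsorption_config, "tracer")
        steady = rc.solve_steady(system)
        g = adsorption_config.groups[0]
        kd = group_kd(adsorption_config.radionuclides[0], g)
        biota_conc = steady["plankton"] / g.biomass
        water_conc = steady["water"] / adsorption_config.basin.volume
        assert biota_conc / water_conc == pytest.approx(kd, rel=1e-9)

    def test_nonnegative_trajectories_from_metzler_structure(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            system = random_metzler_system(rng)
            traj = rc.integrate(system, duration=5.0, output_step=0.5)
            assert traj.values.min() >= -1e-12

    def test_matrix_csv_export(self, toy_config, tmp_path):
        import pandas as pd

        system = rc.assemble(toy_config, "Cs135")
        path = tmp_path / "system.csv"
        system.to_csv(path)
        table = pd.read_csv(path)
        assert {"from", "to", "rate_per_year"} == set(table.columns)
        assert (table["rate_per_year"] > 0).all()
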