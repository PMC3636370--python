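import numpy as np
import pytest

import radcomp as rc


@pytest.fixture(scope="session")
def toy_config():
    return rc.make_toy_fixture(seed=1)


@pytest.fixture(scope="session")
def toy_fluxes(toy_config):
    return rc.build_fluxes(toy_config)


@pytest.fixture(scope="session")
def adsorption_config():
    return rc.make_adsorption_only_config()


@pytest.fixture()
def water_only_config():
    """One basin, no PM, no biota, no sediment: pure turnover."""
    config = rc.make_adsorption_only_config(retention_time=0.1, volume=1.0e7)
    config.groups = []
    config.diet = {}
    return config


def random_metzler_system(rng: np.random.Generator, n: int | None = None):
    """A random small conservative Metzler system with one export sink.

    Off-diagonal rates are non-negative; every compartment reaches the
    sink through the dense coupling, so the steady state exists.
    """
    if n is None:
        n = int(rng.integers(3, 7))
    off = rng.uniform(0.0, 2.0, size=(n, n)) * (rng.random((n, n)) < 0.6)
    np.fill_diagonal(off, 0.0)
    # guarantee connectivity to the sink: a chain plus an export rate
    for i in range(n - 1):
        off[i + 1, i] += 0.5
    m = off.copy()
    export = np.zeros(n)
    export[n - 1] = rng.uniform(0.5, 2.0)
    for j in range(n):
        m[j, j] = -off[:, j].sum() - export[j]
    source = rng.uniform(0.0, 1.0, size=n)
    source[0] += 0.5  # at least one inflow
    return rc.TracerSystem(
        matrix=m,
        source=source,
        sink_matrix=export[None, :],
        compartments=[f"c{i}" for i in range(n)],
        sinks=["exported"],
    )
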