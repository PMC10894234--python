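"""Shared fixtures: small deterministic simulation runs reused across tests."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20241122)


@pytest.fixture(scope="session")
def small_open_run():
    """Open 10x10 field, 400k histories — shared by tally/transport tests."""
    from gridmc import RunConfig, simulate

    return simulate(RunConfig(n_histories=400_000, seed=11))


@pytest.fixture(scope="session")
def small_brass_run():
    """Brass-grid 10x10 field, 400k histories."""
    from gridmc import GridSpec, RunConfig, simulate

    return simulate(RunConfig(grid=GridSpec(), n_histories=400_000, seed=11))


@pytest.fixture(scope="session")
def pencil_run():
    """Near-monoenergetic 2 MeV pencil beam for transport oracles."""
    from gridmc import BeamSpec, RunConfig, simulate

    beam = BeamSpec(alpha=400.0, beta=200.0, field_size=(0.2, 0.2),
                    penumbra_margin=0.0, extra_focal_fraction=0.0)
    return simulate(RunConfig(beam=beam, n_histories=200_000, seed=5))
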