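import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import repairmap as rm

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec() -> rm.SyntheticSpec:
    """Compact noisy genome used by most recovery tests."""
    return rm.SyntheticSpec(seed=3, chrom_lengths=[("chrI", 300_000), ("chrII", 200_000)])


@pytest.fixture(scope="session")
def small_genome(small_spec):
    return rm.generate_genome(small_spec)


@pytest.fixture(scope="session")
def noise_free_spec() -> rm.SyntheticSpec:
    return rm.SyntheticSpec(
        seed=7, chrom_lengths=[("chrI", 250_000)], noise_sd=0.0, n_replicates=2
    )


@pytest.fixture(scope="session")
def noise_free_genome(noise_free_spec):
    return rm.generate_genome(noise_free_spec)


@pytest.fixture()
def flat_track() -> rm.ProbeTrack:
    layout = rm.GenomeLayout((("chrI", 50_000),))
    grid = rm.generate_probe_grid(layout, 250)
    return grid.with_values(np.zeros(len(grid)))


def make_noise_track(n_probes: int, seed: int, loc: float = 0.0, scale: float = 1.0):
    layout = rm.GenomeLayout((("chrN", n_probes * 250),))
    grid = rm.generate_probe_grid(layout, 250)
    rng = np.random.default_rng(seed)
    return grid.with_values(rng.normal(loc, scale, size=len(grid)))
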