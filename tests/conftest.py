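import numpy as np
import pytest

from epiland.landscape import LandscapeSummary, LocusSet, parse_genotype


@pytest.fixture
def loci() -> LocusSet:
    return LocusSet()


@pytest.fixture
def three_loci() -> LocusSet:
    return LocusSet(("a", "b", "c"))


def make_landscape(loci: LocusSet, env_data: dict) -> LandscapeSummary:
    """Build a summary directly from {env: {label: (mean, sd, n)}}."""
    cells = {}
    for env, table in env_data.items():
        for label, (mean, sd, n) in table.items():
            g = parse_genotype(label, loci)
            cells[(env, g.mask)] = (float(mean), float(sd), int(n))
    return LandscapeSummary(loci, cells)


def random_landscape(loci: LocusSet, seed: int, env: str = "env") -> LandscapeSummary:
    """A random complete landscape with replicate statistics, for oracle tests."""
    rng = np.random.default_rng(seed)
    cells = {}
    for mask in range(2**loci.size):
        mean = float(rng.uniform(0.5, 1.6))
        sd = float(rng.uniform(0.005, 0.08))
        cells[(env, mask)] = (mean, sd, int(rng.integers(3, 6)))
    return LandscapeSummary(loci, cells)
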