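import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from siqchip import (
    AnnotationSet,
    ExperimentMetadata,
    FragmentSet,
    SimulationDesign,
    simulate_experiment,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def example_meta():
    """Hand-checkable metadata: alpha = 0.25 * 0.1 * 2 * 1 = 0.05."""
    return ExperimentMetadata(v_in=50, v_ip=200, m_ip=10, m_in=100,
                              L=300, L_in=300, depth_ip=10_000_000, depth_in=20_000_000)


def random_fragments(rng, chrom_sizes, n, min_len=5, max_len=60) -> FragmentSet:
    """Random fragments uniformly over a small genome (test helper)."""
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    lengths = rng.integers(min_len, max_len + 1, size=n)
    which = rng.integers(0, len(chroms), size=n)
    starts = (rng.random(n) * (sizes[which] - lengths + 1)).astype(np.int64)
    return FragmentSet.from_arrays(np.array(chroms, dtype=object)[which], starts, starts + lengths)


def simple_annotations(blocks) -> AnnotationSet:
    """AnnotationSet from a list of (chrom, start, stop, state) tuples."""
    return AnnotationSet(pd.DataFrame(blocks, columns=["chrom", "start", "stop", "state"]))


@pytest.fixture(scope="session")
def small_simulation():
    """One moderately sized seeded experiment shared across tests."""
    design = SimulationDesign(genome=(("chr1", 400_000), ("chr2", 300_000)),
                              n_input_fragments=40_000, seed=11)
    return design, simulate_experiment(design)
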