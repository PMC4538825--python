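import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from phantompeaks import (
    PhantomCatalog,
    ReferenceRegions,
    SyntheticConfig,
    build_catalog,
    common_peaks,
    consensus_peaks,
    generate_world,
    simulate_peak_sets,
)


@pytest.fixture(scope="session")
def default_world():
    """The reference study conditions: 2 Mb genome, 500 genes, 2 factors."""
    return generate_world(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def default_catalog(default_world):
    """Catalog derived end-to-end from the default world (2 factors x 3 reps,
    majority-support consensus)."""
    truth = default_world
    commons = []
    for factor in truth.config.factors:
        wt = consensus_peaks(
            simulate_peak_sets(truth, "WT", factor, 3),
            min_support=2, min_overlap=50,
        )
        mut = consensus_peaks(
            simulate_peak_sets(truth, "mutant", factor, 3),
            min_support=2, min_overlap=50,
        )
        commons.append((factor, common_peaks(wt, mut, min_overlap=50).common))
    return build_catalog(commons)


@pytest.fixture(scope="session")
def default_reference(default_world):
    return ReferenceRegions.from_tss(
        default_world.genes, window_total=4000,
        chrom_sizes=default_world.config.chrom_sizes(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
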