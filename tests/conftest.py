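import numpy as np
import pytest

import nucarray as na


@pytest.fixture(scope="session")
def default_bank():
    """Full default template bank (NRL 150-210, offset 40-120, footprint 51)."""
    return na.build_bank()


@pytest.fixture(scope="session")
def small_bank():
    """Reduced bank for brute-force comparisons: NRL 160-175, offset 50-70."""
    return na.build_bank(nrl_grid=(160, 175, 1), offset_grid=(50, 70, 2))


def estimate_cohort(dataset, bank, min_len=140, max_len=160, halfwidth=25,
                    window=(0, 1000), min_coverage=50.0):
    """Run the standard analysis chain on a synthetic dataset."""
    frags = na.filter_by_length(dataset.fragments, min_len, max_len)
    track = na.build_dyad_track(frags, dataset.chrom_sizes, halfwidth)
    matrix = na.extract_profiles(track, dataset.genes, "tss", window)
    return na.estimate_all(
        matrix, bank, min_coverage=min_coverage, footprint=2 * halfwidth + 1
    )


@pytest.fixture(scope="session")
def toy_chrom_sizes():
    return {"chrI": 10000}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
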