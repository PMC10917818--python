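import numpy as np
import pytest

from faceenh.intervals import GenomicInterval, IntervalSet
from faceenh.simulate import TruthConfig, generate_truth, write_study


def random_interval_set(rng, n, chroms=("chr1", "chr2"), span=10_000, max_width=400,
                        names=None):
    ivs = []
    for i in range(n):
        start = int(rng.integers(0, span - 1))
        width = int(rng.integers(1, max_width))
        name = None if names is None else str(rng.choice(names))
        ivs.append(GenomicInterval(str(rng.choice(chroms)), start, start + width, name))
    return IntervalSet(ivs)


@pytest.fixture(scope="session")
def lossless_truth():
    """Noise-free small study: dropout 0, no jitter, no background peaks."""
    cfg = TruthConfig(
        seed=11, n_enhancers=300, n_true_pairs=50,
        peak_dropout=0.0, peak_jitter_sd=0.0, background_peak_rate=0.0,
        n_associated_snps=2000, snp_density=0.001,
    )
    return generate_truth(cfg)


@pytest.fixture(scope="session")
def lossless_study(lossless_truth, tmp_path_factory):
    d = tmp_path_factory.mktemp("lossless_study")
    write_study(d, lossless_truth)
    return d


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
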