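import numpy as np
import pytest

import polytarget as pt


@pytest.fixture(scope="session")
def small_cfg():
    """A 2-group x 4-subgenome toy genome, fast enough for every stage."""
    return pt.SimulationConfig(
        seed=11,
        n_groups=2,
        genes_per_chrom=20,
        chrom_length=120_000,
        n_planted_peaks=30,
        n_planted_indirect=40,
    )


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return pt.simulate_genome(small_cfg)


@pytest.fixture(scope="session")
def small_chip(small_cfg, small_genome):
    return pt.simulate_chip_replicates(small_cfg, small_genome)


def make_peak(chrom="chr1", start=100, end=300, summit=None, fold=5.0,
              nlq=6.0, name="p"):
    if summit is None:
        summit = (start + end) // 2
    return pt.Peak(chrom=chrom, start=start, end=end, summit=summit,
                   fold_enrichment=fold, neg_log10_q=nlq, name=name)


def make_pair(chrom="chr1", s1=200, s2=200, fold1=5.0, fold2=5.0,
              name1="a", name2="b", halfwidth=150):
    r1 = make_peak(chrom, s1 - halfwidth, s1 + halfwidth + 1, s1, fold1,
                   6.0, name1)
    r2 = make_peak(chrom, s2 - halfwidth, s2 + halfwidth + 1, s2, fold2,
                   6.0, name2)
    return pt.ReproduciblePeak(rep1=r1, rep2=r2)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
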