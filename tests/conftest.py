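import numpy as np
import pandas as pd
import pytest

from mrscreen import ScreenConfig, harmonize, synth
from mrscreen.sumstats import CANONICAL_COLUMNS, SummaryStats


def make_sumstats(trait_id, rows):
    """Build SummaryStats from a list of per-variant dicts (test shorthand)."""
    defaults = {"chrom": "1", "eaf": 0.3, "se": 0.01, "p": 1e-8, "n": 10000}
    full = []
    for i, row in enumerate(rows):
        r = {**defaults, "pos": (i + 1) * 1000, **row}
        full.append(r)
    return SummaryStats(trait_id, pd.DataFrame(full)[CANONICAL_COLUMNS])


@pytest.fixture
def mr_pair_null():
    truth = synth.make_truth(n_snps=10, theta=0.0, seed=11)
    return synth.make_mr_pair(truth), truth


@pytest.fixture
def instruments_causal():
    """Harmonized 10-SNP instrument set with a true effect of 0.05."""
    truth = synth.make_truth(n_snps=10, theta=0.05, seed=7)
    exp, out = synth.make_mr_pair(truth)
    return harmonize(exp, out), truth


@pytest.fixture(scope="session")
def small_panel():
    return synth.make_panel(n_samples=300, n_snps=40, block_size=5,
                            ld_block_rho=0.9, palindromic_frac=0.25, seed=3)


@pytest.fixture
def fast_cfg():
    return ScreenConfig(presso_sims=50, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
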