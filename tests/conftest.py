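import numpy as np
import pandas as pd
import pytest

from epiclock import (MethylationMatrix, SampleMeta, SyntheticConfig,
                      simulate_methylome)
from epiclock.io_rrbs import CpGSite


def make_matrix(meth, total, sites=None, samples=None):
    """Small helper: build a MethylationMatrix from 2-D arrays."""
    meth = np.asarray(meth)
    total = np.asarray(total)
    n, k = meth.shape
    if sites is None:
        sites = [CpGSite("chr1", 100 + 10 * i) for i in range(n)]
    if samples is None:
        samples = [f"s{j + 1}" for j in range(k)]
    return MethylationMatrix.from_records(sites, samples, meth, total)


def random_matrix(rng, n_sites=30, n_samples=6, max_cov=40, p_zero=0.15, prefix="s"):
    total = rng.integers(0, max_cov, size=(n_sites, n_samples))
    total[rng.random((n_sites, n_samples)) < p_zero] = 0
    meth = rng.binomial(total, rng.random((n_sites, 1)))
    chroms = rng.choice(["chr1", "chr2", "chr3"], size=n_sites)
    pos = rng.choice(np.arange(1000, 100000), size=n_sites, replace=False)
    sites = [CpGSite(c, int(p)) for c, p in zip(chroms, pos)]
    samples = [f"{prefix}{j + 1}" for j in range(n_samples)]
    return make_matrix(meth, total, sites=sites, samples=samples)


@pytest.fixture(scope="session")
def small_sim():
    """A modest synthetic methylome shared across read-only tests."""
    cfg = SyntheticConfig(n_sites=400, n_samples_per_group=3, seed=11)
    matrix, meta, truth = simulate_methylome(cfg)
    return cfg, matrix, meta, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def meta_four_ages():
    """16 pooled samples over the standard four ages, one tissue."""
    out = []
    for age in (0.0, 14.0, 27.0, 41.0):
        for r in range(4):
            out.append(SampleMeta(sample_id=f"a{age:g}_r{r}", age_weeks=age, tissue="liver"))
    return out
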