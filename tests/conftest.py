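import numpy as np
import pandas as pd
import pytest

from adipomethyl import simulate


@pytest.fixture(scope="session")
def small_consortium():
    """Five cohorts (scaled-down sizes), 600 CpGs, 2% causal effects."""
    configs = [
        simulate.CohortConfig(cohort_id=f"C{k}", n_samples=n, n_cpgs=600,
                              frac_causal=0.02, effect_size_sd=0.02, seed=7)
        for k, n in enumerate((200, 180, 170, 60, 110))
    ]
    return simulate.generate_consortium(configs)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_summary_stats(rng, n=8, trait="traitA"):
    """A valid random summary-statistics table."""
    pairs = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    alleles = [pairs[i] for i in rng.integers(0, len(pairs), size=n)]
    se = rng.uniform(0.01, 0.5, size=n)
    beta = rng.normal(0, 0.3, size=n)
    return pd.DataFrame({
        "variant_id": [f"rs{i}" for i in range(n)],
        "chrom": [f"chr{int(c)}" for c in rng.integers(1, 23, size=n)],
        "pos": rng.integers(1, 10**8, size=n),
        "effect_allele": [a for a, _ in alleles],
        "other_allele": [b for _, b in alleles],
        "eaf": rng.uniform(0.01, 0.99, size=n),
        "beta": beta,
        "se": se,
        "pval": rng.uniform(0, 1, size=n),
        "n": rng.integers(100, 10**6, size=n),
        "trait_id": trait,
    })
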