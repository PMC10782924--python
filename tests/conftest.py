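import numpy as np
import pytest

from pgxprs.io import LDBlock, LDBlockPanel, PGxCohort, PGxSummaryStats, VariantKey
from pgxprs.simulate import SimScenario, build_scenario


def make_variants(m, prefix="rs"):
    return [VariantKey(f"{prefix}{j+1}", "1", 1000 * (j + 1), "A", "G")
            for j in range(m)]


def random_corr(m, rng, jitter=0.1):
    if m == 1:
        return np.eye(1)
    A = rng.standard_normal((2 * m, m))
    return np.corrcoef(A.T @ A + jitter * np.eye(m))


def make_pgx_sumstats(m=10, seed=0, population="EUR", n=5000, r=0.5):
    rng = np.random.default_rng(seed)
    se = rng.uniform(0.01, 0.05, m)
    se2 = rng.uniform(0.01, 0.05, m)
    return PGxSummaryStats(
        population=population,
        variants=make_variants(m),
        beta_G=rng.normal(0, 0.05, m), se_G=se,
        p_G=rng.uniform(1e-6, 1, m),
        beta_GT=rng.normal(0, 0.05, m), se_GT=se2,
        p_GT=rng.uniform(1e-6, 1, m),
        n=n, treated_fraction=r, eaf=rng.uniform(0.05, 0.95, m),
    )


def make_panel(m=10, seed=0, population="EUR", block_size=None):
    rng = np.random.default_rng(seed + 1)
    block_size = block_size or m
    variants = make_variants(m)
    blocks = []
    for s in range(0, m, block_size):
        ids = [v.id for v in variants[s:s + block_size]]
        blocks.append(LDBlock(ids, random_corr(len(ids), rng)))
    return LDBlockPanel(population, blocks, variants)


@pytest.fixture(scope="session")
def small_bundle():
    """A modest single-population scenario shared by slower tests."""
    scn = SimScenario(m=100, block_size=50, p_causal=0.1, h2=0.3,
                      n_disease=4000, n_pgx_base=2000, n_target=800,
                      n_external_valid=400, n_reference=800, seed=11)
    return build_scenario(scn)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
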