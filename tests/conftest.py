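import numpy as np
import pandas as pd
import pytest

from nciiqtl.simdata import SimConfig, TrueGenetics, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact NCII study with additive + dominance architecture."""
    cfg = SimConfig(
        n_ril=60,
        n_chromosomes=3,
        markers_per_chrom=25,
        map_length_cM=100,
        n_env=3,
        n_rep=2,
        tester_similarity=0.5,
        residual_het_rate=0.0,
        seed=11,
    )
    m = cfg.n_chromosomes * cfg.markers_per_chrom
    rng = np.random.default_rng(101)
    a = np.zeros(m)
    d = np.zeros(m)
    a[rng.choice(m, 15, replace=False)] = rng.normal(size=15)
    d[rng.choice(m, 15, replace=False)] = rng.normal(size=15)
    truth = TrueGenetics(
        a, d, [], {"a": 1.0, "d": 0.5, "gxe": 0.2, "rep": 0.1, "residual": 0.8}
    )
    return simulate_study(cfg, truth)


@pytest.fixture(scope="session")
def hybrid_blues(small_study):
    """Pooled-hybrid genotype-mean phenotypes aligned to the coding rows."""
    pooled = small_study.pooled
    blues = small_study.records.groupby("genotype")["value"].mean()
    y = blues.reindex(pooled.hybrids).to_numpy()
    X = np.column_stack([np.ones(len(y)), pooled.population_indicator])
    return y, X


def balanced_trial_records(
    n_geno=25,
    n_env=3,
    n_rep=2,
    s2_g=10.0,
    s2_gxe=4.0,
    s2_rep=2.0,
    s2_e=8.0,
    seed=0,
    trait="t",
):
    """Balanced multi-environment records drawn from the trial model."""
    rng = np.random.default_rng(seed)
    g = rng.normal(0, np.sqrt(s2_g), n_geno) if s2_g > 0 else np.zeros(n_geno)
    ge = (
        rng.normal(0, np.sqrt(s2_gxe), (n_geno, n_env))
        if s2_gxe > 0
        else np.zeros((n_geno, n_env))
    )
    re = (
        rng.normal(0, np.sqrt(s2_rep), (n_env, n_rep))
        if s2_rep > 0
        else np.zeros((n_env, n_rep))
    )
    env_eff = rng.normal(0, 3.0, n_env)
    rows = []
    for i in range(n_geno):
        for j in range(n_env):
            for k in range(n_rep):
                eps = rng.normal(0, np.sqrt(s2_e)) if s2_e > 0 else 0.0
                rows.append(
                    {
                        "genotype": f"g{i:03d}",
                        "environment": f"e{j}",
                        "replicate": f"r{k}",
                        "trait": trait,
                        "value": 50.0 + g[i] + env_eff[j] + ge[i, j] + re[j, k] + eps,
                    }
                )
    return pd.DataFrame(rows)
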