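import numpy as np
import pandas as pd
import pytest

from roiconcord import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest default-map cohort shared by read-only tests."""
    cfg = SimConfig(n_per_group=(40, 30, 20), seed=5)
    subjects, tables = simulate_cohort(cfg)
    return cfg, subjects, tables


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def brute_force_auroc(a, b):
    """Independent AUROC oracle: count all ordered pairs, ties one half."""
    a = np.asarray(a, float)[:, None]
    b = np.asarray(b, float)[None, :]
    return ((a > b).sum() + 0.5 * (a == b).sum()) / (a.size * b.size)


def enumerate_mw_p(a, b):
    """Independent exact Mann-Whitney oracle: enumerate every assignment of
    the pooled (tie-free) sample to the two groups; two-sided p as the
    fraction of assignments with |U - n_a*n_b/2| at least as extreme."""
    from itertools import combinations

    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    assert np.unique(pooled).size == pooled.size, "oracle requires tie-free data"
    n_a, n = len(a), len(pooled)
    ranks = pooled.argsort().argsort() + 1.0
    mu = n_a * (n - n_a) / 2.0
    u_obs = brute_force_auroc(a, b) * n_a * (n - n_a)
    combos = np.array(list(combinations(range(n), n_a)))
    u_all = ranks[combos].sum(axis=1) - n_a * (n_a + 1) / 2.0
    return float(np.mean(np.abs(u_all - mu) >= abs(u_obs - mu) - 1e-12))
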