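"""Independent statistical oracles used to cross-check the stats module.

These deliberately avoid the library calls under test: the Welch statistic
and the studentized range are computed by hand, and the null distribution
comes from label permutations.
"""

import numpy as np


def welch_stat(a, b):
    va = a.var(ddof=1, axis=-1) / a.shape[-1]
    vb = b.var(ddof=1, axis=-1) / b.shape[-1]
    return (a.mean(axis=-1) - b.mean(axis=-1)) / np.sqrt(va + vb)


def perm_welch_p(a, b, n_perm=100_000, seed=0):
    """Two-sided label-permutation p-value for the Welch statistic."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pool = np.concatenate([a, b])
    n1 = a.size
    t_obs = abs(welch_stat(a, b))
    rng = np.random.default_rng(seed)
    idx = rng.permuted(np.tile(np.arange(pool.size), (n_perm, 1)), axis=1)
    x = pool[idx]
    t = welch_stat(x[:, :n1], x[:, n1:])
    return float(np.mean(np.abs(t) >= t_obs - 1e-12))


def perm_tukey_p(groups, n_perm=20_000, seed=0):
    """Permutation null of the max studentized range statistic.

    Returns a k x k matrix of p-values: the fraction of permutations whose
    maximal pairwise studentized range exceeds each observed pairwise
    statistic (equal group sizes assumed).
    """
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    n = groups[0].size
    assert all(g.size == n for g in groups)
    nu = k * n - k
    pool = np.concatenate(groups)

    def q_matrix(parts):
        means = np.array([p.mean() for p in parts])
        s2 = sum((len(p) - 1) * np.var(p, ddof=1) for p in parts) / nu
        se = np.sqrt(s2 / n)
        return np.abs(means[:, None] - means[None, :]) / se

    q_obs = q_matrix(groups)
    rng = np.random.default_rng(seed)
    exceed = np.zeros((k, k))
    for _ in range(n_perm):
        p = rng.permutation(pool)
        parts = [p[i * n:(i + 1) * n] for i in range(k)]
        exceed += (q_matrix(parts).max() >= q_obs - 1e-12)
    return exceed / n_perm
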