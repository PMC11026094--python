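"""Brute-force oracles and hand examples for the statistical primitives."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy.special import gammaincc
from scipy.stats import norm, rankdata

from tethym import stat_kernel as sk

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_spearman(x, y):
    """Pearson on mid-ranks, p from the t transform, written out by hand."""
    rx, ry = rankdata(x), rankdata(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    rho = float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))
    n = len(x)
    t = rho * math.sqrt((n - 2) / (1 - rho**2)) if abs(rho) < 1 else math.inf
    # two-sided p via the t distribution survival function (regularized beta)
    from scipy.special import betainc

    df = n - 2
    p = betainc(df / 2.0, 0.5, df / (df + t * t)) if math.isfinite(t) else 0.0
    return rho, p


def oracle_kendall_tau_b(x, y):
    """O(n^2) concordance count with tie corrections."""
    n = len(x)
    c = d = 0
    for i, j in combinations(range(n), 2):
        s = (x[i] - x[j]) * (y[i] - y[j])
        if s > 0:
            c += 1
        elif s < 0:
            d += 1
    n0 = n * (n - 1) / 2

    def ties(v):
        _, cnt = np.unique(v, return_counts=True)
        return sum(t * (t - 1) / 2 for t in cnt)

    n1, n2 = ties(x), ties(y)
    return (c - d) / math.sqrt((n0 - n1) * (n0 - n2))


def oracle_bh(p):
    """Step-up BH written out by hand."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def oracle_fisher_two_sided(table):
    """Enumerate all tables with the observed margins; sum hypergeometric
    probabilities no larger than the observed table's."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


def oracle_ks_statistic(a, b):
    """Sup distance between ECDFs by sweeping every observed value."""
    values = np.unique(np.concatenate([a, b]))
    fa = np.array([(a <= v).mean() for v in values])
    fb = np.array([(b <= v).mean() for v in values])
    return float(np.abs(fa - fb).max())


def oracle_rank_sum(a, b):
    """Normal-approximation Mann-Whitney with tie correction, no continuity."""
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    r = rankdata(pooled)
    u = r[:n1].sum() - n1 * (n1 + 1) / 2
    n = n1 + n2
    _, cnt = np.unique(pooled, return_counts=True)
    tie_term = sum(t**3 - t for t in cnt)
    var = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return u, 1.0
    z = (u - n1 * n2 / 2) / math.sqrt(var)
    return u, 2 * norm.sf(abs(z))


def oracle_chi2_gof(obs, props):
    obs = np.asarray(obs, float)
    exp = np.asarray(props, float) * obs.sum()
    stat = ((obs - exp) ** 2 / exp).sum()
    df = len(obs) - 1
    return stat, float(gammaincc(df / 2.0, stat / 2.0))


# ---------------------------------------------------------------------------
# randomized oracle-equivalence tests
# ---------------------------------------------------------------------------


def _random_pair(rng, ties=False):
    n = int(rng.integers(5, 40))
    if ties:
        x = rng.integers(0, 5, size=n).astype(float)
        y = rng.integers(0, 5, size=n).astype(float)
    else:
        x = rng.normal(size=n)
        y = rng.normal(size=n)
    return x, y


def test_spearman_matches_oracle(rng):
    for i in range(60):
        x, y = _random_pair(rng, ties=i % 2 == 0)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        rho, p = sk.spearman_rho(x, y)
        orho, op = oracle_spearman(x, y)
        assert rho == pytest.approx(orho, abs=1e-10)
        assert p == pytest.approx(op, abs=1e-8)


def test_kendall_matches_oracle(rng):
    for i in range(40):
        x, y = _random_pair(rng, ties=i % 2 == 0)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        tau, _ = sk.kendall_tau(x, y)
        assert tau == pytest.approx(oracle_kendall_tau_b(x, y), abs=1e-10)


def test_bh_matches_oracle(rng):
    for _ in range(50):
        p = rng.uniform(size=int(rng.integers(1, 30)))
        res = sk.adjust_pvalues(p, "benjamini_hochberg")
        assert np.allclose(res.adjusted, oracle_bh(p), atol=1e-12)


def test_fisher_matches_oracle(rng):
    for _ in range(50):
        tbl = rng.integers(0, 15, size=(2, 2))
        if tbl.sum() == 0:
            continue
        _, p = sk.fisher_exact_2x2(tbl)
        assert p == pytest.approx(oracle_fisher_two_sided(tbl), abs=1e-9)


def test_ks_statistic_matches_oracle(rng):
    for i in range(40):
        a = rng.normal(size=int(rng.integers(5, 50)))
        b = rng.normal(loc=0.5 * (i % 3), size=int(rng.integers(5, 50)))
        d, _ = sk.ks_two_sample(a, b)
        assert d == pytest.approx(oracle_ks_statistic(a, b), abs=1e-12)


def test_rank_sum_matches_oracle(rng):
    for i in range(40):
        a = rng.integers(0, 6, size=int(rng.integers(4, 30))).astype(float)
        b = rng.integers(0, 6, size=int(rng.integers(4, 30))).astype(float)
        u, p = sk.wilcoxon_rank_sum(a, b)
        ou, op = oracle_rank_sum(a, b)
        assert u == pytest.approx(ou, abs=1e-9)
        assert p == pytest.approx(op, abs=1e-9)


def test_chi2_gof_matches_oracle(rng):
    for _ in range(30):
        k = int(rng.integers(2, 8))
        obs = rng.integers(1, 50, size=k).astype(float)
        props = rng.uniform(0.2, 1.0, size=k)
        props /= props.sum()
        stat, p = sk.chi_squared_gof(obs, props)
        ostat, op = oracle_chi2_gof(obs, props)
        assert stat == pytest.approx(ostat, abs=1e-9)
        assert p == pytest.approx(op, abs=1e-9)


def test_spearman_matrix_matches_scalar(rng):
    X = rng.normal(size=(25, 4))
    Y = np.round(rng.normal(size=(25, 3)), 1)  # introduce ties
    rho, p = sk.spearman_matrix(X, Y)
    for i in range(4):
        for j in range(3):
            r1, p1 = sk.spearman_rho(X[:, i], Y[:, j])
            assert rho[i, j] == pytest.approx(r1, abs=1e-10)
            assert p[i, j] == pytest.approx(p1, abs=1e-8)


def test_spearman_matrix_constant_column_is_nan(rng):
    X = rng.normal(size=(10, 2))
    Y = np.column_stack([np.ones(10), rng.normal(size=10)])
    rho, _ = sk.spearman_matrix(X, Y)
    assert np.isnan(rho[:, 0]).all() and not np.isnan(rho[:, 1]).any()


# ---------------------------------------------------------------------------
# hand examples, invariants, errors
# ---------------------------------------------------------------------------


def test_bh_hand_example():
    res = sk.adjust_pvalues([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(res.adjusted, [0.04, 0.04, 0.04, 0.04])


def test_bonferroni_hand_example():
    res = sk.adjust_pvalues([0.01, 0.5], method="bonferroni")
    assert np.allclose(res.adjusted, [0.02, 1.0])


def test_adjusted_dominates_raw_and_is_capped(rng):
    for _ in range(20):
        p = rng.uniform(size=10)
        for method in ("benjamini_hochberg", "bonferroni"):
            res = sk.adjust_pvalues(p, method)
            assert np.all(res.adjusted >= res.raw - 1e-12)
            assert np.all(res.adjusted <= 1.0)


def test_adjustment_is_permutation_equivariant(rng):
    p = rng.uniform(size=15)
    perm = rng.permutation(15)
    direct = sk.adjust_pvalues(p).adjusted[perm]
    permuted = sk.adjust_pvalues(p[perm]).adjusted
    assert np.allclose(direct, permuted)


def test_empty_pvalue_vector():
    res = sk.adjust_pvalues([])
    assert res.raw.size == 0 and res.adjusted.size == 0


def test_correlations_reject_constant_input():
    with pytest.raises(ValueError):
        sk.spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])
    with pytest.raises(ValueError):
        sk.kendall_tau([1, 2, 3, 4], [2, 2, 2, 2])


def test_correlations_reject_short_or_mismatched():
    with pytest.raises(ValueError):
        sk.spearman_rho([1, 2], [3, 4])
    with pytest.raises(ValueError):
        sk.kendall_tau([1, 2, 3], [1, 2])


def test_fisher_rejects_bad_tables():
    with pytest.raises(ValueError):
        sk.fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])
    with pytest.raises(ValueError):
        sk.fisher_exact_2x2([[1, -1], [2, 3]])
    with pytest.raises(ValueError):
        sk.fisher_exact_2x2([[1.5, 1], [2, 3]])


def test_chi2_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        sk.chi_squared_gof([5], [1.0])
    with pytest.raises(ValueError):
        sk.chi_squared_gof([5, 5], [0.5, 0.4])
    with pytest.raises(ValueError):
        sk.chi_squared_gof([5, 5], [1.0, 0.0])


def test_rank_sum_fully_tied_returns_one():
    u, p = sk.wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0, 2.0])
    assert u == 3.0 and p == 1.0


def test_pvalues_outside_unit_interval_rejected():
    with pytest.raises(ValueError):
        sk.adjust_pvalues([0.5, 1.2])
    with pytest.raises(ValueError):
        sk.adjust_pvalues([0.5, np.nan])
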