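"""Conditional-inference tree: tests, splits, surrogates, full growth."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tziprisk.tree import (
    association_test,
    best_split_point,
    fit_urpss,
    select_split_feature,
    surrogate_splits,
)


def test_perfect_association_is_significant():
    rng = np.random.default_rng(0)
    y = (rng.uniform(size=60) < 0.5).astype(float)
    z, p = association_test(y.copy(), y)
    assert p < 1e-6
    assert z > 0


def test_constant_feature_convention():
    y = np.array([0, 1, 0, 1, 1, 0], dtype=float)
    z, p = association_test(np.ones(6), y)
    assert (z, p) == (0.0, 1.0)


def test_permutation_p_matches_exhaustive_enumeration():
    """On a 12-row instance the exhaustive p equals a direct enumeration
    over all label placements, written independently here."""
    rng = np.random.default_rng(5)
    x = rng.normal(size=12)
    y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0], dtype=float)
    z, p = association_test(x, y, exhaustive=True)
    g = stats.rankdata(x)
    e = g.sum() * y.sum() / 12
    t_obs = abs(g[y == 1].sum() - e)
    hits = total = 0
    for ones in itertools.combinations(range(12), int(y.sum())):
        total += 1
        hits += abs(g[list(ones)].sum() - e) >= t_obs - 1e-12
    assert p == pytest.approx(hits / total, abs=1e-15)
    # seeded Monte-Carlo permutation approximates the same value
    _, p_mc = association_test(x, y, n_permutations=4_000, seed=1)
    assert p_mc == pytest.approx(p, abs=0.03)


def test_permutation_p_uniform_under_null():
    """Independently shuffled features give uniform p-values (KS check)."""
    rng = np.random.default_rng(6)
    y = np.array([1.0] * 12 + [0.0] * 18)
    pvals = []
    for _ in range(250):
        x = rng.normal(size=30)
        _, p = association_test(x, rng.permutation(y), n_permutations=199, seed=7)
        pvals.append(p)
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_p_invariant_under_monotone_transform():
    rng = np.random.default_rng(8)
    x = rng.uniform(0.1, 5.0, size=40)
    y = (rng.uniform(size=40) < 0.4).astype(float)
    _, p1 = association_test(x, y, n_permutations=499, seed=2)
    _, p2 = association_test(np.log(x), y, n_permutations=499, seed=2)
    _, p3 = association_test(x**3, y, n_permutations=499, seed=2)
    assert p1 == p2 == p3


def test_select_informative_among_noise():
    """A single informative feature wins against 20 noise features."""
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        n = 2_000
        signal = rng.normal(size=n)
        y = (rng.uniform(size=n) < stats.norm.cdf(signal)).astype(float)
        X = pd.DataFrame({f"noise_{j}": rng.normal(size=n) for j in range(20)})
        X["signal"] = signal
        feat, p_adj, _ = select_split_feature(X, y, alpha=0.05)
        hits += feat == "signal"
    assert hits >= 19  # >= 95% of seeds


def test_all_noise_stops_at_type_i_rate():
    """Permutation p-values (add-one smoothed) give guaranteed finite-sample
    type-I control, so with all-noise features the tree stops at >= 1 - alpha."""
    stops = 0
    n_runs = 200
    for seed in range(n_runs):
        rng = np.random.default_rng(300 + seed)
        n = 300
        y = (rng.uniform(size=n) < 0.3).astype(float)
        X = pd.DataFrame({f"noise_{j}": rng.normal(size=n) for j in range(8)})
        feat, _, _ = select_split_feature(X, y, alpha=0.05, n_permutations=199, seed=seed)
        stops += feat is None
    # one-sided binomial check: the observed stop count must not contradict
    # a true stop rate of at least 1 - alpha (level 0.5%)
    assert stats.binom.cdf(stops, n_runs, 0.95) > 0.005


def test_alpha_zero_always_stops():
    rng = np.random.default_rng(9)
    y = (rng.uniform(size=200) < 0.5).astype(float)
    X = pd.DataFrame({"x": y + rng.normal(scale=0.1, size=200)})
    feat, _, _ = select_split_feature(X, y, alpha=0.0)
    assert feat is None


def test_best_split_point_matches_hand_enumeration():
    """10-row oracle: the cut maximising the standardised two-sample
    statistic, enumerated explicitly."""
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
    y = np.array([0, 0, 0, 1, 0, 1, 1, 1, 1, 1], dtype=float)
    n = len(x)
    ybar, ssy = y.mean(), np.sum((y - y.mean()) ** 2)
    best, best_z2 = None, -np.inf
    for k in range(1, n):
        t = y[:k].sum()
        v = k * (n - k) / n * ssy / (n - 1)
        z2 = (t - k * ybar) ** 2 / v
        if z2 > best_z2 + 1e-12:
            best_z2, best = z2, (x[k - 1] + x[k]) / 2
    cut, stat = best_split_point(x, y)
    assert cut == pytest.approx(best)
    assert stat == pytest.approx(np.sqrt(best_z2))


def test_split_point_degenerate_cases():
    y = np.array([0, 1, 0, 1], dtype=float)
    assert best_split_point(np.ones(4), y) == (None, 0.0)
    cut, _ = best_split_point(np.array([0.0, 0, 1, 1]), np.array([0, 0, 1, 1.0]))
    assert cut == pytest.approx(0.5)  # binary feature: unique cut


def test_surrogate_duplicate_and_independent_features():
    rng = np.random.default_rng(10)
    n = 400
    prim = rng.normal(size=n)
    X = pd.DataFrame(
        {
            "prim": prim,
            "dup": prim.copy(),
            "indep": rng.normal(size=n),
        }
    )
    surr = surrogate_splits(X, "prim", 0.0)
    assert surr[0].feature == "dup"
    assert surr[0].agreement == pytest.approx(1.0)
    indep = next(s for s in surr if s.feature == "indep")
    balance = max((prim <= 0).mean(), (prim > 0).mean())
    assert indep.agreement == pytest.approx(balance, abs=0.07)
    assert surr == sorted(surr, key=lambda s: -s.agreement)


def test_surrogate_routing_hand_trace():
    """12-row example: rows missing the primary follow the best surrogate;
    the expected routing is traced by hand."""
    prim = np.array([0.0, 1, 2, 3, 4, 5, np.nan, np.nan, np.nan, 6, 7, np.nan])
    surr = np.array([0.0, 1, 2, 3, 4, 5, 0.5, 1.5, 9.0, 6, 7, np.nan])
    # on the rows where only svc is observed its values contradict the
    # outcome, so the primary feature keeps the stronger association
    y = np.array([0, 0, 0, 1, 1, 1, 1, 1, 0, 1, 1, 0], dtype=float)
    X = pd.DataFrame({"prim": prim, "svc": surr})
    tree = fit_urpss(X, y, alpha=0.9, min_node=4, min_leaf=2, max_depth=1)
    assert tree.root_feature == "prim"
    cut = tree.root.cut
    # surrogate must mirror the primary perfectly on co-observed rows
    assert tree.root.surrogates[0].feature == "svc"
    assert tree.root.surrogates[0].agreement == pytest.approx(1.0)
    preds = tree.predict(X)
    # hand trace: rows 6, 7 have svc <= cut -> left; row 8 -> right;
    # row 11 missing both -> majority direction (left here)
    left_rate = tree.root.left.rate
    right_rate = tree.root.right.rate
    assert preds[6] == preds[7] == left_rate
    assert preds[8] == right_rate
    assert preds[11] == (left_rate if tree.root.majority_left else right_rate)


def test_tree_degenerate_and_terminal_rates(small_cohort, ref_params):
    from tziprisk.tree import build_feature_matrix

    X, y = build_feature_matrix(small_cohort, ref_params, horizon=28)
    # outcome independent of everything -> single leaf
    rng = np.random.default_rng(11)
    t0 = fit_urpss(X, rng.permutation(y), alpha=0.01)
    assert t0.root.is_leaf or t0.root.p_adj > 1e-4  # overwhelmingly a leaf
    # single-class outcome -> trivial root leaf
    t1 = fit_urpss(X.head(100), np.zeros(100))
    assert t1.root.is_leaf and t1.root.rate == 0.0
    # training predictions reproduce terminal-node outcome rates exactly
    tree = fit_urpss(X, y, alpha=0.05)
    preds = tree.predict(X)
    leaf_rates = {round(l.rate, 12) for l in tree.leaves()}
    assert {round(v, 12) for v in np.unique(preds)} <= leaf_rates


def test_partition_refines_with_depth(small_cohort, ref_params):
    """With alpha near 1, deeper limits only refine the training partition."""
    from tziprisk.tree import build_feature_matrix

    X, y = build_feature_matrix(small_cohort.head(1500), ref_params, horizon=28)
    t1 = fit_urpss(X, y, alpha=0.99, max_depth=1, min_node=50)
    t2 = fit_urpss(X, y, alpha=0.99, max_depth=3, min_node=50)
    assert len(t2.leaves()) >= len(t1.leaves())
    # same root split in both
    assert t1.root_feature == t2.root_feature
    assert t1.root.cut == t2.root.cut


def test_every_row_reaches_exactly_one_leaf(small_cohort, ref_params):
    from tziprisk.tree import build_feature_matrix

    X, y = build_feature_matrix(small_cohort, ref_params, horizon=28)
    tree = fit_urpss(X, y, alpha=0.05)
    sizes = sum(l.n for l in tree.leaves())
    assert sizes == len(X)
    preds = tree.predict(X)
    assert np.all(np.isfinite(preds))
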