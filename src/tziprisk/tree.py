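"""Unbiased recursive partitioning with surrogate splits (URPSS).

A conditional-inference classification tree for the hybrid stage: the
tZIP-based joint estimator (as a 28-day risk feature) competes against
clinical and post-discharge service-utilisation features for the root
("mother node") split of a 28-day rehospitalisation outcome.

The partitioning scheme follows the conditional-inference lineage:

1. at each node, every candidate feature is tested for association with the
   outcome by a standardised linear statistic on midrank scores (so the
   p-value is invariant under strictly monotone feature transforms), with
   rows missing that feature excluded from its test;
2. the minimum Bonferroni-adjusted p-value decides whether to split at all
   (stop when it exceeds ``alpha``), separating variable *selection* from
   cut-point search and thereby avoiding the bias toward many-valued
   features that exhaustive-search trees suffer from;
3. the cut point maximises the standardised two-sample statistic over
   observed cuts;
4. surrogate splits, ranked by agreement with the primary routing on
   co-observed rows, route records whose primary feature is logically
   missing (e.g. service timing fields that exist only for patients
   eligible for the service); rows with no usable surrogate follow the
   majority direction.

P-values are asymptotically normal by default; a seeded Monte-Carlo
permutation option and an exhaustive enumeration (for small binary-outcome
instances) are available for verification.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "build_feature_matrix",
    "association_test",
    "select_split_feature",
    "best_split_point",
    "surrogate_splits",
    "Surrogate",
    "TreeNode",
    "URPSSTree",
    "fit_urpss",
]


# ---------------------------------------------------------------------------
# Feature matrix for the hybrid stage
# ---------------------------------------------------------------------------

def build_feature_matrix(episodes: pd.DataFrame, params, horizon: float = 28.0):
    """Assemble ``(X, y)`` for the hybrid tree from an episode table.

    ``X`` holds the tZIP-based joint estimator at the horizon (``je_28d``
    for the default 28 days) next to the patient's clinical profile —
    comorbidity, diagnosis flags, ICU/surgical events — the discharge
    destination, and any post-discharge service columns (``svc_*``, NaN
    where logically missing).  The LACE inputs themselves are not in the
    pool: they enter only through the risk estimator, which is the feature
    whose marginal contribution the tree is meant to rank.  ``y`` is the
    binary within-horizon rehospitalisation label; episodes whose exposure
    is shorter than the horizon are dropped (unlabellable).  ``params`` may
    be a fit or a parameter set.
    """
    from .cohort import label_horizon
    from .risk import joint_estimator
    from .tzip import TZIPFit, linear_predictors

    if isinstance(params, TZIPFit):
        params = params.params
    labels = label_horizon(episodes, horizon)
    keep = labels.notna().to_numpy()
    sub = episodes.loc[keep]
    p, lam = linear_predictors(params, sub, float(horizon))
    je_col = f"je_{int(horizon)}d"
    X = pd.DataFrame({je_col: joint_estimator(p, lam)}, index=sub.index)
    X["comorbidity"] = sub["charlson_index"].to_numpy(dtype=float)
    for col in sub.columns:
        if col.startswith(("diag_", "icu_", "surgical_")):
            X[col] = sub[col].to_numpy(dtype=float)
    if "residence" in sub.columns:
        X["residential_care"] = (sub["residence"] == "residential_care").astype(float)
    for col in [c for c in sub.columns if c.startswith("svc_")]:
        X[col] = sub[col].to_numpy(dtype=float)
    y = labels.dropna().to_numpy(dtype=float)
    return X.reset_index(drop=True), y


# ---------------------------------------------------------------------------
# Permutation-framework association test
# ---------------------------------------------------------------------------

def _linear_stat(g: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(T, E[T], Var[T]) of T = sum g_i y_i under the permutation null."""
    n = g.size
    T = float(g @ y)
    e = float(g.sum() * y.sum() / n)
    v = float(np.sum((g - g.mean()) ** 2) * np.sum((y - y.mean()) ** 2) / (n - 1))
    return T, e, v


def association_test(
    x,
    y,
    n_permutations: int | None = None,
    exhaustive: bool = False,
    seed: int = 0,
) -> tuple[float, float]:
    """Association between one feature and a binary outcome.

    Returns ``(statistic, p_value)`` where the statistic is the standardised
    linear statistic ``(T - E[T]) / sqrt(Var[T])`` with ``T = sum rank(x_i)
    y_i`` (midranks, so ties and monotone transforms are handled).  The
    p-value is two-sided: asymptotic normal by default, Monte-Carlo
    permutation when ``n_permutations`` is given (seeded, with add-one
    smoothing), or exact enumeration over all distinct label arrangements
    when ``exhaustive`` (binary outcome only; feasible for small n).

    A constant feature (or outcome) has no permutation distribution and
    returns ``(0, 1)`` by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-d arrays")
    n = x.size
    if n < 2:
        return 0.0, 1.0
    g = stats.rankdata(x)  # midranks
    if np.ptp(g) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0
    T, e, v = _linear_stat(g, y)
    z = (T - e) / math.sqrt(v)
    t_obs = abs(T - e)

    if exhaustive:
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("exhaustive enumeration requires a binary outcome")
        k = int(y.sum())
        total = 0
        hits = 0
        # every permutation of y is a placement of the k ones; each placement
        # has equal multiplicity, so combinations enumerate the exact null
        for ones in itertools.combinations(range(n), k):
            t = abs(g[list(ones)].sum() - e)
            total += 1
            hits += t >= t_obs - 1e-12
        return z, hits / total
    if n_permutations is not None:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            t = abs(g @ rng.permutation(y) - e)
            hits += t >= t_obs - 1e-12
        return z, (hits + 1) / (n_permutations + 1)
    return z, 2.0 * stats.norm.sf(abs(z))


# ---------------------------------------------------------------------------
# Variable selection and cut-point search
# ---------------------------------------------------------------------------

def select_split_feature(
    X: pd.DataFrame,
    y: np.ndarray,
    alpha: float = 0.05,
    n_permutations: int | None = None,
    seed: int = 0,
):
    """Bonferroni-adjusted feature selection at one node.

    Tests every column of ``X`` (rows with that feature missing excluded),
    multiplies the minimum p by the number of candidates, and returns
    ``(feature, adjusted_p, per_feature_p)`` or ``(None, adjusted_p, ...)``
    to STOP when the adjusted minimum exceeds ``alpha``.  Ties break toward
    the larger absolute statistic, then column order.
    """
    y = np.asarray(y, dtype=float)
    results: dict[str, tuple[float, float]] = {}
    for j, col in enumerate(X.columns):
        xv = X[col].to_numpy(dtype=float)
        obs = ~np.isnan(xv)
        if obs.sum() < 2:
            results[col] = (0.0, 1.0)
            continue
        z, p = association_test(
            xv[obs], y[obs], n_permutations=n_permutations, seed=seed + j
        )
        results[col] = (z, p)
    m = len(X.columns)
    # order: smallest p, then largest |z|, then column order
    order = sorted(
        X.columns, key=lambda c: (results[c][1], -abs(results[c][0]), list(X.columns).index(c))
    )
    best = order[0]
    p_adj = min(1.0, results[best][1] * m)
    if p_adj > alpha:
        return None, p_adj, results
    return best, p_adj, results


def best_split_point(x, y, min_leaf: int = 1):
    """Cut point maximising the standardised two-sample statistic.

    Candidate cuts are midpoints between consecutive distinct observed
    values; each side must keep at least ``min_leaf`` rows.  Ties break
    toward the smaller cut.  Returns ``(cut, statistic)`` or ``(None, 0.0)``
    when no valid cut exists (constant feature or leaf-size limits).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2 * min_leaf or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, 0.0
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    csum = np.cumsum(ys)
    total = csum[-1]
    ybar = total / n
    ssy = float(np.sum((y - ybar) ** 2))
    # cut after position k (1-based count of left rows)
    ks = np.arange(1, n)
    valid = (xs[1:] != xs[:-1]) & (ks >= min_leaf) & (n - ks >= min_leaf)
    if not np.any(valid):
        return None, 0.0
    T = csum[:-1]
    e = ks * ybar
    v = ks * (n - ks) / n * ssy / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z2 = np.where(valid & (v > 0), (T - e) ** 2 / v, -np.inf)
    k_best = int(np.argmax(z2))  # argmax takes first max -> smaller cut
    cut = float((xs[k_best] + xs[k_best + 1]) / 2.0)
    return cut, float(math.sqrt(z2[k_best]))


# ---------------------------------------------------------------------------
# Surrogate splits
# ---------------------------------------------------------------------------

@dataclass
class Surrogate:
    feature: str
    cut: float
    #: if True, surrogate "x <= cut" routes left like the primary split
    same_direction: bool
    agreement: float


def surrogate_splits(
    X: pd.DataFrame,
    primary_feature: str,
    primary_cut: float,
    max_surrogates: int = 5,
) -> list[Surrogate]:
    """Rank other features by how well a cut on them mimics the primary.

    Agreement is measured on rows where both features are observed, in the
    better of the two orientations, and surrogates are returned in
    nonincreasing agreement order.
    """
    pv = X[primary_feature].to_numpy(dtype=float)
    prim_obs = ~np.isnan(pv)
    left = pv <= primary_cut
    out: list[Surrogate] = []
    for col in X.columns:
        if col == primary_feature:
            continue
        xv = X[col].to_numpy(dtype=float)
        both = prim_obs & ~np.isnan(xv)
        nb = int(both.sum())
        if nb < 2 or np.ptp(xv[both]) == 0:
            continue
        xs_idx = np.argsort(xv[both], kind="stable")
        xs = xv[both][xs_idx]
        ls = left[both][xs_idx].astype(float)
        n_left = ls.sum()
        cum_left = np.cumsum(ls)
        ks = np.arange(1, nb)
        valid = xs[1:] != xs[:-1]
        if not np.any(valid):
            continue
        # orientation "same": x<=cut -> left; matches = left in prefix + right in suffix
        match_same = cum_left[:-1] + ((nb - ks) - (n_left - cum_left[:-1]))
        match_flip = nb - match_same
        match = np.maximum(match_same, match_flip)
        match = np.where(valid, match, -1)
        k_best = int(np.argmax(match))
        agreement = match[k_best] / nb
        out.append(
            Surrogate(
                feature=col,
                cut=float((xs[k_best] + xs[k_best + 1]) / 2.0),
                same_direction=bool(match_same[k_best] >= match_flip[k_best]),
                agreement=float(agreement),
            )
        )
    out.sort(key=lambda s: -s.agreement)
    return out[:max_surrogates]


# ---------------------------------------------------------------------------
# Tree fitting
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    node_id: int
    n: int
    rate: float  # outcome prevalence among routed rows
    feature: str | None = None
    cut: float | None = None
    p_adj: float | None = None
    statistic: float | None = None
    surrogates: list[Surrogate] = field(default_factory=list)
    majority_left: bool = True
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        d = {
            "node_id": self.node_id,
            "n": self.n,
            "rate": self.rate,
        }
        if not self.is_leaf:
            d.update(
                {
                    "feature": self.feature,
                    "cut": self.cut,
                    "p_adj": self.p_adj,
                    "statistic": self.statistic,
                    "majority_left": self.majority_left,
                    "surrogates": [
                        {
                            "feature": s.feature,
                            "cut": s.cut,
                            "same_direction": s.same_direction,
                            "agreement": s.agreement,
                        }
                        for s in self.surrogates
                    ],
                    "left": self.left.to_dict(),
                    "right": self.right.to_dict(),
                }
            )
        return d


def _route_left(node: TreeNode, X: pd.DataFrame) -> np.ndarray:
    """Vectorised left/right routing with surrogate and majority fallback."""
    xv = X[node.feature].to_numpy(dtype=float)
    go_left = np.where(np.isnan(xv), node.majority_left, xv <= node.cut)
    unresolved = np.isnan(xv)
    for s in node.surrogates:
        if not unresolved.any():
            break
        if s.feature not in X.columns:
            continue
        sv = X[s.feature].to_numpy(dtype=float)
        usable = unresolved & ~np.isnan(sv)
        sl = sv[usable] <= s.cut
        go_left[usable] = sl if s.same_direction else ~sl
        unresolved &= ~usable
    return go_left.astype(bool)


@dataclass
class URPSSTree:
    root: TreeNode
    features: list[str]
    alpha: float
    selection_order: list[str]  # features by root-ward first appearance

    @property
    def root_feature(self) -> str | None:
        return self.root.feature

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Terminal-node outcome rates for each row (surrogate routing)."""
        X = X.reset_index(drop=True)
        out = np.empty(len(X))

        def rec(node: TreeNode, idx: np.ndarray) -> None:
            if node.is_leaf:
                out[idx] = node.rate
                return
            go_left = _route_left(node, X.iloc[idx])
            rec(node.left, idx[go_left])
            rec(node.right, idx[~go_left])

        rec(self.root, np.arange(len(X)))
        return out

    def leaves(self) -> list[TreeNode]:
        acc: list[TreeNode] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            if nd.is_leaf:
                acc.append(nd)
            else:
                stack.extend([nd.right, nd.left])
        return acc

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "features": self.features,
            "selection_order": self.selection_order,
            "root": self.root.to_dict(),
        }

    def render(self) -> str:
        lines: list[str] = []

        def rec(node: TreeNode, indent: str) -> None:
            if node.is_leaf:
                lines.append(f"{indent}[{node.node_id}] leaf n={node.n} rate={node.rate:.3f}")
            else:
                lines.append(
                    f"{indent}[{node.node_id}] {node.feature} <= {node.cut:.4g} "
                    f"(p_adj={node.p_adj:.3g}, n={node.n})"
                )
                rec(node.left, indent + "  ")
                rec(node.right, indent + "  ")

        rec(self.root, "")
        return "\n".join(lines)


def fit_urpss(
    X: pd.DataFrame,
    y,
    alpha: float = 0.05,
    min_node: int = 20,
    min_leaf: int = 7,
    max_depth: int | None = None,
    max_surrogates: int = 5,
    n_permutations: int | None = None,
    seed: int = 0,
    features: Sequence[str] | None = None,
) -> URPSSTree:
    """Grow the conditional-inference tree.

    ``X`` may contain NaN for (systematically) missing features; ``y`` is a
    binary outcome.  Fully reproducible given ``seed`` (which only matters
    when Monte-Carlo permutation p-values are requested).  A degenerate
    outcome yields a single root leaf.
    """
    if features is not None:
        X = X[list(features)]
    X = X.reset_index(drop=True)
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(X) != y.size:
        raise ValueError("X and y must be aligned")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary")
    counter = itertools.count()
    selection_order: list[str] = []

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        node = TreeNode(
            node_id=next(counter), n=idx.size, rate=float(y[idx].mean())
        )
        if (
            idx.size < min_node
            or np.ptp(y[idx]) == 0
            or (max_depth is not None and depth >= max_depth)
        ):
            return node
        sub = X.iloc[idx]
        feat, p_adj, _ = select_split_feature(
            sub, y[idx], alpha=alpha, n_permutations=n_permutations, seed=seed + depth
        )
        if feat is None:
            return node
        xv = sub[feat].to_numpy(dtype=float)
        obs = ~np.isnan(xv)
        cut, stat = best_split_point(xv[obs], y[idx][obs], min_leaf=min_leaf)
        if cut is None:
            return node
        node.feature, node.cut, node.p_adj, node.statistic = feat, cut, p_adj, stat
        node.surrogates = surrogate_splits(sub, feat, cut, max_surrogates)
        if feat not in selection_order:
            selection_order.append(feat)
        # majority direction comes from rows whose primary feature is observed
        node.majority_left = bool((xv[obs] <= cut).mean() >= 0.5)
        go_left = _route_left(node, sub)
        left_idx, right_idx = idx[go_left], idx[~go_left]
        if left_idx.size == 0 or right_idx.size == 0:
            node.feature = None  # routing failed to partition: make a leaf
            return node
        node.left = grow(left_idx, depth + 1)
        node.right = grow(right_idx, depth + 1)
        return node

    root = grow(np.arange(len(X)), 0)
    return URPSSTree(
        root=root,
        features=list(X.columns),
        alpha=alpha,
        selection_order=selection_order,
    )
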