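"""Univariate statistics and clustering: Welch pre-filter, Holm-Bonferroni,
Kruskal-Wallis across stages, and Spearman-distance complete-linkage trees."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    metabolite_id: str
    statistic: float
    df: float
    p_value: float
    adjusted_p: float | None = None
    fold_change: float | None = None


def welch_t_test(x, y, metabolite_id: str = "") -> TestResult:
    """Two-sided Welch's t-test (unequal variances, Welch-Satterthwaite df).

    Scale-equivariant: multiplying both groups by a constant leaves t, df and
    p unchanged. Requires >= 2 values per group and variance in at least one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t_test requires >= 2 values per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return TestResult(metabolite_id, 0.0, float(len(x) + len(y) - 2), 1.0)
        raise ValueError("both groups have zero variance with unequal means")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    # Welch–Satterthwaite degrees of freedom
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    return TestResult(metabolite_id, float(t), float(df), float(p))


def prefilter(X, labels, p_max: float = 0.30) -> list:
    """Welch pre-filter: keep metabolites with two-group p <= ``p_max``.

    ``X`` is a samples x metabolites frame (typically log-autoscaled, the
    same data the multivariate model sees); ``labels`` a two-class vector.
    The inclusive boundary follows the "maximum p-value threshold" reading.
    Output preserves input column order.
    """
    X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"prefilter requires exactly two classes, got {len(classes)}")
    a = X.loc[np.asarray(labels == classes[0])]
    b = X.loc[np.asarray(labels == classes[1])]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs >= 2 samples")
    t, p = stats.ttest_ind(a.to_numpy(), b.to_numpy(), axis=0, equal_var=False)
    keep = np.nan_to_num(p, nan=1.0) <= p_max
    return [c for c, k in zip(X.columns, keep) if k]


def holm_bonferroni(p_values, alpha: float = 0.05):
    """Step-down Holm procedure; returns (reject flags, adjusted p-values).

    Adjusted p-values are monotone and the rejection set is a prefix of the
    sorted p order; Holm rejects a superset of plain Bonferroni at equal
    alpha. Delegates to the standard step-down implementation.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, adjusted


def kruskal_wallis(groups, metabolite_id: str = "") -> TestResult:
    """Kruskal-Wallis H test with tie correction, chi-square p with k-1 df.

    Rank-based, hence invariant to monotone transforms of the pooled values.
    All-equal observations give H = 0, p = 1 by convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("total n must be >= 3")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(metabolite_id, 0.0, float(len(groups) - 1), 1.0)
    h, p = stats.kruskal(*groups)
    return TestResult(metabolite_id, float(h), float(len(groups) - 1), float(p))


def kruskal_wallis_table(X, labels, alpha: float = 0.05) -> pd.DataFrame:
    """Per-metabolite Kruskal-Wallis across groups with Bonferroni adjustment."""
    X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    rows = []
    for col in X.columns:
        vals = X[col]
        res = kruskal_wallis([vals[labels == g].to_numpy() for g in pd.unique(labels)], col)
        rows.append((col, res.statistic, res.df, res.p_value))
    out = pd.DataFrame(rows, columns=["metabolite_id", "H", "df", "p_value"]).set_index("metabolite_id")
    m = len(out)
    out["adjusted_p"] = np.minimum(out["p_value"] * m, 1.0)
    out["significant"] = out["adjusted_p"] <= alpha
    return out


def spearman_distance_matrix(X) -> np.ndarray:
    """Pairwise 1 - Spearman rho between the columns of ``X``."""
    X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    sds = X.std(axis=0, ddof=0)
    constant = sds[sds == 0]
    if len(constant):
        raise ValueError(
            f"constant items (Spearman rho undefined): {list(constant.index)}"
        )
    rho = stats.spearmanr(X.to_numpy(), axis=0).statistic
    rho = np.atleast_2d(rho)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d[d < 0] = np.maximum(d[d < 0], 0.0)
    return d


def spearman_complete_linkage(X) -> np.ndarray:
    """Complete-linkage agglomeration on 1 - Spearman rho distances.

    Returns the standard 4-column merge table (scipy linkage format). Items
    are the columns of ``X``; requires >= 3 observations per item. Ties are
    broken deterministically by lowest pair index (the distance-matrix
    ordering the agglomeration consumes).
    """
    X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    if X.shape[1] < 2:
        raise ValueError("need >= 2 items to cluster")
    if X.shape[0] < 3:
        raise ValueError("need >= 3 observations per item")
    d = spearman_distance_matrix(X)
    return linkage(squareform(d, checks=False), method="complete")


def group_fold_change(x, y) -> float:
    """Ratio of group means on the raw concentration scale."""
    my = float(np.mean(y))
    return float(np.mean(x)) / my if my != 0 else np.inf
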