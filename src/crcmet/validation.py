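"""Model validation: cross-validated Q2, CV-ANOVA, permutation diagnostics,
and external-validation metrics (confusion table, AUROC with DeLong CI).

Two permutation schemes are provided. The model-level test permutes class
labels with the feature set and model structure frozen, refits, and reports
the Q2-intercept of a line through (label correlation, Q2) points — a model
counts as valid and non-random when that intercept is at or below zero. The
pre-analysis test re-runs the entire discovery procedure (feature selection
included) per permutation and reports add-one empirical p-values for Q2 and
RMSEP against the permutation distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone


# ---------------------------------------------------------------------------
# cross-validated Q2
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    folds: int
    press: float
    ss_tot: float
    q2y: float
    residuals: np.ndarray
    fold_assignment: np.ndarray
    fold_press: np.ndarray


def _encode_labels(y):
    """Dummy-code labels: a {0,1} vector for two classes, indicator matrix otherwise."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if len(classes) == 2:
        return (y == classes[1]).astype(float), classes
    return np.column_stack([(y == c).astype(float) for c in classes]), classes


def stratified_folds(y, folds: int, seed: int) -> np.ndarray:
    """Seeded class-stratified round-robin fold assignment (a partition)."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=int)
    start = 0
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        assignment[idx] = (np.arange(len(idx)) + start) % folds
        start += len(idx)
    return assignment


def q2_cv(estimator, X, y, folds: int = 7, seed: int = 0) -> CvResult:
    """Q2Y = 1 - PRESS/SS_tot under seeded, class-stratified k-fold CV.

    The estimator is refit per fold with its hyperparameters fixed; PRESS
    accumulates squared residuals of held-out continuous predictions against
    the dummy-coded labels. SS_tot is taken around the full-data label mean.
    """
    X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    y = np.asarray(y)
    n = len(y)
    if n < folds:
        raise ValueError(f"n={n} < folds={folds}")
    y_enc, classes = _encode_labels(y)
    assignment = stratified_folds(y, folds, seed)
    residuals = np.zeros_like(y_enc, dtype=float)
    fold_press = np.zeros(folds)
    for k in range(folds):
        test = assignment == k
        train = ~test
        counts = [int(np.sum(y[train] == c)) for c in classes]
        if min(counts) < 2:
            raise ValueError(
                f"fold {k}: training split leaves a class with {min(counts)} "
                "samples; use fewer folds"
            )
        est = clone(estimator).fit(X.loc[train], y[train])
        y_hat = est.decision_function(X.loc[test])
        res = y_enc[test] - np.asarray(y_hat)
        residuals[test] = res
        fold_press[k] = float(np.sum(res**2))
    press = float(fold_press.sum())
    ss_tot = float(np.sum((y_enc - y_enc.mean(axis=0)) ** 2))
    return CvResult(folds, press, ss_tot, 1.0 - press / ss_tot, residuals, assignment, fold_press)


def cv_anova(cv: CvResult, n_components_total: int):
    """F-test of cross-validated residuals against variation around the mean.

    F = ((SS_tot - PRESS)/df1) / (PRESS/df2) with df1 = total model
    components and df2 = n - components - 1; p from the F distribution.
    These degrees of freedom are a documented approximation of the
    proprietary accounting in commercial chemometrics software.
    """
    n = len(np.ravel(cv.residuals)) if cv.residuals.ndim == 1 else cv.residuals.shape[0]
    df1 = n_components_total
    df2 = n - n_components_total - 1
    if df2 <= 0:
        raise ValueError(f"df2 = n - components - 1 = {df2} must be positive")
    f = ((cv.ss_tot - cv.press) / df1) / (cv.press / df2)
    p = float(stats.f.sf(f, df1, df2)) if f > 0 else 1.0
    return float(f), df1, df2, p


# ---------------------------------------------------------------------------
# permutation schemes
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    n_iterations: int
    label_correlations: np.ndarray
    q2_values: np.ndarray
    rmsep_values: np.ndarray
    observed_q2: float
    observed_rmsep: float
    q2_intercept: float | None = None
    q2_slope: float | None = None
    valid: bool | None = None
    p_q2: float | None = None
    p_rmsep: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(1, self.n_iterations + 1),
                "label_correlation": self.label_correlations,
                "q2": self.q2_values,
                "rmsep": self.rmsep_values,
            }
        )


def q2_intercept_line(r_values, q2_values):
    """Least-squares line through (label correlation, Q2) points.

    Returns (slope, intercept); the intercept at r = 0 is the permutation
    validity statistic.
    """
    xs = np.asarray(r_values, dtype=float)
    ys = np.asarray(q2_values, dtype=float)
    if len(xs) < 3:
        raise ValueError("line fit needs >= 3 points")
    slope, intercept = np.polyfit(xs, ys, 1)
    return float(slope), float(intercept)


def permutation_q2_intercept(estimator, X, y, n: int = 999, seed: int = 0,
                             folds: int = 7) -> PermutationResult:
    """Label-permutation test with frozen model structure; Q2-intercept rule.

    Per iteration the labels are permuted, |Pearson r| between the permuted
    and original dummy-coded labels is recorded, the model is refit and its
    cross-validated Q2 recomputed. A least-squares line through all
    permutation points plus the unpermuted point (r = 1, Q2_model) gives the
    Q2-intercept at r = 0; the model is flagged valid iff the intercept is
    at or below zero.
    """
    if n < 20:
        raise ValueError("n < 20 permutations gives an unstable intercept")
    X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    y = np.asarray(y)
    y_enc, _ = _encode_labels(y)
    if y_enc.ndim != 1:
        raise ValueError("Q2-intercept permutation is defined for two-class labels")
    rng = np.random.default_rng(seed)
    obs_cv = q2_cv(estimator, X, y, folds=folds, seed=seed)
    obs_q2 = obs_cv.q2y
    obs_rmsep = float(np.sqrt(obs_cv.press / len(y)))
    rs, q2s, rmseps = np.empty(n), np.empty(n), np.empty(n)
    for i in range(n):
        perm = rng.permutation(len(y))
        y_p = y[perm]
        rs[i] = abs(float(np.corrcoef(y_enc, y_enc[perm])[0, 1]))
        cv = q2_cv(estimator, X, y_p, folds=folds, seed=seed)
        q2s[i] = cv.q2y
        rmseps[i] = np.sqrt(cv.press / len(y))
    slope, intercept = q2_intercept_line(
        np.concatenate([rs, [1.0]]), np.concatenate([q2s, [obs_q2]])
    )
    p_q2 = (1 + int(np.sum(q2s >= obs_q2))) / (n + 1)
    p_rmsep = (1 + int(np.sum(rmseps <= obs_rmsep))) / (n + 1)
    return PermutationResult(
        n_iterations=n, label_correlations=rs, q2_values=q2s, rmsep_values=rmseps,
        observed_q2=obs_q2, observed_rmsep=obs_rmsep,
        q2_intercept=float(intercept), q2_slope=float(slope),
        valid=bool(intercept <= 0), p_q2=p_q2, p_rmsep=p_rmsep,
    )


def label_permutation_test(fit_and_score, X, y, n: int = 10_000, seed: int = 0) -> PermutationResult:
    """Pre-analysis class-permutation test with discovery re-run per iteration.

    ``fit_and_score(X, y) -> (q2, rmsep)`` must execute the full discovery
    procedure — feature selection included — so selection bias is inside the
    permutation loop. Empirical p-values use the add-one estimator
    (1 + #{as extreme}) / (n + 1), which never returns zero.
    """
    X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    y = np.asarray(y)
    y_enc, _ = _encode_labels(y)
    rng = np.random.default_rng(seed)
    obs_q2, obs_rmsep = fit_and_score(X, y)
    rs, q2s, rmseps = np.empty(n), np.empty(n), np.empty(n)
    for i in range(n):
        perm = rng.permutation(len(y))
        y_p = y[perm]
        if y_enc.ndim == 1:
            rs[i] = abs(float(np.corrcoef(y_enc, y_enc[perm])[0, 1]))
        else:
            rs[i] = np.nan
        q2s[i], rmseps[i] = fit_and_score(X, y_p)
    p_q2 = (1 + int(np.sum(q2s >= obs_q2))) / (n + 1)
    p_rmsep = (1 + int(np.sum(rmseps <= obs_rmsep))) / (n + 1)
    return PermutationResult(
        n_iterations=n, label_correlations=rs, q2_values=q2s, rmsep_values=rmseps,
        observed_q2=float(obs_q2), observed_rmsep=float(obs_rmsep),
        p_q2=p_q2, p_rmsep=p_rmsep,
    )


# ---------------------------------------------------------------------------
# external-validation metrics
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(Decimal(str(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    precision: float | None
    undefined: list = field(default_factory=list)

    @property
    def percentages(self) -> dict:
        """Report-display percentages, rounded half-up to the nearest integer."""
        out = {}
        for name in ("sensitivity", "specificity", "accuracy", "precision"):
            v = getattr(self, name)
            out[name] = None if v is None else _round_half_up(100 * v)
        return out


def confusion_metrics(y_true, y_pred, positive_label=None) -> ConfusionMetrics:
    """Confusion counts and sensitivity/specificity/accuracy/precision.

    Metrics with an empty denominator are flagged undefined (None) rather
    than propagated as NaN. Raw ratios are retained; integer percentages for
    display round half away from zero.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    if positive_label is None:
        positive_label = np.unique(y_true)[-1]
    t = y_true == positive_label
    p = y_pred == positive_label
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    tn = int(np.sum(~t & ~p))
    fn = int(np.sum(t & ~p))
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    return ConfusionMetrics(
        tp, fp, tn, fn,
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        accuracy=ratio(tp + tn, tp + fp + tn + fn, "accuracy"),
        precision=ratio(tp, tp + fp, "precision"),
        undefined=undefined,
    )


def auroc(scores, labels, positive_label=None, ci_method: str = "delong"):
    """AUROC from the Mann-Whitney statistic with tie correction, plus 95% CI.

    The point estimate is the probability a random positive outscores a
    random negative (ties count half), computed from midranks, so it is
    invariant to strictly monotone transforms of the scores. The CI is the
    DeLong structural-components estimate, truncated to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if positive_label is None:
        positive_label = classes[-1]
    pos = scores[labels == positive_label]
    neg = scores[labels != positive_label]
    m, n = len(pos), len(neg)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    auc = (np.sum(ranks[:m]) - m * (m + 1) / 2) / (m * n)
    if ci_method != "delong":
        raise ValueError(f"unknown ci_method: {ci_method!r}")
    # DeLong structural components via midranks
    tx = ranks[:m]
    ty = ranks[m:]
    txx = stats.rankdata(pos)
    tyy = stats.rankdata(neg)
    v01 = (tx - txx) / n          # per-positive placement values
    v10 = 1.0 - (ty - tyy) / m    # per-negative placement values
    if m > 1 and n > 1:
        var = np.var(v01, ddof=1) / m + np.var(v10, ddof=1) / n
    else:
        var = 0.0
    half = 1.959963984540054 * np.sqrt(var)
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


@dataclass
class ValidationReport:
    """Bundle of external/internal validation diagnostics for one model."""

    confusion: ConfusionMetrics | None = None
    auroc: float | None = None
    auroc_ci: tuple | None = None
    cv_anova_f: float | None = None
    cv_anova_df: tuple | None = None
    cv_anova_p: float | None = None
    r2y: float | None = None
    q2y: float | None = None
    r2q2_gap_flag: bool | None = None

    def flag_gap(self, threshold: float = 0.2) -> bool:
        """Re-evaluation flag: R2Y - Q2Y exceeding the threshold marks overfit risk."""
        if self.r2y is None or self.q2y is None:
            raise ValueError("r2y and q2y must be set")
        self.r2q2_gap_flag = bool(self.r2y - self.q2y > threshold)
        return self.r2q2_gap_flag

    def to_dict(self) -> dict:
        out = {
            "auroc": self.auroc,
            "auroc_ci": list(self.auroc_ci) if self.auroc_ci else None,
            "cv_anova_f": self.cv_anova_f,
            "cv_anova_df": list(self.cv_anova_df) if self.cv_anova_df else None,
            "cv_anova_p": self.cv_anova_p,
            "r2y": self.r2y,
            "q2y": self.q2y,
            "r2q2_gap_flag": self.r2q2_gap_flag,
        }
        if self.confusion is not None:
            out["confusion"] = {
                "tp": self.confusion.tp, "fp": self.confusion.fp,
                "tn": self.confusion.tn, "fn": self.confusion.fn,
                "raw": {
                    "sensitivity": self.confusion.sensitivity,
                    "specificity": self.confusion.specificity,
                    "accuracy": self.confusion.accuracy,
                    "precision": self.confusion.precision,
                },
                "percent": self.confusion.percentages,
            }
        return out
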