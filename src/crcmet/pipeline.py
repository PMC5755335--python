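"""Workflow orchestration: discovery, platform fusion, stage model, external
validation.

The discovery workflow re-enacts the study design end to end: QC/LOD gating
and imputation define the analyzable matrix; median fold-change
normalization, log transform and autoscaling are fitted on training samples
only; PCA screens training outliers at the Hotelling T2 99% limit; a Welch
pre-filter (p <= 0.30) removes clearly uninformative metabolites; OPLS-DA is
fitted and refined by a VIP threshold chosen to maximize cross-validated Q2Y
with a minimal R2Y-Q2Y gap; the surviving model is validated by 7-fold CV,
CV-ANOVA and label permutations. Validation samples only ever pass through
frozen training-state transforms.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io_tables import (
    ConcentrationTable,
    impute_missing,
    lod_filter,
    qc_cov_filter,
    validate_annotations,
)
from .latent_models import NipalsPCA, OPLSDA, PLSDA, hotelling_outliers
from .preprocess import LogAutoscaler, MedianFoldChangeNormalizer, block_scale
from .univariate import kruskal_wallis_table, prefilter
from .validation import (
    PermutationResult,
    ValidationReport,
    auroc,
    confusion_metrics,
    cv_anova,
    label_permutation_test,
    permutation_q2_intercept,
    q2_cv,
)

DEFAULT_VIP_GRID = tuple(np.round(np.arange(0.5, 1.5001, 0.05), 2))


@dataclass
class PipelineConfig:
    """Tunable thresholds of the workflow; defaults are the study settings."""

    prefilter_p_max: float = 0.30
    qc_cov_max: float = 0.25
    lod_min_detect: float = 0.5
    impute_strategy: str = "per_metabolite_min"
    cv_folds: int = 7
    n_perm_model: int = 999
    n_perm_class: int = 10_000
    pca_max_components: int = 3
    outlier_level: float = 0.99
    r2q2_gap_flag: float = 0.2
    alpha: float = 0.05
    vip_grid: tuple = DEFAULT_VIP_GRID
    vip_q2_tolerance: float = 0.05
    n_orth: object = 1
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.prefilter_p_max <= 1:
            raise ValueError("prefilter_p_max must lie in [0, 1]")
        if not 0 < self.outlier_level < 1:
            raise ValueError("outlier_level must lie in (0, 1)")


def _digest(obj) -> str:
    if isinstance(obj, pd.DataFrame):
        payload = obj.to_csv().encode()
    else:
        payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


class SelectingOPLSDA(BaseEstimator):
    """OPLS-DA with the discovery feature selection re-run inside ``fit``.

    Applies the Welch pre-filter (p <= ``p_max``) and the VIP cut at a fixed
    ``vip_threshold`` to whatever training data it is given, then fits
    OPLS-DA on the surviving metabolites. Cloning this estimator inside
    cross-validation or permutation loops therefore re-selects features from
    each training split, so selection bias cannot masquerade as predictive
    power. Thresholds are hyperparameters and stay fixed; the selected
    metabolite set does not. Falls back to all pre-filtered metabolites when
    the VIP cut would leave fewer than two.
    """

    def __init__(self, p_max: float = 0.30, vip_threshold: float = 1.0,
                 n_orth=1, cv_folds: int = 7, random_state: int = 0):
        self.p_max = p_max
        self.vip_threshold = vip_threshold
        self.n_orth = n_orth
        self.cv_folds = cv_folds
        self.random_state = random_state

    def fit(self, X, y):
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        feats = prefilter(X, y, self.p_max)
        if len(feats) < 2:
            feats = list(X.columns)
        Xf = X.loc[:, feats]
        initial = OPLSDA(n_orth=self.n_orth, cv_folds=self.cv_folds,
                         random_state=self.random_state).fit(Xf, y)
        vips = pd.Series(initial.vip_, index=Xf.columns)
        selected = list(vips.index[vips >= self.vip_threshold])
        if len(selected) < 2:
            selected = feats
        self.selected_ids_ = selected
        self.model_ = OPLSDA(n_orth=initial.n_orth_, cv_folds=self.cv_folds,
                             random_state=self.random_state).fit(Xf.loc[:, selected], y)
        return self

    def decision_function(self, X):
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        return self.model_.decision_function(X.loc[:, self.selected_ids_])

    def predict(self, X):
        return self.model_.classes_[(self.decision_function(X) >= 0.5).astype(int)]


@dataclass
class VipSelection:
    threshold: float
    r2y: float
    q2y: float
    n_features: int
    grid: list = field(default_factory=list)  # (threshold, r2y, q2y, n) per candidate


def select_vip_threshold(X, y, vips: pd.Series, grid, n_orth, cv_folds: int, seed: int,
                         q2_tolerance: float = 0.05) -> VipSelection:
    """Choose the VIP refinement threshold from cross-validated (R2Y, Q2Y).

    For each candidate threshold the model is refit on metabolites with
    VIP >= threshold and (R2Y, Q2Y) recorded. Q2Y differences smaller than
    the resampling noise of k-fold CV should not drive feature elimination,
    so thresholds whose Q2Y lies within ``q2_tolerance`` of the grid maximum
    are treated as equivalent; among those the most inclusive model (largest
    feature count, hence maximal R2Y) is preferred, then the smallest
    R2Y - Q2Y gap, then the smallest threshold. Thresholds leaving < 2
    metabolites are skipped. A singleton grid (e.g. the fixed VIP > 1 rule)
    is returned unconditionally.
    """
    records = []
    for thr in grid:
        feats = list(vips.index[vips >= thr])
        if len(feats) < 2:
            records.append((float(thr), None, None, len(feats)))
            continue
        model = OPLSDA(n_orth=n_orth, cv_folds=cv_folds, random_state=seed)
        fitted = OPLSDA(n_orth=n_orth, cv_folds=cv_folds, random_state=seed).fit(X.loc[:, feats], y)
        q2 = q2_cv(model, X.loc[:, feats], y, folds=cv_folds, seed=seed).q2y
        records.append((float(thr), fitted.r2y_, q2, len(feats)))
    usable = [r for r in records if r[1] is not None]
    if not usable:
        raise ValueError("no VIP threshold leaves >= 2 metabolites")
    q2_max = max(r[2] for r in usable)
    candidates = [r for r in usable if r[2] >= q2_max - q2_tolerance]
    best = min(candidates, key=lambda r: (-r[3], r[1] - r[2], r[0]))
    return VipSelection(threshold=best[0], r2y=best[1], q2y=best[2], n_features=best[3], grid=records)


class DiscoveryPipeline(BaseEstimator):
    """End-to-end biomarker discovery for one two-group contrast.

    ``fit(table, annotations, contrast)`` runs the staged workflow on the
    training-set samples of the two contrast arms and freezes every learned
    statistic for later external validation. The second contrast element is
    the case (positive) class.
    """

    def __init__(self, config: PipelineConfig | None = None, run_permutation: bool = False):
        self.config = config
        self.run_permutation = run_permutation

    # -- helpers -----------------------------------------------------------

    def _log(self, stage: str, **info) -> None:
        self.provenance_.append({"stage": stage, **info})

    def fit(self, table: ConcentrationTable, annotations, contrast=("control", "CRC")):
        cfg = self.config or PipelineConfig()
        self.config_ = cfg
        self.contrast_ = tuple(contrast)
        self.provenance_ = []
        ann = validate_annotations(annotations, table)
        study_ids = [s for s in table.sample_ids if not ann.loc[s, "is_qc"]]
        train_ids = [
            s for s in study_ids
            if ann.loc[s, "set"] == "train" and ann.loc[s, "group"] in contrast
        ]
        if not train_ids:
            raise ValueError("no training samples for the requested contrast")

        # LOD screen uses all study samples (detectability is label-free)
        study_table = table.subset_samples(study_ids + [s for s in table.sample_ids if ann.loc[s, "is_qc"]])
        lod_table, self.lod_report_ = lod_filter(study_table, cfg.lod_min_detect)
        self._log("lod_filter", n_kept=int(self.lod_report_.lod_kept.sum()),
                  digest=_digest(list(lod_table.metabolite_ids)))

        self.qc_report_ = qc_cov_filter(lod_table, ann, cfg.qc_cov_max)
        kept = list(self.qc_report_.kept.index[self.qc_report_.kept])
        gated = lod_table.subset_metabolites(kept)
        self._log("qc_cov_filter", n_kept=len(kept))
        self.kept_metabolite_ids_ = kept

        study_gated = gated.subset_samples(study_ids)
        imputed = impute_missing(study_gated, cfg.impute_strategy)
        self.train_min_ = imputed.values.min(axis=0)
        self._log("impute", strategy=cfg.impute_strategy)

        # preliminary preprocessing on training samples for outlier screening
        train_raw = imputed.values.loc[train_ids]
        norm0 = MedianFoldChangeNormalizer().fit(train_raw)
        scal0 = LogAutoscaler().fit(norm0.transform(train_raw))
        scaled0 = scal0.transform(norm0.transform(train_raw))
        pca = NipalsPCA(n_components=min(cfg.pca_max_components, len(train_ids) - 1)).fit(scaled0)
        self.outlier_ids_ = hotelling_outliers(pca, train_ids, cfg.outlier_level)
        self.pca_ = pca
        train_ids = [s for s in train_ids if s not in self.outlier_ids_]
        self._log("pca_outliers", excluded=list(self.outlier_ids_), level=cfg.outlier_level)
        self.train_sample_ids_ = train_ids

        labels = ann.loc[train_ids, "group"]
        y = (labels == contrast[1]).astype(int).to_numpy()
        if len(np.unique(y)) < 2:
            raise ValueError("single class remains after outlier removal")

        # final frozen preprocessing state, fitted on the retained training set
        train_raw = imputed.values.loc[train_ids]
        self.normalizer_ = MedianFoldChangeNormalizer().fit(train_raw)
        normed = self.normalizer_.transform(train_raw)
        self.scaler_ = LogAutoscaler().fit(normed)
        X = self.scaler_.transform(normed)
        self._log("preprocess", n_samples=len(train_ids), digest=_digest(X))

        self.prefiltered_ids_ = prefilter(X, y, cfg.prefilter_p_max)
        if not self.prefiltered_ids_:
            raise ValueError("pre-filter removed every metabolite")
        self._log("prefilter", n_kept=len(self.prefiltered_ids_))
        Xf = X.loc[:, self.prefiltered_ids_]

        model0 = OPLSDA(n_orth=cfg.n_orth, cv_folds=cfg.cv_folds, random_state=cfg.seed).fit(Xf, y)
        self.initial_vip_ = model0.vip_
        self.model_candidate_ids_ = list(Xf.columns)
        vips = pd.Series(model0.vip_, index=Xf.columns)

        self.vip_selection_ = select_vip_threshold(
            Xf, y, vips, cfg.vip_grid, model0.n_orth_, cfg.cv_folds, cfg.seed,
            q2_tolerance=cfg.vip_q2_tolerance,
        )
        self.vip_threshold_ = self.vip_selection_.threshold
        self.selected_ids_ = list(vips.index[vips >= self.vip_threshold_])
        self._log("vip_refinement", threshold=self.vip_threshold_, n_selected=len(self.selected_ids_))

        Xs = Xf.loc[:, self.selected_ids_]
        self.model_ = OPLSDA(n_orth=model0.n_orth_, cv_folds=cfg.cv_folds, random_state=cfg.seed).fit(Xs, y)
        self.cv_ = q2_cv(
            OPLSDA(n_orth=model0.n_orth_, cv_folds=cfg.cv_folds, random_state=cfg.seed),
            Xs, y, folds=cfg.cv_folds, seed=cfg.seed,
        )
        # cross-model validation: feature selection re-run per fold, so the
        # CV-ANOVA significance is not inflated by in-training selection
        self.cv_cmv_ = q2_cv(
            SelectingOPLSDA(p_max=cfg.prefilter_p_max, vip_threshold=self.vip_threshold_,
                            n_orth=model0.n_orth_, cv_folds=cfg.cv_folds, random_state=cfg.seed),
            X, y, folds=cfg.cv_folds, seed=cfg.seed,
        )
        f, df1, df2, p = cv_anova(self.cv_cmv_, self.model_.n_orth_ + 1)
        self.training_report_ = ValidationReport(
            cv_anova_f=f, cv_anova_df=(df1, df2), cv_anova_p=p,
            r2y=self.model_.r2y_, q2y=self.cv_.q2y,
        )
        self.training_report_.flag_gap(cfg.r2q2_gap_flag)
        self.y_train_ = y
        self.X_train_ = Xs

        self.permutation_ = None
        if self.run_permutation:
            self.permutation_ = permutation_q2_intercept(
                OPLSDA(n_orth=self.model_.n_orth_, cv_folds=cfg.cv_folds, random_state=cfg.seed),
                Xs, y, n=cfg.n_perm_model, seed=cfg.seed, folds=cfg.cv_folds,
            )
        self._audit()
        return self

    def _audit(self) -> None:
        # monotone filter audit: selected ⊆ prefiltered ⊆ QC/LOD-retained
        if not set(self.selected_ids_) <= set(self.prefiltered_ids_):
            raise AssertionError("selected features escape the pre-filter")
        if not set(self.prefiltered_ids_) <= set(self.kept_metabolite_ids_):
            raise AssertionError("pre-filtered features escape the QC/LOD gates")

    # -- application to new data ------------------------------------------

    def transform_samples(self, table: ConcentrationTable, sample_ids) -> pd.DataFrame:
        """Apply the frozen gates and transforms to new samples."""
        sub = table.values.loc[list(sample_ids), self.kept_metabolite_ids_]
        sub = sub.fillna(self.train_min_)  # frozen training minima for censored cells
        normed = self.normalizer_.transform(sub)
        return self.scaler_.transform(normed)

    def decision_function(self, table: ConcentrationTable, sample_ids):
        X = self.transform_samples(table, sample_ids).loc[:, self.selected_ids_]
        return self.model_.decision_function(X)

    def permutation_diagnostics(self, n: int | None = None, seed: int | None = None) -> PermutationResult:
        cfg = self.config_
        self.permutation_ = permutation_q2_intercept(
            OPLSDA(n_orth=self.model_.n_orth_, cv_folds=cfg.cv_folds, random_state=cfg.seed),
            self.X_train_, self.y_train_,
            n=n or cfg.n_perm_model, seed=cfg.seed if seed is None else seed,
            folds=cfg.cv_folds,
        )
        return self.permutation_

    def to_json(self) -> str:
        payload = {
            "contrast": list(self.contrast_),
            "config": asdict(self.config_) | {"vip_grid": [float(v) for v in self.config_.vip_grid]},
            "kept_metabolite_ids": list(self.kept_metabolite_ids_),
            "outliers": list(self.outlier_ids_),
            "prefiltered_ids": list(self.prefiltered_ids_),
            "vip_threshold": self.vip_threshold_,
            "selected_ids": list(self.selected_ids_),
            "train_sample_ids": list(self.train_sample_ids_),
            "train_min": self.train_min_.to_dict(),
            "reference_profile": self.normalizer_.reference_profile_.to_dict(),
            "column_means": self.scaler_.column_means_.to_dict(),
            "column_sds": self.scaler_.column_sds_.to_dict(),
            "model": json.loads(self.model_.to_json()),
            "r2y": self.model_.r2y_,
            "q2y": self.cv_.q2y,
            "cv_anova_p": self.training_report_.cv_anova_p,
            "provenance": self.provenance_,
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def discover(table, annotations, contrast, config: PipelineConfig | None = None,
             run_permutation: bool = False) -> DiscoveryPipeline:
    """Functional wrapper over :class:`DiscoveryPipeline`."""
    return DiscoveryPipeline(config=config, run_permutation=run_permutation).fit(
        table, annotations, contrast
    )


def external_validate(fitted: DiscoveryPipeline, table: ConcentrationTable, annotations) -> ValidationReport:
    """Score held-out validation samples with the frozen pipeline.

    Training/validation id overlap is rejected outright — training metrics
    are never computed on validation samples.
    """
    ann = validate_annotations(annotations, table)
    contrast = fitted.contrast_
    val_ids = [
        s for s in table.sample_ids
        if not ann.loc[s, "is_qc"] and ann.loc[s, "set"] == "validation"
        and ann.loc[s, "group"] in contrast
    ]
    overlap = sorted(set(val_ids) & set(fitted.train_sample_ids_))
    if overlap:
        raise ValueError(f"validation samples overlap the training set: {overlap}")
    if not val_ids:
        raise ValueError("no validation samples for the contrast")
    y_true = (ann.loc[val_ids, "group"] == contrast[1]).astype(int).to_numpy()
    scores = fitted.decision_function(table, val_ids)
    y_pred = (scores >= 0.5).astype(int)
    cm = confusion_metrics(y_true, y_pred, positive_label=1)
    auc, lo, hi = auroc(scores, y_true, positive_label=1)
    report = ValidationReport(
        confusion=cm, auroc=auc, auroc_ci=(lo, hi),
        r2y=fitted.model_.r2y_, q2y=fitted.cv_.q2y,
    )
    report.flag_gap(fitted.config_.r2q2_gap_flag)
    return report


# ---------------------------------------------------------------------------
# pre-analysis class permutation with in-loop feature selection
# ---------------------------------------------------------------------------

def pre_analysis_permutation(X, y, config: PipelineConfig | None = None,
                             n: int | None = None, seed: int | None = None,
                             vip_refine: bool = False) -> PermutationResult:
    """Class-permutation test re-running discovery selection per iteration.

    ``X`` is the preprocessed (scaled) training matrix before pre-filtering;
    the Welch pre-filter runs inside the permutation loop so selection bias
    is part of the permuted models. ``vip_refine`` additionally repeats the
    VIP-grid refinement per iteration (markedly slower).
    """
    cfg = config or PipelineConfig()
    n = n if n is not None else cfg.n_perm_class
    seed = cfg.seed if seed is None else seed

    def fit_and_score(Xm, ym):
        feats = prefilter(Xm, ym, cfg.prefilter_p_max)
        if len(feats) < 2:
            return -1.0, 1.0
        Xf = Xm.loc[:, feats]
        if vip_refine:
            m0 = OPLSDA(n_orth=cfg.n_orth, cv_folds=cfg.cv_folds, random_state=cfg.seed).fit(Xf, ym)
            vips = pd.Series(m0.vip_, index=Xf.columns)
            sel = select_vip_threshold(Xf, ym, vips, cfg.vip_grid, m0.n_orth_, cfg.cv_folds,
                                       cfg.seed, q2_tolerance=cfg.vip_q2_tolerance)
            Xf = Xf.loc[:, list(vips.index[vips >= sel.threshold])]
        cv = q2_cv(
            OPLSDA(n_orth=cfg.n_orth, cv_folds=cfg.cv_folds, random_state=cfg.seed),
            Xf, ym, folds=cfg.cv_folds, seed=cfg.seed,
        )
        return cv.q2y, float(np.sqrt(cv.press / len(ym)))

    return label_permutation_test(fit_and_score, X, y, n=n, seed=seed)


# ---------------------------------------------------------------------------
# platform fusion
# ---------------------------------------------------------------------------

@dataclass
class FusionResult:
    model_: OPLSDA
    selected_ids_: list
    vip_threshold_: float
    cv_: object
    report_: ValidationReport
    block_of_: dict          # fused column -> platform tag
    fused_columns_: list
    X_train_: pd.DataFrame
    y_train_: np.ndarray


def _block_preprocess(table: ConcentrationTable, ann, train_ids, cfg: PipelineConfig):
    lod_table, _ = lod_filter(table, cfg.lod_min_detect)
    qc_ids = [s for s in lod_table.sample_ids if ann.loc[s, "is_qc"]]
    if len(qc_ids) >= 2:
        qc_rep = qc_cov_filter(lod_table, ann, cfg.qc_cov_max)
        kept = list(qc_rep.kept.index[qc_rep.kept])
        lod_table = lod_table.subset_metabolites(kept)
    study_ids = [s for s in lod_table.sample_ids if not ann.loc[s, "is_qc"]]
    imputed = impute_missing(lod_table.subset_samples(study_ids), cfg.impute_strategy)
    train_raw = imputed.values.loc[train_ids]
    norm = MedianFoldChangeNormalizer().fit(train_raw)
    scal = LogAutoscaler().fit(norm.transform(train_raw))
    return scal.transform(norm.transform(train_raw))


def fuse_platforms(tables, annotations, contrast, config: PipelineConfig | None = None,
                   prior_signatures=None) -> FusionResult:
    """Block-scaled fusion of >= 2 platforms followed by joint OPLS-DA discovery.

    Each block is gated, imputed, normalized and autoscaled independently on
    the shared training samples, then down-weighted by 1/sqrt(width) so the
    blocks contribute equal total variance. ``prior_signatures`` (one feature
    list per block) restricts blocks to pre-selected per-platform signatures,
    mirroring the combination of existing platform biomarkers; without it the
    Welch pre-filter runs on the fused matrix. VIP refinement follows either
    way, and each fused column keeps its platform provenance.
    """
    cfg = config or PipelineConfig()
    if len(tables) < 2:
        raise ValueError("fusion requires >= 2 blocks")
    anns = [validate_annotations(annotations, t) for t in tables]
    ann = anns[0]
    shared = set.intersection(*[
        {s for s in t.sample_ids if not a.loc[s, "is_qc"]} for t, a in zip(tables, anns)
    ])
    train_ids = [
        s for s in tables[0].sample_ids
        if s in shared and ann.loc[s, "set"] == "train" and ann.loc[s, "group"] in contrast
    ]
    if len(train_ids) < 2:
        raise ValueError(f"fewer than 2 shared training samples: {train_ids}")

    blocks, names = [], []
    for t in tables:
        scaled = _block_preprocess(t, validate_annotations(annotations, t), train_ids, cfg)
        blocks.append(scaled)
        names.append(t.platform_tag)
    if prior_signatures is not None:
        blocks = [b.loc[:, list(sig)] for b, sig in zip(blocks, prior_signatures)]
    if len(set(names)) < len(names):
        names = [f"{n}#{i}" for i, n in enumerate(names)]
    fused = block_scale(blocks, names)
    block_of = {}
    for name, b in zip(names, blocks):
        for c in b.columns:
            block_of[f"{name}::{c}"] = name

    y = (ann.loc[train_ids, "group"] == contrast[1]).astype(int).to_numpy()
    X = fused
    if prior_signatures is None:
        feats = prefilter(X, y, cfg.prefilter_p_max)
        X = X.loc[:, feats]
    model0 = OPLSDA(n_orth=cfg.n_orth, cv_folds=cfg.cv_folds, random_state=cfg.seed).fit(X, y)
    vips = pd.Series(model0.vip_, index=X.columns)
    sel = select_vip_threshold(X, y, vips, cfg.vip_grid, model0.n_orth_, cfg.cv_folds, cfg.seed,
                               q2_tolerance=cfg.vip_q2_tolerance)
    selected = list(vips.index[vips >= sel.threshold])
    Xs = X.loc[:, selected]
    model = OPLSDA(n_orth=model0.n_orth_, cv_folds=cfg.cv_folds, random_state=cfg.seed).fit(Xs, y)
    cv = q2_cv(OPLSDA(n_orth=model0.n_orth_, cv_folds=cfg.cv_folds, random_state=cfg.seed),
               Xs, y, folds=cfg.cv_folds, seed=cfg.seed)
    f, df1, df2, p = cv_anova(cv, model.n_orth_ + 1)
    report = ValidationReport(cv_anova_f=f, cv_anova_df=(df1, df2), cv_anova_p=p,
                              r2y=model.r2y_, q2y=cv.q2y)
    report.flag_gap(cfg.r2q2_gap_flag)
    return FusionResult(
        model_=model, selected_ids_=selected, vip_threshold_=sel.threshold,
        cv_=cv, report_=report, block_of_=block_of, fused_columns_=list(fused.columns),
        X_train_=Xs, y_train_=y,
    )


# ---------------------------------------------------------------------------
# multi-class stage model
# ---------------------------------------------------------------------------

@dataclass
class StageResult:
    model_: PLSDA
    kruskal_: pd.DataFrame
    X_: pd.DataFrame
    labels_: np.ndarray
    sample_ids_: list


def stage_analysis(table: ConcentrationTable, annotations,
                   config: PipelineConfig | None = None,
                   n_predictive: int = 2) -> StageResult:
    """Five-class disease-stage model plus stage-wise Kruskal-Wallis screen.

    Uses every non-QC control/CRC sample regardless of train/validation set,
    labelling controls "control" and CRC samples by stage. The multi-class
    model is PLS2-DA on the class-indicator matrix (no orthogonal
    filtering); the univariate screen is Bonferroni-corrected Kruskal-Wallis
    per metabolite across the five classes.
    """
    cfg = config or PipelineConfig()
    ann = validate_annotations(annotations, table)
    ids = [
        s for s in table.sample_ids
        if not ann.loc[s, "is_qc"] and ann.loc[s, "group"] in ("control", "CRC")
    ]
    labels = np.asarray([
        "control" if ann.loc[s, "group"] == "control" else str(ann.loc[s, "stage"])
        for s in ids
    ])
    lod_table, _ = lod_filter(table, cfg.lod_min_detect)
    qc_ids = [s for s in lod_table.sample_ids if ann.loc[s, "is_qc"]]
    if len(qc_ids) >= 2:
        qc_rep = qc_cov_filter(lod_table, ann, cfg.qc_cov_max)
        lod_table = lod_table.subset_metabolites(qc_rep.kept.index[qc_rep.kept])
    imputed = impute_missing(lod_table.subset_samples(ids), cfg.impute_strategy)
    norm = MedianFoldChangeNormalizer().fit(imputed.values)
    scal = LogAutoscaler().fit(norm.transform(imputed.values))
    X = scal.transform(norm.transform(imputed.values))
    model = PLSDA(n_components=n_predictive).fit(X, labels)
    kw = kruskal_wallis_table(X, labels, alpha=cfg.alpha)
    return StageResult(model_=model, kruskal_=kw, X_=X, labels_=labels, sample_ids_=ids)


def score_covariate_association(scores: np.ndarray, covariate) -> pd.DataFrame:
    """Association p-value of each latent score with a (possibly binary) covariate.

    Generic confounder check: Pearson correlation (point-biserial for a
    binary covariate) of every score column with the covariate.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1:
        scores = scores.T
    cov = pd.Series(covariate)
    if cov.dtype == object or cov.dtype == bool:
        cov = pd.factorize(cov)[0]
    cov = np.asarray(cov, dtype=float)
    rows = []
    for a in range(scores.shape[1]):
        r, p = stats.pearsonr(scores[:, a], cov)
        rows.append((a + 1, float(r), float(p)))
    return pd.DataFrame(rows, columns=["component", "r", "p_value"]).set_index("component")
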