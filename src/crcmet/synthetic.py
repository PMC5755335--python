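"""Synthetic Biocrates-kit-style serum metabolomics data with known truth.

Emulates the input structure of a targeted FIA-MS/MS concentration study of
colorectal neoplasia: 163 kit metabolites in the kit's chemical classes,
log-normal concentrations with within-class co-regulation, per-sample
dilution-like analytical bias, multiplicative analytical noise calibrated to
a QC coefficient of variation, limit-of-detection censoring that leaves 146
reliably detected metabolites, and class-dependent concentration shifts on a
designated effect subset. Every generated dataset carries its ground truth
(effect metabolites with signed sizes, dilution factors, censoring mask) so
feature-recovery and normalization accuracy are directly testable.

Concentrations are generated on the log2 scale with a per-metabolite total
biological sd of 1.0 log2 unit, so effect sizes stated as log2 fold changes
coincide with sd units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import ConcentrationTable

# kit-convention class composition summing to 163
DEFAULT_CLASS_COMPOSITION = {
    "acylcarnitine": 41,
    "amino_acid": 14,
    "PC_aa": 38,
    "PC_ae": 38,
    "lysoPC": 15,
    "SM": 15,
    "other": 2,
}

# fixture conventions for class-typical serum levels (log2 uM at class center)
CLASS_LOG2_LOCATION = {
    "acylcarnitine": np.log2(0.2),
    "amino_acid": np.log2(50.0),
    "PC_aa": np.log2(20.0),
    "PC_ae": np.log2(3.0),
    "lysoPC": np.log2(30.0),
    "SM": np.log2(80.0),
    "other": np.log2(100.0),
}

CLASS_PREFIX = {
    "acylcarnitine": "AC",
    "amino_acid": "AA",
    "PC_aa": "PCaa",
    "PC_ae": "PCae",
    "lysoPC": "lysoPC",
    "SM": "SM",
    "other": "OTH",
}

#: (n_train, n_validation) per group, mirroring the study's cohort split.
DEFAULT_GROUP_SIZES = {
    "control": (21, 20),
    "adenoma": (31, 0),
    "I": (5, 3),
    "II": (5, 3),
    "III": (5, 3),
    "IVa": (17, 19),
}

#: Effect-size multiplier per case group; monotone in disease stage.
DEFAULT_STAGE_MULTIPLIERS = {
    "control": 0.0,
    "adenoma": 0.3,
    "I": 0.6,
    "II": 0.8,
    "III": 1.0,
    "IVa": 1.2,
}


@dataclass
class SyntheticSpec:
    """Parameters of the generator; defaults emulate the study conditions."""

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    class_composition: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COMPOSITION))
    n_effect: int = 48
    effect_low: float = 0.5    # |log2 fold change| lower bound (= sd units)
    effect_high: float = 1.5
    stage_multipliers: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_MULTIPLIERS))
    within_class_correlation: float = 0.5   # latent-factor loading in [0, 1)
    analytical_cov: float = 0.10
    dilution_log_sd: float = 0.2
    n_below_lod: int = 17
    lod_quantile: float = 0.6       # censoring quantile for below-LOD metabolites
    base_lod_quantile: float = 0.02  # sporadic censoring for ordinary metabolites
    n_qc: int = 8

    @property
    def p_total(self) -> int:
        return sum(self.class_composition.values())

    def validate(self) -> None:
        if self.n_effect > self.p_total - self.n_below_lod:
            raise ValueError("n_effect exceeds detectable metabolites")
        if not 0.0 <= self.within_class_correlation < 1.0:
            raise ValueError("within_class_correlation must lie in [0, 1)")
        if self.analytical_cov < 0:
            raise ValueError("analytical_cov must be >= 0")
        unknown = set(self.stage_multipliers) - set(self.group_sizes)
        if unknown:
            raise ValueError(f"multipliers for unknown groups: {sorted(unknown)}")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    effect_sizes: pd.Series          # signed log2 fold change per effect metabolite
    dilution_factors: pd.Series      # per study sample
    censored_mask: pd.DataFrame      # True where a cell was censored to missing
    below_lod_ids: list              # metabolites designed to fail the LOD screen

    def to_json(self) -> str:
        return json.dumps(
            {
                "effect_sizes": self.effect_sizes.to_dict(),
                "dilution_factors": self.dilution_factors.to_dict(),
                "below_lod_ids": list(self.below_lod_ids),
            },
            sort_keys=True,
        )


def _metabolite_ids(composition: dict) -> tuple[list, list]:
    ids, classes = [], []
    for cls, count in composition.items():
        prefix = CLASS_PREFIX.get(cls, cls)
        for i in range(1, count + 1):
            ids.append(f"{prefix}_{i:02d}")
            classes.append(cls)
    return ids, classes


def generate(spec: SyntheticSpec | None = None, seed: int = 0):
    """Generate (ConcentrationTable, annotations, SyntheticTruth).

    The same seed yields byte-identical output. Case samples shift the
    effect metabolites by the signed effect size times the group multiplier;
    a log-normal per-sample dilution factor multiplies every metabolite
    (giving median fold-change normalization something real to remove); QC
    samples are analytical-noise replicates of the pooled geometric mean.
    """
    spec = spec or SyntheticSpec()
    spec.validate()
    rng = np.random.default_rng(seed)

    met_ids, met_classes = _metabolite_ids(spec.class_composition)
    p = len(met_ids)
    classes_arr = np.asarray(met_classes)
    class_names = list(spec.class_composition)

    # sample roster: per group, train first then validation
    rows = []
    for group, (n_tr, n_va) in spec.group_sizes.items():
        for k in range(n_tr + n_va):
            which = "train" if k < n_tr else "validation"
            rows.append((group, which))
    sample_ids = [f"S{i + 1:03d}" for i in range(len(rows))]
    qc_ids = [f"QC{i + 1}" for i in range(spec.n_qc)]

    ann = pd.DataFrame(index=pd.Index(sample_ids + qc_ids, name="sample_id"))
    groups = [g for g, _ in rows] + ["none"] * spec.n_qc
    ann["group"] = ["CRC" if g in ("I", "II", "III", "IVa") else g for g in groups]
    ann.loc[ann["group"] == "none", "group"] = "none"
    ann["stage"] = [g if g in ("I", "II", "III", "IVa") else "none" for g in groups]
    ann["set"] = [s for _, s in rows] + ["none"] * spec.n_qc
    ann["is_qc"] = [False] * len(rows) + [True] * spec.n_qc
    ann["age"] = np.round(rng.normal(62, 9, size=len(ann)), 1)
    ann["sex"] = rng.choice(["M", "F"], size=len(ann), p=[0.7, 0.3])
    ann["pre_chemo"] = (ann["stage"] == "IVa").to_numpy() & (rng.random(len(ann)) < 0.45)
    ann.loc[ann["is_qc"], ["age", "sex"]] = np.nan

    # designate below-LOD metabolites, then effect metabolites from the rest
    below_lod = list(rng.choice(met_ids, size=spec.n_below_lod, replace=False))
    detectable = [m for m in met_ids if m not in below_lod]
    effect_ids = list(rng.choice(detectable, size=spec.n_effect, replace=False))
    signs = rng.choice([-1.0, 1.0], size=spec.n_effect)
    mags = rng.uniform(spec.effect_low, spec.effect_high, size=spec.n_effect)
    effect_sizes = pd.Series(signs * mags, index=effect_ids)
    delta = pd.Series(0.0, index=met_ids)
    delta.loc[effect_ids] = effect_sizes

    base_mean = np.array(
        [CLASS_LOG2_LOCATION[c] + 0 for c in classes_arr]
    ) + rng.uniform(-2.0, 2.0, size=p)

    lam = spec.within_class_correlation
    noise_sd = np.sqrt(1.0 - lam**2)
    n_study = len(rows)
    factors = rng.standard_normal((n_study, len(class_names)))  # per-sample class factors
    class_idx = np.array([class_names.index(c) for c in classes_arr])
    eps = rng.standard_normal((n_study, p))
    mult = np.array([spec.stage_multipliers.get(g, 0.0) for g, _ in rows])
    log2_conc = (
        base_mean[None, :]
        + lam * factors[:, class_idx]
        + noise_sd * eps
        + np.outer(mult, delta.to_numpy())
    )

    dilution = np.exp(rng.normal(0.0, spec.dilution_log_sd, size=n_study))
    ana_sd = np.sqrt(np.log1p(spec.analytical_cov**2))
    ana_noise = np.exp(rng.normal(0.0, ana_sd, size=(n_study, p)))
    conc = (2.0**log2_conc) * dilution[:, None] * ana_noise

    # QC replicates: analytical noise around the pooled geometric mean
    geo_mean = np.exp(np.log(conc).mean(axis=0))
    qc_noise = np.exp(rng.normal(0.0, ana_sd, size=(spec.n_qc, p)))
    qc_conc = geo_mean[None, :] * qc_noise

    values = pd.DataFrame(
        np.vstack([conc, qc_conc]), index=sample_ids + qc_ids, columns=met_ids
    )

    # LOD censoring: thresholds from study-sample quantiles per metabolite
    study_vals = values.loc[sample_ids]
    lod = pd.Series(
        np.quantile(study_vals.to_numpy(), spec.base_lod_quantile, axis=0), index=met_ids
    )
    heavy = pd.Series(
        np.quantile(study_vals.to_numpy(), spec.lod_quantile, axis=0), index=met_ids
    )
    lod.loc[below_lod] = heavy.loc[below_lod]
    censored = values < lod
    values = values.mask(censored)

    table = ConcentrationTable(values, pd.Series(met_classes, index=met_ids))
    truth = SyntheticTruth(
        effect_sizes=effect_sizes,
        dilution_factors=pd.Series(dilution, index=sample_ids),
        censored_mask=censored,
        below_lod_ids=below_lod,
    )
    return table, ann, truth


def truth_recovery_report(fitted, truth: SyntheticTruth) -> dict:
    """Recovery metrics of a fitted discovery pipeline against ground truth.

    Reports recall and precision of the selected features relative to the
    injected effect metabolites, the fraction of recovered features whose
    model coefficient sign (w_j * c, case coded 1) agrees with the injected
    direction, and the Spearman correlation of VIP with |effect size| over
    the model's feature universe.
    """
    from scipy import stats as _stats

    selected = list(fitted.selected_ids_)
    universe = [str(c) for c in fitted.model_candidate_ids_]
    unknown = set(truth.effect_sizes.index) - set(fitted.kept_metabolite_ids_)
    if not set(selected) <= set(fitted.kept_metabolite_ids_):
        raise ValueError("selected features outside the analyzed metabolite universe")
    effects = set(truth.effect_sizes.index)
    hits = effects & set(selected)
    recall = len(hits) / len(effects) if effects else np.nan
    precision = len(hits) / len(selected) if selected else np.nan

    coef = pd.Series(
        fitted.model_.weights_ * fitted.model_.y_loading_,
        index=[str(c) for c in fitted.model_.feature_names_in_],
    )
    agree = [
        np.sign(coef[m]) == np.sign(truth.effect_sizes[m])
        for m in hits
        if m in coef.index
    ]
    sign_agreement = float(np.mean(agree)) if agree else np.nan

    vip_series = pd.Series(
        fitted.initial_vip_, index=[str(c) for c in fitted.prefiltered_ids_]
    )
    abs_effect = truth.effect_sizes.abs().reindex(vip_series.index).fillna(0.0)
    rho = _stats.spearmanr(vip_series.to_numpy(), abs_effect.to_numpy()).statistic
    return {
        "recall": float(recall),
        "precision": float(precision),
        "sign_agreement": sign_agreement,
        "vip_effect_spearman": float(rho),
        "n_selected": len(selected),
        "n_effects_in_universe": len(effects - unknown),
    }
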