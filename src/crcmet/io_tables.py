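"""Concentration tables, sample annotations, and the QC/LOD/imputation rules.

The analyzable matrix of a targeted metabolomics study is defined by three
gates applied to the raw concentration table: analytical reliability on QC
replicates (coefficient of variation), detectability (limit-of-detection
censoring), and imputation of the remaining missing cells. This module owns
the on-disk formats (plain TSV/CSV) and those three gates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

METABOLITE_CLASSES = (
    "acylcarnitine",
    "amino_acid",
    "PC_aa",
    "PC_ae",
    "lysoPC",
    "SM",
    "other",
)

GROUPS = ("control", "adenoma", "CRC", "none")
STAGES = ("I", "II", "III", "IVa", "none")
SETS = ("train", "validation", "none")

#: Cell tokens parsed as missing (configurable via ``read_concentration_table``).
DEFAULT_MISSING_TOKENS = ("", "NA", "ND", "<LOD")


class TableFormatError(ValueError):
    """Structured error for malformed concentration/annotation files."""


@dataclass
class ConcentrationTable:
    """Samples x metabolites concentration matrix (uM) with class annotations.

    ``values`` is a float DataFrame indexed by sample id with metabolite ids
    as columns; missing (censored / not detected) cells are NaN, which doubles
    as the missing mask. ``metabolite_class`` maps each metabolite to one of
    :data:`METABOLITE_CLASSES`. ``platform_tag`` distinguishes data blocks
    (e.g. "FIA-MS/MS" vs "GC-MS") when tables are fused.
    """

    values: pd.DataFrame
    metabolite_class: pd.Series
    platform_tag: str = "FIA-MS/MS"

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise TableFormatError(f"duplicate sample ids: {dup}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise TableFormatError(f"duplicate metabolite ids: {dup}")
        if (self.values.to_numpy() < 0).any():
            raise TableFormatError("negative concentrations present")
        self.metabolite_class = self.metabolite_class.reindex(self.values.columns)
        if self.metabolite_class.isna().any():
            missing = self.metabolite_class.index[self.metabolite_class.isna()].tolist()
            raise TableFormatError(f"metabolites without class annotation: {missing}")
        bad = set(self.metabolite_class) - set(METABOLITE_CLASSES)
        if bad:
            raise TableFormatError(f"unknown metabolite classes: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def subset_metabolites(self, metabolite_ids) -> "ConcentrationTable":
        return ConcentrationTable(
            self.values.loc[:, list(metabolite_ids)],
            self.metabolite_class.loc[list(metabolite_ids)],
            self.platform_tag,
        )

    def subset_samples(self, sample_ids) -> "ConcentrationTable":
        return ConcentrationTable(
            self.values.loc[list(sample_ids)], self.metabolite_class, self.platform_tag
        )


ANNOTATION_COLUMNS = ("sample_id", "group", "stage", "set", "is_qc", "age", "sex", "pre_chemo")


def validate_annotations(annotations: pd.DataFrame, table: ConcentrationTable | None = None) -> pd.DataFrame:
    """Validate a sample-annotation frame (indexed or indexable by sample_id)."""
    ann = annotations.copy()
    if "sample_id" in ann.columns:
        ann = ann.set_index("sample_id")
    if ann.index.duplicated().any():
        raise TableFormatError("duplicate sample ids in annotations")
    for col, allowed in (("group", GROUPS), ("stage", STAGES), ("set", SETS)):
        if col not in ann.columns:
            raise TableFormatError(f"annotation column '{col}' missing")
        bad = set(ann[col].astype(str)) - set(allowed)
        if bad:
            raise TableFormatError(f"invalid values in '{col}': {sorted(bad)}")
    if "is_qc" not in ann.columns:
        raise TableFormatError("annotation column 'is_qc' missing")
    ann["is_qc"] = ann["is_qc"].astype(bool)
    if (ann.loc[ann["is_qc"], "group"] != "none").any():
        raise TableFormatError("QC samples must have group = none")
    if table is not None:
        missing = set(table.sample_ids) - set(ann.index)
        if missing:
            raise TableFormatError(f"annotation rows missing for samples: {sorted(missing)}")
    return ann


def read_concentration_table(
    path,
    annotation_path,
    class_map_path=None,
    missing_tokens=DEFAULT_MISSING_TOKENS,
    sep: str = "\t",
):
    """Read a concentration table plus its sample annotations.

    The table is TSV/CSV with a header row of metabolite ids and the first
    column holding sample ids. Cells matching ``missing_tokens`` become NaN in
    the missing mask, never zeros. ``class_map_path`` (TSV: metabolite_id,
    class, platform_tag) defaults to ``<path>.classes.tsv``.

    Returns ``(ConcentrationTable, annotations DataFrame)``.
    """
    path = Path(path)
    values = pd.read_csv(
        path, sep=sep, index_col=0, na_values=list(missing_tokens), keep_default_na=False,
        float_precision="round_trip",
    )
    values.index = values.index.astype(str)
    values = values.astype(float)
    if class_map_path is None:
        class_map_path = path.with_suffix(path.suffix + ".classes.tsv")
    cmap = pd.read_csv(class_map_path, sep="\t", dtype=str)
    classes = cmap.set_index("metabolite_id")["class"]
    platform = cmap["platform_tag"].iloc[0] if "platform_tag" in cmap.columns else "FIA-MS/MS"
    table = ConcentrationTable(values, classes, platform_tag=platform)
    ann = pd.read_csv(annotation_path, sep="\t", dtype={"sample_id": str})
    ann = validate_annotations(ann, table)
    return table, ann


def write_concentration_table(table: ConcentrationTable, path, annotations=None, sep: str = "\t") -> None:
    """Write a table (+ class map, + optional annotations) round-trippably.

    Missing cells are written as "NA"; values keep full float precision.
    """
    path = Path(path)
    out = table.values.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep, na_rep="NA", float_format="%.17g")
    cmap = pd.DataFrame(
        {
            "metabolite_id": table.metabolite_ids,
            "class": table.metabolite_class.values,
            "platform_tag": table.platform_tag,
        }
    )
    cmap.to_csv(path.with_suffix(path.suffix + ".classes.tsv"), sep="\t", index=False)
    if annotations is not None:
        ann = annotations.reset_index()
        ann.to_csv(path.with_suffix(path.suffix + ".annotations.tsv"), sep="\t", index=False)


@dataclass
class QcReport:
    """Per-metabolite QC outcome: CoV over QC replicates and keep flags."""

    cov: pd.Series
    kept: pd.Series
    lod_kept: pd.Series = field(default=None)
    threshold: float = 0.25

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"cov": self.cov, "kept": self.kept})
        if self.lod_kept is not None:
            frame["lod_kept"] = self.lod_kept
        frame.index.name = "metabolite_id"
        return frame

    def to_json(self) -> str:
        payload = {
            "threshold": self.threshold,
            "n_kept": self.n_kept,
            "cov": {k: (None if pd.isna(v) else float(v)) for k, v in self.cov.items()},
            "kept": {k: bool(v) for k, v in self.kept.items()},
        }
        if self.lod_kept is not None:
            payload["lod_kept"] = {k: bool(v) for k, v in self.lod_kept.items()}
        return json.dumps(payload, indent=1, sort_keys=True)


def qc_cov_filter(table: ConcentrationTable, annotations: pd.DataFrame, max_cov: float = 0.25) -> QcReport:
    """Flag metabolites whose QC-replicate coefficient of variation exceeds ``max_cov``.

    CoV = sample (n-1) standard deviation / mean over the non-missing QC
    values of each metabolite. Metabolites with all-missing QC values are
    flagged (kept = False, CoV = NaN), never silently retained. CoV is
    scale-free, so the filter is invariant to rescaling a metabolite.
    """
    ann = validate_annotations(annotations, table)
    qc_ids = [s for s in table.sample_ids if ann.loc[s, "is_qc"]]
    if len(qc_ids) < 2:
        raise ValueError(
            f"qc_cov_filter requires >= 2 QC samples, found {len(qc_ids)}"
        )
    qc = table.values.loc[qc_ids]
    mean = qc.mean(axis=0, skipna=True)
    sd = qc.std(axis=0, ddof=1, skipna=True)
    cov = sd / mean
    cov[qc.notna().sum(axis=0) < 2] = np.nan
    kept = (cov <= max_cov).fillna(False)
    return QcReport(cov=cov, kept=kept, threshold=max_cov)


def lod_filter(table: ConcentrationTable, min_detect_fraction: float = 0.5):
    """Drop metabolites detected in fewer than ``min_detect_fraction`` of samples.

    Operationalizes limit-of-detection screening as a detected-fraction
    threshold on the missing mask. Returns ``(filtered table, QcReport)``
    where the report's ``lod_kept`` lists survivors.
    """
    if not 0.0 <= min_detect_fraction <= 1.0:
        raise ValueError("min_detect_fraction must lie in [0, 1]")
    detected = table.values.notna().mean(axis=0)
    lod_kept = detected >= min_detect_fraction
    filtered = table.subset_metabolites(lod_kept.index[lod_kept])
    report = QcReport(
        cov=pd.Series(np.nan, index=table.metabolite_ids),
        kept=lod_kept,
        lod_kept=lod_kept,
        threshold=min_detect_fraction,
    )
    return filtered, report


def impute_missing(table: ConcentrationTable, strategy: str = "per_metabolite_min") -> ConcentrationTable:
    """Impute missing cells with the minimum observed value.

    ``per_metabolite_min`` (default) uses each metabolite's own observed
    minimum, preserving per-metabolite scale; ``global_min`` uses the single
    smallest value in the table. Observed cells are never altered and the
    result has no missing cells (idempotent).
    """
    values = table.values.copy()
    if strategy == "per_metabolite_min":
        all_missing = values.isna().all(axis=0)
        if all_missing.any():
            bad = list(values.columns[all_missing])
            raise ValueError(
                f"metabolites with no observed value (run lod_filter first): {bad}"
            )
        values = values.fillna(values.min(axis=0))
    elif strategy == "global_min":
        gmin = np.nanmin(values.to_numpy())
        if np.isnan(gmin):
            raise ValueError("table has no observed values")
        values = values.fillna(gmin)
    else:
        raise ValueError(f"unknown imputation strategy: {strategy!r}")
    return ConcentrationTable(values, table.metabolite_class, table.platform_tag)
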