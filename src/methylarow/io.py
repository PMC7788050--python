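"""Reading, validation, alignment and filtering of methylation-array tables.

The on-disk formats are plain tab-separated text in the style of a
GenomeStudio final-report export: a beta-value matrix keyed by Illumina
``TargetID`` (one CpG probe per row, one sample per column, values in
``[0, 1]``, ``NA`` for missing), an accompanying detection-p matrix with the
same layout, a sample sheet and a probe-annotation table.

Probe-level quality filtering follows standard array practice: a probe is
eliminated if its sequence overlaps a common variant (minor allele frequency
at or above a threshold) or if its detection p value is at or above a
threshold in *any* sample, i.e. the two criteria are a union of independent
exclusion causes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed class order used everywhere (tie-breaks, confusion-matrix axes).
CLASSES: tuple[str, ...] = ("ESC", "iPSC", "ECC", "somatic")
FOLD_GROUPS: tuple[str, ...] = ("A", "B", "C", "D")
DERIVATION_METHODS: tuple[str, ...] = ("Retro", "Sendai", "Episomal", "Lenti", "none")
GENE_FEATURE_GROUPS: tuple[str, ...] = (
    "TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "intergenic",
)
CGI_RELATIONS: tuple[str, ...] = (
    "Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea",
)


class FormatError(ValueError):
    """A file or table violates its documented contract."""


def _check_unique(labels: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise FormatError(f"duplicate {what}: {lab!r}")
        seen.add(lab)


@dataclass
class BetaMatrix:
    """Probes x samples table of methylation rates.

    ``data`` is a float64 DataFrame indexed by probe TargetID with sample IDs
    as columns. Values are beta methylation rates in ``[0, 1]``; missing
    measurements are ``NaN``.
    """

    data: pd.DataFrame
    value_name: str = "beta"

    def __post_init__(self) -> None:
        self.data = self.data.astype(np.float64)
        _check_unique(self.data.index, "TargetID")
        _check_unique(self.data.columns, "sample ID")
        self._validate_range()

    def _validate_range(self) -> None:
        vals = self.data.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = (vals < 0.0) | (vals > 1.0)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise FormatError(
                f"{self.value_name} value {vals[i, j]!r} outside [0, 1] at "
                f"probe {self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return BetaMatrix(self.data.loc[:, list(sample_ids)], self.value_name)

    def subset_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        missing = [p for p in probe_ids if p not in self.data.index]
        if missing:
            raise KeyError(f"probes not in matrix: {missing[:5]}")
        return BetaMatrix(self.data.loc[list(probe_ids)], self.value_name)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BetaMatrix):
            return NotImplemented
        return self.data.equals(other.data)


#: A detection-p matrix shares layout and validation with the beta matrix.
DetectionPMatrix = BetaMatrix


def read_beta_matrix(path: str | Path, value_name: str = "beta") -> BetaMatrix:
    """Read a TSV beta (or detection-p) matrix keyed by a TargetID column.

    Raises :class:`FormatError` naming the offending probe/sample for
    malformed headers, duplicate TargetIDs, non-numeric cells and values
    outside ``[0, 1]``. ``NA`` (and empty) cells become ``NaN``.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "TargetID":
        raise FormatError(
            f"{path}: first header column must be 'TargetID', got {header[:1]!r}"
        )
    _check_unique(header[1:], "sample ID")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], dtype=str)
    _check_unique(df.index, "TargetID")
    try:
        df = df.astype(np.float64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell: {exc}") from exc
    df.index = df.index.astype(str)
    df.index.name = "TargetID"
    return BetaMatrix(df, value_name=value_name)


def write_beta_matrix(beta: BetaMatrix, path: str | Path) -> None:
    """Write a beta matrix as TSV; round-trip through read is exact.

    Full ``repr`` precision is used so float64 values survive bitwise.
    """
    df = beta.data.copy()
    df.index.name = "TargetID"
    df.to_csv(path, sep="\t", na_rep="NA", float_format=lambda v: repr(float(v)))


def read_detection_p_matrix(path: str | Path) -> DetectionPMatrix:
    return read_beta_matrix(path, value_name="detection p")


_SHEET_COLUMNS = ("sample_id", "cell_type", "fold_group", "derivation_method", "parental_cell")


def validate_sample_sheet(sheet: pd.DataFrame, require_fold: bool = True) -> pd.DataFrame:
    """Validate token columns of a sample sheet; returns the sheet unchanged.

    Tokens are case-sensitive: cell types in ``CLASSES``, fold groups A-D,
    derivation methods Retro/Sendai/Episomal/Lenti/none (non-iPSC lines
    carry ``none``).
    """
    for col in ("sample_id", "cell_type"):
        if col not in sheet.columns:
            raise FormatError(f"sample sheet missing column {col!r}")
    _check_unique(sheet["sample_id"], "sample_id")
    bad = set(sheet["cell_type"]) - set(CLASSES)
    if bad:
        raise FormatError(f"unknown cell_type {sorted(bad)}; allowed: {list(CLASSES)}")
    if require_fold or "fold_group" in sheet.columns:
        bad = set(sheet["fold_group"].dropna()) - set(FOLD_GROUPS)
        if bad:
            raise FormatError(f"unknown fold_group {sorted(bad)}; allowed: {list(FOLD_GROUPS)}")
    if "derivation_method" in sheet.columns:
        bad = set(sheet["derivation_method"].dropna()) - set(DERIVATION_METHODS)
        if bad:
            raise FormatError(
                f"unknown derivation_method {sorted(bad)}; allowed: {list(DERIVATION_METHODS)}"
            )
    return sheet


def read_sample_sheet(path: str | Path, require_fold: bool = True) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    if "parental_cell" in sheet.columns:
        sheet["parental_cell"] = sheet["parental_cell"].fillna("")
    return validate_sample_sheet(sheet, require_fold=require_fold)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in _SHEET_COLUMNS if c in sheet.columns]
    sheet.loc[:, cols].to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a probe-annotation TSV into a DataFrame indexed by probe_id.

    ``gene_feature_groups`` is parsed from a semicolon-joined string into a
    frozenset of group labels; ``maf`` may be missing (``NaN``).
    """
    ann = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    for col in ("probe_id", "chromosome", "gene_feature_groups", "cgi_relation"):
        if col not in ann.columns:
            raise FormatError(f"annotation missing column {col!r}")
    _check_unique(ann["probe_id"], "probe_id")
    ann = ann.set_index("probe_id")
    ann["maf"] = pd.to_numeric(ann.get("maf"), errors="raise")
    with np.errstate(invalid="ignore"):
        bad = (ann["maf"] < 0) | (ann["maf"] > 0.5)
    if bad.any():
        raise FormatError(f"maf outside [0, 0.5] for probe {ann.index[bad.argmax()]!r}")
    groups = ann["gene_feature_groups"].map(
        lambda s: frozenset(s.split(";")) if isinstance(s, str) and s else frozenset()
    )
    unknown = set().union(*groups) - set(GENE_FEATURE_GROUPS)
    if unknown:
        raise FormatError(f"unknown gene feature groups {sorted(unknown)}")
    if (groups.map(len) == 0).any():
        raise FormatError("gene_feature_groups must be non-empty (use 'intergenic')")
    ann["gene_feature_groups"] = groups
    bad_cgi = set(ann["cgi_relation"].dropna()) - set(CGI_RELATIONS)
    if bad_cgi:
        raise FormatError(f"unknown cgi_relation {sorted(bad_cgi)}")
    return ann


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    out = ann.copy()
    out["gene_feature_groups"] = out["gene_feature_groups"].map(
        lambda g: ";".join(sorted(g))
    )
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", na_rep="")


def intersect_common_probes(matrices: Sequence[BetaMatrix]) -> list[BetaMatrix]:
    """Restrict every matrix to the probes common to all of them.

    Mirrors the merging of 450K and EPIC arrays, which share only part of
    their probe sets. Output probe order is sorted TargetID for determinism;
    sample columns are untouched.
    """
    if len(matrices) == 0:
        raise ValueError("need at least one matrix")
    common = set(matrices[0].probe_ids)
    for m in matrices[1:]:
        common &= set(m.probe_ids)
    if not common:
        raise ValueError("probe intersection is empty")
    order = sorted(common)
    return [m.subset_probes(order) for m in matrices]


@dataclass
class FilterReport:
    """Counts of probes removed by each quality criterion."""

    n_input: int
    n_maf_removed: int
    n_detp_removed: int
    n_removed: int
    n_kept: int
    n_unannotated: int = 0


def filter_probes(
    beta: BetaMatrix,
    annotation: pd.DataFrame,
    detp: DetectionPMatrix | None = None,
    maf_threshold: float = 0.05,
    detp_threshold: float = 0.05,
) -> tuple[BetaMatrix, FilterReport]:
    """Remove unreliable probes before analysis.

    A probe is eliminated if its annotated MAF is at or above
    ``maf_threshold`` (its sequence overlaps a common variant), or if its
    detection p value is at or above ``detp_threshold`` in at least one
    sample. Probes without annotation (or with missing MAF) are kept by the
    MAF criterion and logged. Input probe order is preserved; beta values are
    never altered.
    """
    probes = pd.Index(beta.probe_ids)
    maf = annotation["maf"].reindex(probes)
    n_unannotated = int(maf.isna().sum())
    maf_fail = (maf >= maf_threshold).fillna(False).to_numpy(bool)

    if detp is not None:
        if list(detp.probe_ids) != list(probes) or detp.sample_ids != beta.sample_ids:
            detp = BetaMatrix(
                detp.data.reindex(index=probes, columns=beta.sample_ids),
                detp.value_name,
            )
        with np.errstate(invalid="ignore"):
            detp_fail = np.nan_to_num(detp.data.to_numpy()) >= detp_threshold
        detp_fail = detp_fail.any(axis=1)
    else:
        detp_fail = np.zeros(len(probes), bool)

    removed = maf_fail | detp_fail
    report = FilterReport(
        n_input=len(probes),
        n_maf_removed=int(maf_fail.sum()),
        n_detp_removed=int(detp_fail.sum()),
        n_removed=int(removed.sum()),
        n_kept=int((~removed).sum()),
        n_unannotated=n_unannotated,
    )
    logger.info(
        "filter_probes: %d input, %d removed (MAF %d, detection-p %d), %d kept, "
        "%d without MAF annotation (kept on MAF criterion)",
        report.n_input, report.n_removed, report.n_maf_removed,
        report.n_detp_removed, report.n_kept, report.n_unannotated,
    )
    kept = probes[~removed]
    return beta.subset_probes(list(kept)), report
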