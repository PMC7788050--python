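"""Mining determination weights: high-weight sites and the cross-fold signature.

For each learned model, the ESC and iPSC class weight vectors are combined
into one joint table of (class, probe, weight) entries — weights of the two
class models within one learned model are directly comparable — and the
top-K and bottom-K entries across the combined table are the positive and
negative high-weight sites. Intersecting each class/sign set across the
four cross-validation folds gives the common high-weight sites, and the two
cross-class intersections define the epigenetic signature:

* ``esc_pos_ipsc_neg`` — probes common to the ESC positive and iPSC
  negative sets (methylation argues for ESC, against iPSC);
* ``ipsc_pos_esc_neg`` — probes common to the iPSC positive and ESC
  negative sets (the iPSC-specific signature core).

Ties at the K-th rank are broken deterministically by class order, then
lexicographic probe ID.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .arow import MulticlassArowModel

Entry = tuple[str, str]  # (class, probe_id)


def extract_weight_table(
    model: MulticlassArowModel, classes: Sequence[str] = ("ESC", "iPSC")
) -> pd.DataFrame:
    """Combined per-class determination weights as a (class, probe, weight) table."""
    frames = []
    for cls in classes:
        c = model.classes.index(cls)
        frames.append(
            pd.DataFrame(
                {"class": cls, "probe_id": model.probe_ids, "weight": model.mu[c]}
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class HighWeightSelection:
    series_id: int
    k: int
    positive_set: frozenset[Entry]
    negative_set: frozenset[Entry]


def select_high_weight(
    table: pd.DataFrame, k: int = 2000, series_id: int = 0,
    class_order: Sequence[str] = ("ESC", "iPSC"),
) -> HighWeightSelection:
    """Top-k and bottom-k entries of the combined weight table.

    Selection is a joint ranking over all (class, probe) entries, so the two
    classes may contribute unequal counts to either set.
    """
    if k > len(table):
        raise ValueError(f"k={k} exceeds table size {len(table)}")
    rank = {c: i for i, c in enumerate(class_order)}
    df = table.assign(_corder=table["class"].map(rank))
    top = df.sort_values(
        by=["weight", "_corder", "probe_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).head(k)
    bottom = df.sort_values(
        by=["weight", "_corder", "probe_id"],
        ascending=[True, True, True],
        kind="mergesort",
    ).head(k)
    as_set = lambda d: frozenset(zip(d["class"], d["probe_id"]))
    return HighWeightSelection(
        series_id=series_id, k=k,
        positive_set=as_set(top), negative_set=as_set(bottom),
    )


def per_class_counts(selection: HighWeightSelection) -> dict[str, int]:
    """Counts of positive/negative high-weight entries per class."""
    out: dict[str, int] = {}
    for sign, entries in (("pos", selection.positive_set), ("neg", selection.negative_set)):
        for cls, _ in entries:
            out[f"{cls}_{sign}"] = out.get(f"{cls}_{sign}", 0) + 1
    return out


def high_weight_count_summary(
    selections: Sequence[HighWeightSelection],
    classes: Sequence[str] = ("ESC", "iPSC"),
) -> pd.DataFrame:
    """Across-series mean and SEM of per-class high-weight counts."""
    rows = [per_class_counts(sel) for sel in selections]
    df = pd.DataFrame(rows).fillna(0.0)
    for cls in classes:
        for sign in ("pos", "neg"):
            if f"{cls}_{sign}" not in df.columns:
                df[f"{cls}_{sign}"] = 0.0
    n = len(df)
    summary = pd.DataFrame(
        {
            "mean": df.mean(),
            "sem": df.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
        }
    )
    summary.index.name = "class_sign"
    return summary


@dataclass(frozen=True)
class CommonSignature:
    """Cross-fold common high-weight probes and the cross-class signature."""

    common_sites: dict[str, dict[str, frozenset[str]]]  # class -> sign -> probes
    esc_pos_ipsc_neg: frozenset[str]
    ipsc_pos_esc_neg: frozenset[str]


def common_sites(
    selections: Sequence[HighWeightSelection],
    classes: Sequence[str] = ("ESC", "iPSC"),
) -> CommonSignature:
    """Intersect high-weight sets across folds, then across classes."""
    if not selections:
        raise ValueError("no selections")
    common: dict[str, dict[str, frozenset[str]]] = {}
    for cls in classes:
        common[cls] = {}
        for sign, attr in (("pos", "positive_set"), ("neg", "negative_set")):
            per_fold = [
                frozenset(p for c, p in getattr(sel, attr) if c == cls)
                for sel in selections
            ]
            common[cls][sign] = frozenset.intersection(*per_fold)
    return CommonSignature(
        common_sites=common,
        esc_pos_ipsc_neg=common["ESC"]["pos"] & common["iPSC"]["neg"],
        ipsc_pos_esc_neg=common["iPSC"]["pos"] & common["ESC"]["neg"],
    )


def annotate_counts(
    sites: Iterable[str],
    annotation: pd.DataFrame,
    facet: str,
) -> pd.DataFrame:
    """Category counts and proportions of a probe set for one annotation facet.

    ``facet`` is one of ``gene_feature``, ``cgi_relation``, ``chromosome``.
    For the gene-feature facet, a probe carrying several groups contributes
    once to each, so counts may exceed the number of sites; proportions are
    normalized by total contributions.
    """
    sites = list(sites)
    missing = [p for p in sites if p not in annotation.index]
    if missing:
        raise KeyError(f"sites without annotation, e.g. {missing[:3]}")
    tally: dict[str, int] = {}
    if facet == "gene_feature":
        for p in sites:
            for g in sorted(annotation.at[p, "gene_feature_groups"]):
                tally[g] = tally.get(g, 0) + 1
    elif facet in ("cgi_relation", "chromosome"):
        for p in sites:
            cat = str(annotation.at[p, facet])
            tally[cat] = tally.get(cat, 0) + 1
    else:
        raise ValueError(f"unknown facet {facet!r}")
    total = sum(tally.values())
    df = pd.DataFrame(
        {
            "category": list(tally),
            "count": list(tally.values()),
        }
    ).sort_values("category", kind="mergesort", ignore_index=True)
    df["proportion"] = df["count"] / total if total else 0.0
    return df


def signature_table(
    signature: CommonSignature,
    selections: Sequence[HighWeightSelection],
    weight_tables: Sequence[pd.DataFrame],
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Flat TSV-ready table of signature probes with per-fold weights."""
    rows = []
    for name, cls, sign in (
        ("esc_pos_ipsc_neg", "ESC", "pos"),
        ("ipsc_pos_esc_neg", "iPSC", "pos"),
    ):
        for probe in sorted(getattr(signature, name)):
            row: dict[str, object] = {"signature": name, "probe_id": probe,
                                      "class": cls, "sign": sign}
            for sel, wt in zip(selections, weight_tables):
                w = wt.loc[(wt["class"] == cls) & (wt["probe_id"] == probe), "weight"]
                row[f"weight_series{sel.series_id}"] = float(w.iloc[0]) if len(w) else np.nan
            if annotation is not None and probe in annotation.index:
                row["chromosome"] = annotation.at[probe, "chromosome"]
                row["cgi_relation"] = annotation.at[probe, "cgi_relation"]
                row["gene_feature_groups"] = ";".join(
                    sorted(annotation.at[probe, "gene_feature_groups"])
                )
            rows.append(row)
    return pd.DataFrame(rows)
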