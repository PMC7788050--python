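"""Differential-methylation counts and subsample-resampling variability.

A differentially methylated region (DMR) is, in this analysis, a single CpG
site whose group-mean beta values differ by at least a threshold (default
0.3) between two sample groups. To compare groups of unequal size on an
equal footing, statistics are computed on random subsamples: ``n`` samples
(default 15) are drawn without replacement from each pool, the statistic is
computed, and the draw is repeated ``reps`` times (default 100); the mean
and SEM (sample SD / sqrt(reps)) over repetitions are reported.

The same resampling scheme supports per-probe standard-deviation
histograms (how many CpG sites fall in each SD range across the drawn
samples) and within-cell-type variably methylated site counts (beta range
max - min at or above a threshold among the drawn samples).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import BetaMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResamplingResult:
    statistic: str
    n_per_group: int
    reps: int
    values: tuple[float, ...]
    mean: float
    sem: float

    @staticmethod
    def from_values(statistic: str, n_per_group: int, values: Sequence[float]) -> "ResamplingResult":
        arr = np.asarray(values, dtype=np.float64)
        reps = len(arr)
        sem = float(arr.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
        return ResamplingResult(
            statistic=statistic, n_per_group=n_per_group, reps=reps,
            values=tuple(map(float, arr)), mean=float(arr.mean()), sem=sem,
        )


def _group_means(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe mean over non-missing values, plus an all-missing mask."""
    vals = data.to_numpy()
    counts = (~np.isnan(vals)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(vals, axis=1)
    return means, counts == 0


def dmr_count(betaA: BetaMatrix, betaB: BetaMatrix, threshold: float = 0.3) -> int:
    """Number of CpG sites whose group-mean beta differs by >= threshold.

    Missing values are excluded from group means; a probe entirely missing
    in either group is skipped and logged.
    """
    if betaA.probe_ids != betaB.probe_ids:
        raise ValueError("groups must share an identical probe set")
    meansA, emptyA = _group_means(betaA.data)
    meansB, emptyB = _group_means(betaB.data)
    skipped = emptyA | emptyB
    if skipped.any():
        logger.info("dmr_count: %d probes all-missing in a group, skipped", skipped.sum())
    with np.errstate(invalid="ignore"):
        hits = np.abs(meansA - meansB) >= threshold
    return int((hits & ~skipped).sum())


def resampled_dmr_mean(
    beta: BetaMatrix,
    groupA_samples: Sequence[str],
    groupB_samples: Sequence[str],
    n: int = 15,
    reps: int = 100,
    threshold: float = 0.3,
    rng: np.random.Generator | None = None,
) -> ResamplingResult:
    """Mean +/- SEM DMR count over repeated size-n subsamples of each pool."""
    rng = rng or np.random.default_rng()
    poolA, poolB = list(groupA_samples), list(groupB_samples)
    if len(poolA) < n or len(poolB) < n:
        raise ValueError(f"both pools must hold at least n={n} samples")
    counts = []
    for _ in range(reps):
        subA = [poolA[i] for i in rng.choice(len(poolA), size=n, replace=False)]
        subB = [poolB[i] for i in rng.choice(len(poolB), size=n, replace=False)]
        counts.append(dmr_count(beta.subset_samples(subA), beta.subset_samples(subB), threshold))
    return ResamplingResult.from_values("dmr_count", n, counts)


@dataclass(frozen=True)
class SdHistogram:
    bin_edges: tuple[float, ...]
    mean_counts: tuple[float, ...]
    sem_counts: tuple[float, ...]
    high_sd_threshold: float
    high_sd_mean_count: float
    high_sd_sem: float
    n_probes: int
    reps: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "mean_count": self.mean_counts,
                "sem": self.sem_counts,
            }
        )


def sd_range_histogram(
    beta: BetaMatrix,
    sample_pool: Sequence[str],
    n: int = 15,
    reps: int = 100,
    bins: Sequence[float] | None = None,
    high_sd_threshold: float = 0.10,
    rng: np.random.Generator | None = None,
) -> SdHistogram:
    """Mean +/- SEM counts of CpG sites per SD range over resampled draws.

    Default bins are width 0.05 on [0, 0.5] with a final catch-all edge at
    the maximum possible beta SD, so per-repetition bin counts always sum
    to the number of probes. The "high SD" count tallies probes with SD at
    or above ``high_sd_threshold``.
    """
    rng = rng or np.random.default_rng()
    pool = list(sample_pool)
    if len(pool) < n:
        raise ValueError(f"pool must hold at least n={n} samples")
    if bins is None:
        bins = list(np.round(np.arange(0.0, 0.5001, 0.05), 10))
    edges = np.asarray(bins, dtype=np.float64)
    # beta in [0,1] bounds the population SD by 0.5; pad so nothing falls out
    if edges[-1] <= 0.5:
        edges = np.append(edges, 0.5 + 1e-9)
    per_rep = np.empty((reps, len(edges) - 1))
    high = np.empty(reps)
    X = beta.data.to_numpy()
    col = {s: j for j, s in enumerate(beta.sample_ids)}
    for rep in range(reps):
        sub = [pool[i] for i in rng.choice(len(pool), size=n, replace=False)]
        vals = X[:, [col[s] for s in sub]]
        sd = np.nanstd(vals, axis=1, ddof=0)
        per_rep[rep], _ = np.histogram(sd, bins=edges)
        high[rep] = (sd >= high_sd_threshold).sum()
    sem = per_rep.std(axis=0, ddof=1) / np.sqrt(reps) if reps > 1 else np.zeros(per_rep.shape[1])
    return SdHistogram(
        bin_edges=tuple(map(float, edges)),
        mean_counts=tuple(map(float, per_rep.mean(axis=0))),
        sem_counts=tuple(map(float, sem)),
        high_sd_threshold=high_sd_threshold,
        high_sd_mean_count=float(high.mean()),
        high_sd_sem=float(high.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0,
        n_probes=X.shape[0],
        reps=reps,
    )


def within_type_variable_count(
    beta: BetaMatrix,
    samples_of_one_type: Sequence[str],
    n: int = 15,
    reps: int = 100,
    range_threshold: float = 0.3,
    rng: np.random.Generator | None = None,
) -> ResamplingResult:
    """Mean count of probes whose beta range >= threshold within one cell type.

    Per repetition, n samples of the type are drawn and probes whose
    max - min beta across them reaches ``range_threshold`` are counted.
    """
    rng = rng or np.random.default_rng()
    pool = list(samples_of_one_type)
    if len(pool) < n:
        raise ValueError(f"pool must hold at least n={n} samples")
    X = beta.data.to_numpy()
    col = {s: j for j, s in enumerate(beta.sample_ids)}
    counts = []
    for _ in range(reps):
        sub = [pool[i] for i in rng.choice(len(pool), size=n, replace=False)]
        vals = X[:, [col[s] for s in sub]]
        with np.errstate(invalid="ignore"):
            rng_span = np.nanmax(vals, axis=1) - np.nanmin(vals, axis=1)
        counts.append(int((rng_span >= range_threshold).sum()))
    return ResamplingResult.from_values("within_type_variable_count", n, counts)


def site_methylation_profile(
    beta: BetaMatrix,
    sites: Sequence[str],
    sheet: pd.DataFrame,
    grouping: str = "cell_type",
) -> pd.DataFrame:
    """Per-site, per-group beta summaries (min/max/mean/SD and values).

    ``grouping`` names a sample-sheet column (cell_type, derivation_method,
    parental_cell). Returns one row per (site, group).
    """
    if grouping not in sheet.columns:
        raise KeyError(f"sample sheet has no column {grouping!r}")
    sub = beta.subset_probes(list(sites))
    rows = []
    for group, members in sheet.groupby(grouping)["sample_id"]:
        cols = [s for s in members if s in sub.data.columns]
        if not cols:
            continue
        vals = sub.data.loc[:, cols]
        for site in sites:
            v = vals.loc[site].to_numpy(dtype=np.float64)
            v = v[~np.isnan(v)]
            rows.append(
                {
                    "site": site,
                    "group": group,
                    "n": len(v),
                    "min": float(v.min()) if len(v) else np.nan,
                    "max": float(v.max()) if len(v) else np.nan,
                    "mean": float(v.mean()) if len(v) else np.nan,
                    "sd": float(v.std(ddof=0)) if len(v) else np.nan,
                    "values": ",".join(repr(float(x)) for x in v),
                }
            )
    return pd.DataFrame(rows)
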