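"""Synthetic methylation-array cohorts with known ground truth.

The generator emulates the statistical structure of a methylation study of
pluripotent and somatic cell lines — 27 ESC, 43 iPSC, 9 ECC and 25 somatic
lines by default, one array sample per line — so the whole pipeline can be
exercised and its recovery quantified without any data download.

Per-probe archetypes
--------------------
* ``pluripotency_hypo`` — hypomethylated in pluripotent cells (ESC, iPSC,
  ECC), highly methylated in somatic cells, as at promoters of
  pluripotency-associated genes.
* ``somatic_hypo``      — the mirror image (somatic-cell-associated genes).
* ``ecc_marker``        — highly methylated in ECCs only, so the ECC class
  is separable from the other pluripotent types.
* ``esc_variable``      — same mean everywhere but strongly inflated noise
  in ESC lines (ESCs carry more background variability genome-wide).
* ``ipsc_variable``     — each iPSC *line* gets its own methylation level
  drawn from a wide distribution, while ESC/ECC/somatic sit at a low mean;
  these are the probes an iPSC-specific signature should recover. Their
  annotations are enriched near TSS/1st-exon and CpG islands.
* ``ipsc_method_marker`` — residual reprogramming signatures: each probe is
  tied to one derivation method (Retro/Sendai/Episomal/Lenti) and mildly
  elevated only in iPSC lines made with that method. Individually weak
  (group means stay well below the DMR threshold), collectively they force
  the iPSC class model to spread weight over many CpGs, as a heterogeneous
  class does.
* ``esc_marker``        — a small set of crisp ESC-specific hypermethylated
  loci, so the ESC model can anchor its identity on few sites.
* ``neutral``           — the remaining background, class-independent.

Beta values are drawn from a Beta distribution parameterized by mean ``m``
and concentration ``k`` (shape ``a = m*k``, ``b = (1-m)*k``): variance
shrinks near 0 and 1, as on real arrays. ESC samples use a slightly lower
concentration than other classes (more background noise).

A configurable number of "filter spike" probes (taken from the neutral
pool) are destined for removal by quality control: either an annotated
minor allele frequency at or above 5%, or a detection p value at or above
0.05 in at least one sample. The emitted :class:`SyntheticTruth` records
every probe's archetype, per-class target means and spike flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .crossval import assign_fold_groups
from .io import (
    CGI_RELATIONS,
    CLASSES,
    GENE_FEATURE_GROUPS,
    BetaMatrix,
    DetectionPMatrix,
    validate_sample_sheet,
)

_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

_BASE_GENE_FEATURE_P = {
    "Body": 0.34, "TSS1500": 0.12, "TSS200": 0.10, "5'UTR": 0.10,
    "1stExon": 0.06, "3'UTR": 0.04, "intergenic": 0.24,
}
_IPSC_VARIABLE_GENE_FEATURE_P = {
    "TSS200": 0.30, "TSS1500": 0.20, "1stExon": 0.20, "Body": 0.20, "5'UTR": 0.10,
}
_BASE_CGI_P = {
    "Island": 0.31, "N_Shore": 0.12, "S_Shore": 0.10,
    "N_Shelf": 0.05, "S_Shelf": 0.04, "OpenSea": 0.38,
}
_IPSC_VARIABLE_CGI_P = {
    "Island": 0.60, "N_Shore": 0.15, "S_Shore": 0.15, "N_Shelf": 0.02,
    "S_Shelf": 0.02, "OpenSea": 0.06,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of the synthetic cohort (defaults = study scale)."""

    n_probes: int = 20_000
    class_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"ESC": 27, "iPSC": 43, "ECC": 9, "somatic": 25}
    )
    # archetype fractions of n_probes (remainder is neutral background)
    frac_pluripotency_hypo: float = 0.04
    frac_somatic_hypo: float = 0.04
    frac_esc_variable: float = 0.05
    frac_ipsc_variable: float = 0.01
    frac_ipsc_method_marker: float = 0.03
    frac_ecc_marker: float = 0.01
    frac_esc_marker: float = 0.005
    # beta levels
    low_mean: float = 0.10
    high_mean: float = 0.85
    esc_variable_mean: float = 0.35
    ipsc_variable_range: tuple[float, float] = (0.05, 0.95)
    method_marker_mean: float = 0.55
    # noise concentrations (Beta distribution, higher = tighter)
    noise_concentration: float = 150.0
    esc_variable_concentration: float = 8.0
    # quality-control spikes
    n_maf_fail: int = 120
    n_detp_fail: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        total_frac = (
            self.frac_pluripotency_hypo + self.frac_somatic_hypo
            + self.frac_esc_variable + self.frac_ipsc_variable
            + self.frac_ipsc_method_marker + self.frac_ecc_marker
            + self.frac_esc_marker
        )
        if total_frac > 1:
            raise ValueError("archetype fractions must sum to at most 1")
        for m in (self.low_mean, self.high_mean, self.esc_variable_mean):
            if not 0 < m < 1:
                raise ValueError("beta means must lie in (0, 1)")
        if any(n < 5 for n in self.class_sizes.values()):
            raise ValueError("class sizes must be at least 5")
        if set(self.class_sizes) != set(CLASSES):
            raise ValueError(f"class_sizes must cover exactly {list(CLASSES)}")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, one row per probe."""

    table: pd.DataFrame  # archetype, maf_fail, detp_fail, mean_<class>
    ipsc_line_means: pd.DataFrame  # ipsc_variable probes x iPSC samples
    config: SimulationConfig

    def probes_of(self, archetype: str) -> list[str]:
        return list(self.table.index[self.table["archetype"] == archetype])

    def planted_between_class_probes(
        self, class_a: str = "ESC", class_b: str = "iPSC", threshold: float = 0.3
    ) -> list[str]:
        """Probes whose population-level class means differ by >= threshold."""
        diff = (self.table[f"mean_{class_a}"] - self.table[f"mean_{class_b}"]).abs()
        return list(self.table.index[diff >= threshold])


def _sample_ids(class_sizes: Mapping[str, int]) -> tuple[list[str], list[str]]:
    ids, types = [], []
    for cls in CLASSES:
        for i in range(class_sizes[cls]):
            ids.append(f"{cls}_{i + 1:02d}")
            types.append(cls)
    return ids, types


def _categorical(rng: np.random.Generator, p: Mapping[str, float], size: int) -> np.ndarray:
    cats = list(p)
    probs = np.array([p[c] for c in cats], dtype=float)
    probs /= probs.sum()
    return rng.choice(cats, size=size, p=probs)


def generate_cohort(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[BetaMatrix, pd.DataFrame, pd.DataFrame, DetectionPMatrix, SyntheticTruth]:
    """Generate (beta, sample sheet, annotation, detection-p, truth).

    Fully deterministic given ``seed`` (falls back to ``config.seed``).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_probes
    sample_ids, cell_types = _sample_ids(config.class_sizes)
    n_samples = len(sample_ids)
    probe_ids = [f"cg{i + 1:08d}" for i in range(n)]

    # --- derivation methods (drawn first; method markers depend on them) -----
    methods = ("Retro", "Sendai", "Episomal", "Lenti")
    derivation = []
    parental = []
    for t in cell_types:
        if t == "iPSC":
            derivation.append(str(rng.choice(methods, p=[0.4, 0.25, 0.25, 0.1])))
            parental.append(
                str(rng.choice(["fibroblast", "blood", "keratinocyte"],
                               p=[0.6, 0.3, 0.1]))
            )
        else:
            derivation.append("none")
            parental.append("")

    # --- archetype assignment ------------------------------------------------
    counts = {
        "pluripotency_hypo": round(config.frac_pluripotency_hypo * n),
        "somatic_hypo": round(config.frac_somatic_hypo * n),
        "esc_variable": round(config.frac_esc_variable * n),
        "ipsc_variable": round(config.frac_ipsc_variable * n),
        "ipsc_method_marker": round(config.frac_ipsc_method_marker * n),
        "ecc_marker": round(config.frac_ecc_marker * n),
        "esc_marker": round(config.frac_esc_marker * n),
    }
    archetypes = np.array(["neutral"] * n, dtype=object)
    perm = rng.permutation(n)
    start = 0
    for name, cnt in counts.items():
        archetypes[perm[start:start + cnt]] = name
        start += cnt
    neutral_idx = perm[start:]
    if len(neutral_idx) < config.n_maf_fail + config.n_detp_fail:
        raise ValueError("not enough neutral probes for the requested filter spikes")
    maf_fail_idx = neutral_idx[: config.n_maf_fail]
    detp_fail_idx = neutral_idx[config.n_maf_fail: config.n_maf_fail + config.n_detp_fail]

    # --- per-class target means ---------------------------------------------
    lo, hi = config.low_mean, config.high_mean
    means = np.empty((n, len(CLASSES)))
    # bimodal background levels, shared across classes
    neutral_levels = 0.02 + 0.96 * rng.beta(0.4, 0.4, size=n)
    means[:] = neutral_levels[:, None]
    sel = archetypes == "pluripotency_hypo"
    means[sel] = [lo, lo, lo, hi]  # ESC, iPSC, ECC, somatic
    sel = archetypes == "somatic_hypo"
    means[sel] = [hi, hi, hi, lo]
    sel = archetypes == "ecc_marker"
    means[sel] = [lo, lo, hi, lo]
    sel = archetypes == "esc_marker"
    means[sel] = [hi, lo, lo, lo]
    sel = archetypes == "esc_variable"
    means[sel] = config.esc_variable_mean
    ipsc_sel = archetypes == "ipsc_variable"
    means[ipsc_sel] = lo
    method_sel = archetypes == "ipsc_method_marker"
    means[method_sel] = lo

    # iPSC lines get line-level means at ipsc_variable probes
    ipsc_cols = [j for j, t in enumerate(cell_types) if t == "iPSC"]
    a, b = config.ipsc_variable_range
    line_means = rng.uniform(a, b, size=(int(ipsc_sel.sum()), len(ipsc_cols)))

    class_col = {c: k for k, c in enumerate(CLASSES)}
    mean_matrix = means[:, [class_col[t] for t in cell_types]]
    mean_matrix[np.ix_(ipsc_sel, ipsc_cols)] = line_means

    # method markers: each probe elevated only in iPSC lines of one method
    method_rows = np.flatnonzero(method_sel)
    probe_method = rng.choice(methods, size=len(method_rows))
    method_frac = np.zeros(len(method_rows))  # iPSC-population mixing weight
    n_ipsc = len(ipsc_cols)
    for meth in methods:
        cols = [j for j in ipsc_cols if derivation[j] == meth]
        rows = method_rows[probe_method == meth]
        if cols and len(rows):
            mean_matrix[np.ix_(rows, cols)] = config.method_marker_mean
        method_frac[probe_method == meth] = len(cols) / n_ipsc if n_ipsc else 0.0

    conc = np.full((n, n_samples), config.noise_concentration)
    esc_cols = [j for j, t in enumerate(cell_types) if t == "ESC"]
    conc[np.ix_(archetypes == "esc_variable", esc_cols)] = config.esc_variable_concentration

    beta_vals = rng.beta(mean_matrix * conc, (1.0 - mean_matrix) * conc)
    beta = BetaMatrix(pd.DataFrame(beta_vals, index=probe_ids, columns=sample_ids))

    # --- detection p and MAF spikes -----------------------------------------
    detp_vals = rng.uniform(0.0, 0.04, size=(n, n_samples))
    for i in detp_fail_idx:
        n_bad = int(rng.integers(1, 4))
        cols = rng.choice(n_samples, size=n_bad, replace=False)
        detp_vals[i, cols] = rng.uniform(0.05, 0.6, size=n_bad)
    detp = DetectionPMatrix(
        pd.DataFrame(detp_vals, index=probe_ids, columns=sample_ids),
        value_name="detection p",
    )

    maf = np.full(n, np.nan)
    common_variant = rng.random(n) < 0.3
    maf[common_variant] = rng.uniform(0.0, 0.0499, size=int(common_variant.sum()))
    maf[maf_fail_idx] = rng.uniform(0.05, 0.5, size=len(maf_fail_idx))

    # --- annotation ----------------------------------------------------------
    chromosome = rng.choice(_CHROMOSOMES, size=n)
    gene_feature = _categorical(rng, _BASE_GENE_FEATURE_P, n)
    cgi = _categorical(rng, _BASE_CGI_P, n)
    n_var = int(ipsc_sel.sum())
    gene_feature[ipsc_sel] = _categorical(rng, _IPSC_VARIABLE_GENE_FEATURE_P, n_var)
    cgi[ipsc_sel] = _categorical(rng, _IPSC_VARIABLE_CGI_P, n_var)
    groups = []
    second = rng.random(n) < 0.25
    extra = rng.choice([g for g in GENE_FEATURE_GROUPS if g != "intergenic"], size=n)
    for i in range(n):
        g = {gene_feature[i]}
        if second[i] and gene_feature[i] != "intergenic":
            g.add(str(extra[i]))
        groups.append(frozenset(g))
    annotation = pd.DataFrame(
        {
            "chromosome": chromosome,
            "gene_feature_groups": groups,
            "cgi_relation": cgi,
            "maf": maf,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )

    # --- sample sheet --------------------------------------------------------
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cell_type": cell_types,
            "derivation_method": derivation,
            "parental_cell": parental,
        }
    )
    sheet = assign_fold_groups(sheet, rng)
    validate_sample_sheet(sheet)

    # --- truth ---------------------------------------------------------------
    truth_means = means.copy()
    if n_var:
        truth_means[ipsc_sel, class_col["iPSC"]] = line_means.mean(axis=1)
    if len(method_rows):
        # iPSC population mean: mixture over lines of the probe's method
        truth_means[method_rows, class_col["iPSC"]] = (
            lo + method_frac * (config.method_marker_mean - lo)
        )
    truth = pd.DataFrame(
        {
            "archetype": archetypes,
            "maf_fail": np.isin(np.arange(n), maf_fail_idx),
            "detp_fail": np.isin(np.arange(n), detp_fail_idx),
            **{f"mean_{c}": truth_means[:, class_col[c]] for c in CLASSES},
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    line_mean_df = pd.DataFrame(
        line_means,
        index=[probe_ids[i] for i in np.flatnonzero(ipsc_sel)],
        columns=[sample_ids[j] for j in ipsc_cols],
    )
    return beta, sheet, annotation, detp, SyntheticTruth(truth, line_mean_df, config)


def write_truth(truth: SyntheticTruth, path) -> None:
    truth.table.to_csv(path, sep="\t", na_rep="NA")


def generate_toy_confusion_cohort() -> list[tuple[str, str]]:
    """104 (true, predicted) label pairs matching the benchmark confusion table.

    Row counts: ESC 27 (25 correct, 2 as iPSC), iPSC 43 (40 correct, 3 as
    ESC), ECC 9 (8 correct, 1 as somatic), somatic 25 (all correct).
    """
    pairs: list[tuple[str, str]] = []
    pairs += [("ESC", "ESC")] * 25 + [("ESC", "iPSC")] * 2
    pairs += [("iPSC", "ESC")] * 3 + [("iPSC", "iPSC")] * 40
    pairs += [("ECC", "ECC")] * 8 + [("ECC", "somatic")] * 1
    pairs += [("somatic", "somatic")] * 25
    return pairs
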