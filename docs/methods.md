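# Methods

## Data model and quality control

A methylation cohort is a probes × samples matrix of β values (fraction
methylated, in [0, 1]; `NaN` for failed measurements) keyed by Illumina
TargetID, with a sample sheet (cell type, fold group A–D, derivation
method, parental cell) and a probe annotation (chromosome, gene-feature
groups, CpG-island relation, minor allele frequency). The package consumes
already-normalized β values; IDAT parsing, background subtraction and
normalization are out of scope.

Probe filtering removes a probe when either of two independent quality
criteria fires: annotated MAF ≥ `maf_threshold` (default 0.05 — the probe
sequence overlaps a common variant, so the signal may be genetic rather
than epigenetic), or detection p ≥ `detp_threshold` (default 0.05) in *at
least one* sample. The per-sample reading of the detection criterion is the
conservative one — a probe must be reliable in every sample to enter the
analysis. Both boundaries are inclusive (`≥`). Probes without MAF
annotation are kept by the MAF criterion (absence of evidence) and counted
in the filter report. Filtering only ever selects rows; β values are never
altered, so the operation is idempotent. When several arrays are merged
(450K and EPIC share only part of their probe sets), matrices are first
reduced to their common probes, sorted lexicographically by TargetID for
determinism.

## The classifier

AROW keeps per feature a weight mean μ and a positive diagonal confidence
Σ (initialized μ = 0, Σ = 1). With margin m = y(μ·x) and regularization
weight r > 0, an example with m ≥ 1 leaves the model untouched; otherwise

    β = 1 / (Σx·x + r),  α = max(0, 1 − m)β,
    μ ← μ + αyΣx,        Σ ← Σ − β(Σx)².

Σ entries only shrink and stay positive, so confident (frequently
observed) features receive ever smaller corrections. The diagonal variant
is the only practical one at array scale (hundreds of thousands of
features); a full covariance would be quadratic in probe count.

Design choices fixed here:

* **No bias term.** The decision score is exactly Σ μ_j x_j (methylation
  rate × determination weight). A constant feature would change the
  semantics of the weights that the signature analysis mines.
* **One-vs-others with all models updated.** Each of the four class models
  is updated on every training sample (y = +1 for its class, −1
  otherwise). Prediction is the argmax of the four scores, ties broken by
  the fixed class order (ESC, iPSC, ECC, somatic); with real-valued
  weights ties have measure zero, the rule exists for determinism.
* **Epochs are shuffles.** One epoch presents every training sample
  exactly once in an order drawn from the run's random stream — sampling
  without replacement, so epoch counts are comparable across runs.
* **Missing β contributes 0** to dot products and updates (the feature is
  simply absent from that sample).

## Cross-validation protocol

Lines are divided into four groups A–D, stratified by cell type (shuffled
round-robin, so per-class group sizes differ by at most one). The four
series are fixed: Series-1 trains on B,C,D and tests on A; Series-2 on
C,D,A / B; Series-3 on D,A,B / C; Series-4 on A,B,C / D. For every
(series, r) cell the model trains `epochs` (default 300) epochs and is
assessed on its training and test folds every `checkpoint_every` (default
10) epochs; the default r grid is (0.10, 0.25, 0.50, 0.90, 1.00, 1.10),
giving 4 × 6 × 30 = 720 checkpoint records from 7,200 trained epochs.

Each (series, r) cell derives its own random stream from
`SeedSequence([master_seed, series_id, r_index])`, so any cell is
reproducible in isolation and results are independent of sweep order.

The optimal (epoch, r) maximizes the *test* macro F-score averaged over
the four series; the training average is only a tie-breaker (then smaller
epoch, then smaller r). Selecting on test folds leaks information — the
selected cell's pooled metrics are mildly optimistic. This mirrors the
protocol being reproduced and is deliberately not "fixed"; an outer
validation split would be required for unbiased error estimation.

Pooled ("mixed") evaluation concatenates the four series' test-fold
predictions at the selected cell, so each cohort line contributes exactly
once to the 4×4 confusion matrix. Metrics follow the reference formulas:
per-class precision (column) and recall (row), macro averages are
unweighted means over the four classes, the macro F-score is the harmonic
mean of macro precision and macro recall — *not* the mean of per-class
F-scores, a convention that matters in the second decimal — and accuracy
is the trace over the total. Per-class values with a zero denominator
(a class never predicted at a degenerate early checkpoint) are flagged NaN
and enter macro averages as 0 with a warning, keeping the selection
criterion defined everywhere. Displayed percentages are rounded half-up to
two decimals; all internal computation keeps full precision.

## Weight mining

Within one learned model the per-class determination weights are directly
comparable, so the ESC and iPSC weight vectors are *combined* into a single
table of 2 × n_probes (class, probe, weight) entries and ranked jointly:
the K largest entries form the positive high-weight set, the K smallest
the negative set (K default 2,000; ties at the K-th rank broken by class
order then probe ID, so selection is deterministic). Joint ranking is what
lets the two classes contribute unequal counts — the per-class share of
the top/bottom sets is itself a finding.

Intersecting each class/sign set across the four folds gives the common
high-weight sites; the cross-class intersections define the signature:
`esc_pos_ipsc_neg` (methylation argues for ESC and against iPSC) and
`ipsc_pos_esc_neg` (the iPSC-specific core). Annotation summaries count a
probe once per gene-feature group it carries (a probe may be both TSS200
and Body; proportions are normalized by total contributions), while
CpG-island relation and chromosome are single-valued.

## Variability statistics

A DMR is a single CpG whose two group-mean β values differ by ≥ 0.3
(inclusive; means over non-missing values; a probe entirely missing in a
group is skipped and logged). Group means are arithmetic means of β, the
standard choice for β-difference screens. Because the pools are unequal
(e.g. 27 ESC vs 43 iPSC lines), statistics are computed on `n` = 15 lines
drawn without replacement from each pool and repeated `reps` = 100 times;
the mean and SEM (sample SD/√reps) over repetitions are reported.

The same resampling drives per-CpG SD histograms (bins of width 0.05 on
[0, 0.5], plus a guard bin so per-repetition counts always sum to the
probe count; the SD of a [0,1] variable cannot exceed 0.5) with a
"high-SD" summary at SD ≥ 0.10, and within-cell-type variably methylated
site counts (β range max − min ≥ 0.3 among the drawn lines — the range
criterion shares the DMR threshold for coherence; both are configurable).

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes, at
desk scale: 20,000 probes (not the full array's ~385,000 — all counts that
depend on probe number are reported per cohort and never compared to
genome-wide values) and one array sample per cell line, 27 ESC / 43 iPSC /
9 ECC / 25 somatic by default. β noise is Beta-distributed with mean m and
concentration k (shape mk, (1−m)k; k = 150 by default), so variance
shrinks near 0 and 1 as on real arrays; technical noise is
class-independent.

Probe archetypes (fractions of the cohort, chosen once as a realistic
structure):

| archetype | fraction | structure |
|---|---|---|
| pluripotency_hypo | 0.04 | β 0.10 in ESC/iPSC/ECC, 0.85 in somatic |
| somatic_hypo | 0.04 | the mirror image |
| ecc_marker | 0.01 | 0.85 in ECC only |
| esc_marker | 0.005 | 0.85 in ESC only — few crisp ESC-identity loci |
| esc_variable | 0.05 | mean 0.35 everywhere, ESC concentration 8 (broad ESC background variability) |
| ipsc_variable | 0.01 | each iPSC line gets its own mean ~ U(0.05, 0.95); other classes 0.10 |
| ipsc_method_marker | 0.03 | β 0.55 only in iPSC lines of one derivation method |
| neutral | rest | class-independent bimodal background levels |

Two structural points deserve explanation. First, the per-class share of
the joint high-weight sets is near zero-sum: any probe informative about
the ESC/iPSC boundary feeds *both* classes' sets (opposite signs), so an
iPSC-heavy count — the qualitative finding the mining should reproduce —
can only emerge from how each class model distributes its weight mass. A
class defined purely by the absence of markers keeps violating margins and
spreads large weights everywhere, dominating the sets. The generator
therefore gives the iPSC class its realistic heterogeneity (line-variable
sites plus derivation-method-linked residual signatures, individually weak
— group means stay below the DMR threshold — but numerous) and the ESC
class a small set of crisp identity loci, so the iPSC model spreads weight
over many CpGs while the ESC model concentrates. Second, ESC lines carry
more genome-wide variability than iPSC lines via the esc_variable
archetype alone rather than a globally inflated noise level, which matches
how such variability appears in arrays (specific variable loci, not
uniformly noisier measurements).

Filter spikes (120 MAF failures, 80 detection-p failures, drawn from the
neutral pool) are flagged in the emitted truth table, so tests can assert
that QC removes exactly the planted probes. The truth table records each
probe's archetype and population-level per-class target means (for
line-variable probes, the mean of the drawn line means; for method
markers, the method-frequency-weighted mixture), from which the planted
between-class probe count is derived.

What the generator does **not** emulate: probe genomic coordinates and
spatial correlation, Infinium type I/II chemistry differences, batch and
slide effects, imprinting, replicate samples per line, and realistic
chromosome-specific probe densities. Passing recovery tests therefore
demonstrates that the pipeline's logic is correct under its assumed
statistical structure, not that real ESC/iPSC cohorts are separable at
these effect sizes.

## Problem sizes used in the checks

The test suite and the acceptance script run the synthetic study at
20,000 probes × 104 lines with a reduced sweep (r ∈ {0.5, 1.0} × 100
epochs, checkpoints every 10) — the selection, mining and resampling
machinery is identical to the full protocol, only the grid is smaller —
and exercise the full default protocol (6 r-values × 300 epochs ×
4 series = 7,200 epochs, 720 records) on a reduced 200-probe, 32-line
cohort, where the bookkeeping is scale-invariant. Exact metric-formula
checks use the reference 104-sample confusion counts directly.

## Known limitations

* Model selection on test folds (see above) reproduces the protocol's
  optimism; treat pooled metrics as descriptive, not as generalization
  estimates.
* The learner is strictly linear in β; interactions and non-monotone
  effects are invisible except through their linear shadow.
* Checkpoint files are NumPy `.npz` containers (versioned, bit-exact round
  trip); they are runtime artifacts, not an interchange format.
* With default settings the synthetic cohort is comfortably separable;
  the pooled confusion is typically perfect, unlike the 94% accuracy
  regime of real cohorts. Raising noise (lower concentration) or shrinking
  archetype fractions moves the operating point.
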