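# Methods

This note documents the statistical model behind `scqpcr`, the parameter
choices that matter, what the synthetic generator does and does not
emulate, and the numerical conventions, in enough detail to audit or
extend the package.

## Expression values and preprocessing

Targeted single-cell qPCR reports one cycle threshold (Ct) per well; low
Ct means high abundance, and a well that never crosses the fluorescence
threshold reports nothing.  The package treats "no signal" as *expression
at or below the detection limit*, not as missing data, and encodes it as
Log2Ex = 0 through

    Log2Ex = max(0, lod_ct − Ct).

`lod_ct` (default 24 cycles, the common convention for BioMark-style
experiments) is an anchoring constant, not a measurement: changing it
shifts all detected values additively and leaves every downstream
statistic in the package (dip statistic, t-statistics, fold changes,
PCA structure) unchanged.  On-disk nondetect encodings — empty field,
`NA`, the sentinel 999 — all map to one internal marker, since BioMark
exports vary by software version.

Empty-well filtering follows the 18S control rule: a well with no 18S Ct
or an 18S Ct **above** 40 cycles is empty.  The cutoff is exclusive (a Ct
of exactly 40 is kept), the rule being a literal reading of the source
protocol.  The control assay is dropped after filtering; analysis uses
the 85 target genes only.

Three normalization modes are provided because "normalised to ACTB" is
genuinely ambiguous for this data type:

- `none` (default): raw Log2Ex.  The packaged subset-mean table reports
  ACTB means that differ between subsets (16.3/16.9/16.6) with a
  significant t-test, which is impossible after a strict per-cell ΔCt;
  summaries of that kind therefore cannot have used per-cell
  normalization, and the default follows suit.
- `per_cell_delta`: classic ΔCt — subtract each cell's reference value,
  re-clamp at 0.  Cells whose reference is undetected have no defined ΔCt
  and are excluded (logged).  A matrix whose reference column is
  identically zero is treated as already normalized, which makes the
  operation idempotent.
- `global_scale`: an additive per-batch shift aligning each batch's
  median reference value with the global median; within-cell differences
  are preserved exactly.  With a single batch it is the identity.

Subset means are arithmetic means over **all** cells of a subset, zeros
included.  This zero-inclusive convention is what produces fractional
near-zero means (a gene detected in a handful of cells averages to 0.1,
not to its expressing-cell mean), and "not expressed at subset level"
means a mean of exactly 0, i.e. no cell of the subset detected the gene.

## Hartigan's dip test

The dip of a sample is the smallest sup-norm distance between its
empirical CDF and any unimodal CDF (convex to the left of some mode,
concave to the right, an atom permitted only at the mode).  The
implementation is the classical iterative algorithm: on the sorted
sample, fit the greatest convex minorant and least concave majorant of
the ECDF over a working interval, locate the largest envelope gap,
record the larger of the two one-sided deviations, shrink the interval to
the gap's support, and repeat until no improvement is possible.  The
statistic obeys 1/(2n) ≤ D ≤ 1/4; for n ≤ 3 and for constant samples the
lower bound is returned directly.  Ties are handled through the ECDF's
jumps; nothing is jittered.

Correctness is anchored two ways: unit tests pin down closed-form cases
(D = 1/4 for a two-point sample, 1/6 at n = 3, 1/(2n) for point masses),
and an independent brute-force oracle recomputes the dip from its
definition by linear programming — one small LP per candidate mode
position, minimising the band half-width ε subject to monotonicity,
convex-then-concave shape constraints and the ECDF band — with the
envelope algorithm required to agree to 1e-9 over every multiset of size
≤ 8 on a fixed value grid.  An interior mode can always be slid to a
neighbouring data point by replacing that span of the CDF with its chord,
so the oracle's candidate modes are the data points plus the fully-convex
and fully-concave cases.

**Null calibration.**  p-values are Monte Carlo against Uniform(0,1):
B = 10 000 samples of the same n (default; B and the seed are
configurable), with the add-one correction p = (1 + #{D_b ≥ D})/(B + 1),
so p ∈ (0, 1] and p is non-increasing in D.  Null tables are cached per
(n, B, seed); at n = 90 a table costs about a second.  The uniform is the
classical least-favourable unimodal null, which makes the test
*conservative* for lighter-tailed data: measured at n = 90, dips of clean
Gaussian samples never reach the uniform null's 95th percentile (flag
rate 0/200 at α = 0.05).  This is a property of the dip test itself, not
of the implementation; it means flagged genes are trustworthy, while the
nominal α overstates the false-flag rate on unimodal Gaussian-like genes.
Power is excellent where it matters: 50/50 mixtures separated by 6σ at
n = 90 with 10% dropout are flagged in 100/100 seeded runs.

**Screening conventions.**  The screen runs per (gene, subset) stratum on
zero-inclusive values: detection-limited cells form a point mass at 0
that is part of the expression distribution (a gene off in half the cells
*is* bimodal).  An expressed-only variant sits behind a flag.  Flags use
strict p < α with no multiple-testing correction, matching the raw p <
0.05 convention of the source analysis; a Benjamini–Hochberg step would
be a one-liner on the output table but is deliberately not the default.
Counting multimodal genes in the *packaged, two-decimal* p-value table
uses ≤ 0.05 instead, because the printed table marks a printed 0.05 as
multimodal; both conventions are implemented side by side
(`modality.screen_modality` vs `fixtures.multimodal_counts`).

**Dropout diagnostic.**  If multimodality were an artefact of weak
transcripts dropping out, flagged genes would be the low-expression ones.
The diagnostic computes each screened gene's mean Log2Ex over expressing
cells only, splits genes into unimodal vs multimodal (flagged in at least
one stratum), and runs a two-sided Student t-test between the two groups
of means; a large p-value is the reassuring outcome.

## Subset contrasts

Pairwise subset comparisons are two-sided two-sample Student t-tests
(equal variance) per gene on zero-inclusive Log2Ex, Welch behind a flag.
Degenerate strata are defined explicitly: both groups constant and equal
gives t = 0, p = 1; both constant but different is a separation no t-test
can quantify and is reported as the smallest positive float with a
`degenerate` flag rather than silently propagating NaN.  log2 fold change
is the difference of group means (values are already log-scale).

Rank labels assign highest/medium/lowest per gene across the three subset
means; tied subsets share the higher label and the gene is flagged tied.
The presence filters are set operations on the mean table: never-expressed
(mean 0 everywhere), exclusively-unexpressed-in-a-subset (mean 0 there,
positive in both others), and the expressed-gene count; by construction
never-expressed and any exclusive set are disjoint and expressed + never
= panel size.

## Subgroup discovery

The source analysis picked minority subgroups by eye from a PCA plot;
the package replaces that with a deterministic, gated procedure whose
knobs are all in `SubgroupConfig`:

1. **Space.**  PCA is refit on the cells of one subset and the first 2
   components are used.  A joint all-cell PCA puts the between-subset
   axes on PC1/PC2; a within-subset perturbation of norm r projects onto
   that plane with expected squared norm ≈ (2/85)·r², which buries real
   subgroups.  Within a subset, a coherent minority shift owns the top of
   the remaining variance.  (The joint PCA is still what the overview
   figure shows, and `select_subgroup` accepts any `PcaModel`.)
2. **Partition.**  Deterministic 2-means: seed with the farthest pair of
   cells, run Lloyd updates to convergence.  Cells are sorted by id first,
   so the result is invariant to input order.
3. **Gates.**  The minority cluster is accepted only if its size is in
   [min_subgroup_size = 5, max_subgroup_fraction = 0.4 of the subset] and
   its separation score is ≥ 0.25.  The separation score is the
   partition's mean silhouette **minus** the mean silhouette of the same
   procedure applied to isotropic Gaussian clouds of matching size and
   dimension (internally seeded, cached).  The subtraction matters: a
   forced split of structureless data scores a raw silhouette of
   ≈ 0.33 ± 0.03 essentially regardless of n, so raw silhouettes cannot
   separate artefact from structure; the calibrated score sits at ≈ 0 for
   single-Gaussian data (accepted in 0/200 seeded runs) and at 0.3–0.5
   for genuine planted subgroups.
4. **DE rule.**  Accepted subgroups are contrasted against the rest of
   their subset gene by gene (Student t-test); a gene is reported iff
   p < 0.05 **and** |log2fc| ≥ 1, with direction = sign of the fold
   change.  Both thresholds are fixed study conventions, not tuned knobs.

Hierarchical clustering for heatmap display is complete-linkage on
Euclidean distances, computed on id-sorted rows/columns so leaf orders are
permutation-invariant.

## Synthetic data generator

The generator draws, per cell and gene on the Log2Ex scale: a Normal
(per-subset mean μ_s, sd σ, default 1) or a two-component Normal mixture
(bimodal genes, component means μ1 < μ2, weight π); adds the subgroup
shift Δ for planted members; clamps at 0; applies logistic dropout
P(drop | x) = 1/(1 + exp(slope·(x − midpoint))) with midpoint 3 Log2Ex
and slope 1.5 per Log2Ex unit; emits detected values as
Ct = lod_ct − x + Normal(0, 0.5²) and empty wells (rate 0.02) as cells
whose 18S control draws above 40.  Cell counts default to 94/92/90 per
subset, the scale of the profiled experiment, and panel means can be
seeded from the packaged mean table.  Ground truth (true Log2Ex, dropout
indicators, memberships, gene classes) is stored at the Log2Ex scale so
recovery metrics are LoD-independent.

The logistic-dropout mechanism is the simplest one that reproduces the
observed concentration of non-expression among low-mean genes, and the
generator's monotone dropout, mean recovery (configured μ_s recovered
within 0.1 at n = 2000/subset with dropout off, for genes whose mean is
well above the clamp — for a gene near 0 the clamped-Normal mean exceeds
μ by construction) and pipeline closure (true Log2Ex recovered with RMSE
≤ 2·ct_noise_sd on detected entries) are asserted by tests.

What it does **not** emulate: amplification-efficiency differences
between assays, PCR kinetics, melting-curve artefacts, doublet wells,
cross-chip batch effects beyond a scalar shift, or correlated gene
modules beyond the planted subgroup.  Passing recovery tests therefore
demonstrate that the algorithms do what they claim under the stated
generative model, not that real monocyte data satisfies that model.

## Benchmark scenarios and sizes

The recovery benchmark plants a subgroup of fraction 0.15 in the
classical subset with Δ = −2 on 20 genes whose classical mean is ≥ 6
Log2Ex: a shift planted on a gene at the detection limit is unobservable
by construction (values clamp at 0), so the perturbation goes on
expressed genes.  Across 20 seeded experiments at full study scale the
pipeline scores mean membership ARI ≈ 0.92–0.98 and DE precision/recall
≈ 0.88–1.00.  The dip calibration benchmarks use n = 90 (the smallest
subset), B = 10 000, 100 mixture replicates and 200 Gaussian genes; the
oracle-equivalence sweep covers all ~24 000 multisets of size ≤ 8 on a
9-point grid, deduplicated by affine equivalence to ~5 300 LP solves.
These sizes keep the full verification suite around two minutes on one
CPU while leaving the statistical assertions sharp.

## Known limitations

- The dip test's uniform-null conservativeness (above) is inherited by
  design; per-gene sensitivity on nearly-Gaussian heterogeneity is low.
- Subgroup discovery finds at most one subgroup per subset (a single
  2-partition); nested or multiple subgroups would require recursion.
- The t-tests ignore the zero-inflated structure of Log2Ex; with heavy
  dropout the Gaussian assumption is rough, which is one reason the DE
  rule also demands a full log2 unit of effect size.
- `global_scale` normalization assumes batch effects are additive scalar
  shifts shared by all genes of a cell.
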