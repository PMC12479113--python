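# Methods

`tfcoverage` audits the completeness of transcription-factor (TF) ChIP-seq
compendia. Its central object is the *coverage inventory*: for every pair of
a TF and a sample (a cell line, or a coarser cell-type class), the pair is
**measured** if at least one ChIP-seq experiment targets it, **unmeasured**
if the TF is expressed in the sample but no experiment exists, and
**not expressed** otherwise. Unmeasured pairs are the biologically relevant
experiments a compendium is still missing. Around this object the package
computes inequality metrics, two coverage statistics, an acquisition-order
simulation, and a prioritization filter, all validated on a synthetic world
with planted ground truth.

## Expression thresholding (one-step fit)

A TF is called expressed in a cell line by fitting a one-step function to
the TF's expression values across cell lines, sorted ascending: each
breakpoint k splits the vector into a low block (first k values) and a high
block, each fitted by its mean, and the k minimizing the residual sum of
squares defines the step. The threshold is the midpoint of the two block
means; a value strictly above it is "expressed".

Numerical choices, all configurable:

* **Scale.** `call_expression` fits on `log1p` of the values by default.
  nTPM-style expression is heavy-tailed; on the raw scale the least-squares
  criterion is dominated by variance *within* the expressed component and
  the breakpoint drifts into the upper tail. The transform is monotone, so
  calls are unchanged in meaning; the reported threshold is mapped back to
  the raw scale with `expm1`. `fit_step` itself is scale-agnostic.
* **Ties.** Equal-SSE breakpoints resolve to the smallest k — the most
  conservative expressed set.
* **Flat profiles.** A vector whose range is below
  `1e-9 x max(1, matrix range)` carries no step evidence; the TF is called
  not-expressed everywhere.
* **Boundary values.** Calls use strict `value > threshold`.
* **Missing values** are excluded from the fit, never imputed; rows with
  fewer than two observations are skipped and reported.

Class-level aggregation uses the existential rule: a (TF, class) pair is
expressed iff at least one member cell line is.

Only the binary (one-step) fit is implemented; the audit needs a binary
expressed/not-expressed call, so two-step variants and the significance
statistics of the original step-fitting literature are out of scope.

## Cell-line name matching

Names are matched across resources by Jaro–Winkler similarity (standard
definition: match window `floor(max(|a|,|b|)/2) - 1`, half-transposition
count, Winkler prefix boost with p = 0.1 up to 4 characters) computed on
normalized names (case-folded, separator runs removed), with a **digit
consistency** gate computed on the raw names: the multisets of digit
characters must agree, so "K-562" can match "K562" but never "K-563".
Assignment is greedy one-to-one in descending similarity order with
lexicographic tie-breaking — deterministic and fully auditable via the
candidate log. The default acceptance threshold is 0.9. Greedy matching
rather than optimal assignment is a deliberate choice: at the scale of
cell-line vocabularies the two agree except on pathological near-ties, and
the greedy order is trivial to audit.

## Inequality metrics

The Gini coefficient of per-entity experiment counts is
`G = sum_ij |x_i - x_j| / (2 n^2 mean(x))`, computed via the sorted-vector
identity and cross-checked in tests against the double-loop definition and
against twice the area between the diagonal and the Lorenz curve. Entities
with zero experiments are included by default (the Lorenz curve spans every
TF / cell type in the universe); `counterfactual_gini` recomputes G under
the hypothetical that every expressed pair had exactly one experiment,
isolating how much inequality is attributable to choice of targets rather
than to expression biology. Research-attention effects are summarized by
Spearman correlations (Pearson on average ranks, exact under ties):
publications vs experiment counts, and early-period vs late-period counts
per TF (the rich-get-richer signature).

## Coverage statistics

All genomic coordinates are 0-based half-open; published 1-based TSS and SNP
positions are converted on ingest (`[pos-1, pos)` for SNPs). Overlap is
>= 1 bp under half-open semantics; abutting intervals do not overlap.

* **Reg-TF cover ratio** (per cell line and year): the fraction of the cell
  line's expressed genes — the top 25% by expression, ranked descending
  with ties broken by ascending symbol and a ceiling cut — whose promoter
  window (TSS +/- 500 bp, strand ignored, clipped at position 0) overlaps
  at least one peak from that cell line's experiments deposited up to the
  target year (deposit year <= target, inclusive).
* **GWAS-SNP cover ratio** (per cell type or class, and year): the fraction
  of catalog SNPs (de-duplicated by rsID) overlapping at least one peak of
  the entity's experiments up to the target year. The denominator is always
  the full SNP table. The level (cell line vs class) is an explicit
  parameter; class is the default.

Annual series are computed with a single sweep that records, per query
interval, the earliest deposit year of any overlapping experiment — this
makes the series exactly cumulative (monotone nondecreasing) and invariant
to how peaks are split across files, properties the tests assert.

## Acquisition-order simulation

The experiment set and its peaks are held fixed; the multiset of deposit
dates is randomly permuted over experiment IDs (100 replicates by default).
Each order is scored by the area under its annual GWAS-SNP cover-ratio
trajectory, normalized by the year span — the trapezoidal time average,
which lies in [0, 1] and is comparable across year ranges (a plain
mean-of-years variant is available behind a flag). Because every order
eventually includes all experiments, the final-year ratio is identical
across orders; AUC differences isolate *how early* coverage was gained.
Cumulative unique-TF counts per year quantify early diversity.

Top- and bottom-AUC orders are compared to the real order by subsampling:
`ceil(f * N)` experiments retained uniformly without replacement (f = 0.9
and 0.5 by default, 50 subsamples per order — the subsample count is a
package default, stated here because the procedure it emulates leaves it
open), recomputing the AUC, and applying Welch's two-sided t-test with
Satterthwaite degrees of freedom. Each (order, fraction) pair draws from an
independent, provenance-keyed RNG stream, so the real order's baseline
distribution is reproducible regardless of which orders accompany it. If
both AUC samples are degenerate (zero variance), p is reported as 1 with a
flag.

## Prioritization

DEG counts from TF knockout/knockdown experiments proxy regulatory impact.
`compare_deg_groups` runs a two-sided Wilcoxon rank-sum test between marker
and non-marker TFs, or between measured and unmeasured pairs (joined to the
inventory on (tf, sample); join losses are counted). No multiple-testing
correction is applied — these are single planned comparisons. The Wilcoxon
implementation uses exact enumeration of rank assignments when the pooled
sample has <= 12 tie-free observations, otherwise a tie-corrected normal
approximation with continuity correction.

A **hidden gem** is a pair that is simultaneously (i) unmeasured, (ii) has
more than 1000 DEGs (strict inequality), and (iii) has a marker-annotated
TF. Multiple knockout experiments per pair aggregate by the maximum DEG
count (most permissive evidence of impact; mean aggregation is available).
The filter emits a full per-pair flag audit alongside the accepted set.

## Synthetic world

The generator emulates the statistical structure the audit assumes, with
planted ground truth, and writes exactly the file formats the readers
consume. Defaults (the package's study conditions): 60 TFs among 300 genes,
30 cell lines in 6 classes, 600 experiments over 2005–2023, a 1.7 Mb
two-chromosome toy genome, 50 peaks of 200 bp per experiment, 400 SNPs.

* **Metadata** follows preferential attachment:
  `P(entity) ∝ (count + 1)^attachment_strength`, drawn sequentially for TFs
  and cell types independently; strength 0 is uniform, the default 1.0
  gives Polya-urn skew (Gini ~ 0.5, the right order for real compendia),
  5 is winner-take-all. Dates are uniform over the year range.
* **Expression** is a two-component log-normal mixture: membership in the
  expressed component is Bernoulli(pi = 0.3), values are
  `exp(N(mu, sigma))` with mu_low = 0, mu_high = 4, sigma = 0.8 (5-sigma
  separation — a clean bimodal nTPM-like profile).
* **Peaks**: a `tss_enrichment` fraction (default 0.5) of each experiment's
  peaks is centred inside promoter windows of genes truly expressed in the
  experiment's cell type; the rest is uniform. In `tf_specific_peaks` mode
  each TF instead has a fixed repertoire of positions derived from the world
  seed and TF index only, and every experiment re-emits the whole
  repertoire — replicates add no coverage, so final coverage is a
  deterministic monotone function of the *set* of measured TFs. This is the
  mechanism that makes diversity effects testable exactly.
* **DEG counts** are log-normal (meanlog 6, sdlog 1) with meanlog shifted
  by +1.5 for marker TFs (markers drawn at rate 0.25). When gems are
  planted (default 2), expressed-but-unmeasured pairs are selected, their
  TFs forced into the marker set, their DEG counts pushed above the
  threshold — and every *other* qualifying pair is capped at exactly the
  threshold, so the planted set is provably the filter's unique answer.
  Capping is applied only when planting is requested, keeping
  null-calibration simulations (shift = 0) unbiased.
* **Publications** per TF are Poisson with rate noisily proportional to the
  TF's experiment count, giving the positive attention correlation.

Everything is deterministic given the seed; each artifact draws from its own
named substream, so any one table is byte-stable regardless of the others.

What the generator does **not** emulate: real genome sequence or chromatin
state, antibody failure/survivor bias, ontology ambiguity in the class map
(generated as a balanced partition), correlated SNP positions (LD), or the
actual value distributions of any public resource. Passing tests therefore
demonstrate correctness of the audit machinery under the stated statistical
assumptions, not agreement with any particular database snapshot — the
headline numbers of real compendia depend on those snapshots and are out of
scope here.

## Problem sizes and validation

The test suite validates each primitive against an independent oracle:
exhaustive SSE scan for the step fit (1000 random vectors, n <= 60),
double-loop mean-absolute-difference and Lorenz-area identities for Gini
(1000 vectors), per-base set intersection for interval overlap (200 x 200
random intervals), full rank-assignment enumeration for the exact Wilcoxon
path, a 20 000-draw permutation oracle for its normal path, the hand Welch
formula, and hand-evaluated Jaro–Winkler values. End-to-end tests run the
full pipeline on worlds with an essentially separated mixture (16 sigma) and
assert exact recovery of the planted unmeasured set and gems, plus
byte-identical reruns. Order-simulation contracts use 100 shuffled orders on
a 120-experiment diversity-sensitive world; calibration checks use 200 null
seeds. These sizes keep the whole suite under a minute while leaving each
property statistically unambiguous.

## Known limitations

* The inventory's pair universe is TFs present in the expression matrix
  crossed with samples present in the ontology map; measured pairs outside
  it are reported separately rather than forced into a status.
* Greedy name matching can mis-pair pathological near-duplicates that an
  optimal assignment would resolve.
* The exact Wilcoxon path requires tie-free data; counts with ties fall
  back to the normal approximation even for small samples.
* The simulation permutes dates over a fixed experiment set; it does not
  search for optimal orders, and subsampling treats experiments as
  exchangeable units (no batch structure).
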