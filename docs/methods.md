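# Methods

This note documents the statistical procedures `crgpipe` implements, the
design decisions taken where several reasonable choices existed, what the
synthetic-data generator does and does not emulate, and the package's
known limitations.

## Preprocessing

The pipeline ingests expression matrices that have already been summarized
to probe-set or gene level (RMA or platform-native summarization is
assumed to have happened upstream; it is not reimplemented).

- `log2_quantile_normalize` floors values ≤ 0 to a configurable epsilon
  (default 1.0; background-corrected intensities can be non-positive),
  takes log2, and forces every column onto the mean quantile profile.
  Normalization operates after the log transform. Ties within a column
  receive the mean of the quantile values their ranks span — the standard
  convention. A single-sample matrix is returned log-transformed with a
  warning, since quantile normalization is degenerate there.
- `aggregate_probes` collapses probes to genes by arithmetic mean on the
  matrix's current scale. The default pipeline order is
  normalize-then-aggregate, with the aggregation performed on whichever
  scale the matrix is in at that point; the CLI exposes the opposite order
  (`--order aggregate-then-normalize`). The mean-of-delog vs
  delog-of-mean gap (Jensen) is why FC/AD are always computed from
  linear-scale means, never from de-logged mean logs.

## FC and AD ranking

FC_i = X̄_i^A / X̄_i^B and AD_i = X̄_i^A − X̄_i^B, with group means taken
as arithmetic means of replicate columns on the linear scale and group A
the resistant/treated member, so "up" uniformly means higher in the
resistant or treated state. For genes with positive means the two
statistics always agree in sign (AD > 0 ⇔ FC > 1); they differ in which
genes they rank highly.

A descending sort of the signed statistic alone cannot yield a mixed
up/down top list, so ranking uses the symmetric change magnitude —
max(FC, 1/FC) for FC and |AD| for AD — with a stable tie-break by gene id
for determinism. Signed ranking is available via `rank_by="signed"`.
Genes with no direction call (FC = 1 or AD = 0 exactly) are excluded from
top-N selection. The default list size in the CLI is N = 3000,
appropriate for a ~20k-gene array; synthetic runs at 2000-5000 genes use
proportionally smaller N (300 by default in the pipeline config).

Variance-based statistics (moderated t, SAM) are deliberately absent: at
2-3 technical replicates per condition their variance estimates are too
unstable, which is the regime this design targets.

## Directional concordance and its binomial null

For two directional lists sharing k genes with s direction agreements, the
score is 100·s/k (reported to two decimals; full precision kept
internally) and significance is the exact one-sided upper binomial tail
P(X ≥ s), X ~ Binomial(k, p_e), p_e = 0.5 by default. The tail is summed
in log space (lgamma terms with a max-shift), so values of order 1e-14 at
k ≈ 200 are computed to better than six significant digits — verified in
the tests against exact rational arithmetic and against scipy's survival
function as independent oracles. The test is one-sided (agreement above
chance) by design; an empty overlap returns k = 0, p = 1, flagged, so
batch table generation never aborts.

## Rank-product differential expression

The pairwise (unpaired two-class) rank product: for every admissible
class-A x class-B sample pair, genes are ranked by the within-pair
difference, and rp is the geometric mean of the ranks across pairs (ties
get average ranks). When cohorts pool several datasets, pairs are by
default restricted to samples from the same `dataset_id`. This makes the
statistic immune to two kinds of batch structure, both covered by tests:
a per-sample constant shift changes every gene's difference in a pair
equally (ranks unchanged), and a per-dataset per-gene shift cancels inside
within-dataset pairs. Cross-dataset pairing is an explicit opt-in.

Significance is by permutation of the **class labels**, shuffled within
each dataset so that per-dataset class counts and batch structure are
preserved; each round recomputes the full rank product and contributes to
the one-sided tail counts, giving p = (1 + #{null rp ≤ observed rp}) /
(n_permutations + 1). Whole-sample permutation was chosen over permuting
gene values within pairs because the latter treats pairs sharing a sample
as independent evidence; measured on null cohorts, it inflates the
fraction of genes at p < 0.05 several-fold, whereas label permutation is
calibrated (~4-5% at nominal 5% in the packaged null-calibration test).

The per-gene `p` column is two-sided — the smaller of the two one-sided
tails doubled and capped at 1 — with `direction` taken from the smaller
side; the raw one-sided `p_up`/`p_down` are also emitted. FDR is
Benjamini-Hochberg within each direction; the Breitling pooled-null
"percentage of false positives" (`pfp`) is emitted as an alternative
error-rate column so either convention can be applied downstream.

Two resolution limits matter at small sample sizes and are inherent to a
valid permutation test: p ≥ 1/(n_permutations + 1), and the attainable
minimum is bounded by the number of distinct label assignments (a 3v3
single-dataset design has only C(6,3) = 20, so no gene can reach a
two-sided p below ~0.1 regardless of permutation count). Discovery and
confirmation cohorts should be sized with this in mind; the packaged
analyses use ≥ 4v4 per dataset.

## CRG derivation

Clinical DEG lists are oriented so "up" means higher in non-responders —
the resistant phenotype — matching the cell-line convention, which is what
makes cross-domain consistency scoring meaningful. Two operations derive
CRGs:

- `tiered_crg`: genes at FDR ≤ 0.2 in a discovery table that are
  confirmed at p ≤ 0.05 with the same direction in every confirmation
  table (thresholds configurable, inclusive).
- `intersect_regimens`: for regimens sharing at least one drug, members
  present with the same direction in every regimen's list are attributed
  to the shared drug(s). The justification — that under no (or limited)
  drug-drug antagonism the overlap of regimen CRGs is the CRG set of the
  shared drugs — is a mathematical argument about the union structure of
  combination effects; the code implements its conclusion as set logic
  and does not model interactions. Genes with conflicting directions are
  excluded and reported; genes measured in only a subset of lists are
  excluded (complete-case: a direction cannot be confirmed where
  unmeasured). The operation is commutative, associative, and
  monotonically shrinking in the number of regimens.

`id_clinical` is a thin FDR filter (default 0.1) over a post-chemotherapy
responder/non-responder DEG table.

## Pathway enrichment

Upper-tail hypergeometric over-representation, P(X ≥ x) including the
observed count, against GMT collections, BH-adjusted across sets. The
universe defaults to all genes measured on the platform and both query
and set members are intersected with it; enrichment results are
universe-sensitive and the universe used is recorded in the output. No
KEGG or other collection is bundled (licensing); tests use a small
synthetic GMT.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with bit-identical output for identical (config, seed).

Cell-line experiments: {parental, resistant} x {0, 6, 12, 24 h} x 3
replicates, expression 2^(baseline + effects + noise) with baseline
log2-N(7, 2), replicate noise sd 0.25 (log2), i.e. a log-additive
(multiplicative) effect model under which both FC and AD are meaningful.
Planted classes on a 5000-gene default matrix:

- **resistance** genes (60 shared across drugs with one direction, plus 60
  per drug): log2 effect 2.0 only in the treated-resistant arm, rising as
  min(t/12 h, 1) — saturated before the 24-hour point, so late ID lists
  capture them at full strength.
- a **high-expression/low-FC stratum** (20 of the shared resistance
  genes): baseline log2 ≈ 12, effect 0.35 (FC ≈ 1.27) — large AD, small
  FC, giving the expression-bias diagnostic known positives.
- **drug-response** genes (300): log2 effect 2.0 in every treated arm,
  transient (linear rise to 6 h, linear decay to zero at 30 h), plus a
  chronic-exposure imprint of 0.8x the effect in all resistant arms.
  The imprint models a resistant line maintained under drug and is the
  mechanism that makes BD lists direction-consistent with IP lists — the
  confounding phenomenon the pipeline exists to expose.
- **basal-difference** genes (150): log2 effect 1.0 in all resistant
  arms, directions drawn per drug — line differences irrelevant to
  resistance; the null remainder carries noise only.

Clinical cohorts: responders and non-responders split over several
datasets (pre-chemotherapy default (10,13), (9,12), (4,4); one
post-chemotherapy dataset (13,17)); non-responders carry the resistance
effects of the regimen's drugs attenuated by 0.6 and scaled by a
per-patient heterogeneity factor ~ N(1, 0.35) truncated at 0;
post-chemotherapy samples additionally carry 0.8x the drug-response
effects in every patient (these cancel between response groups, so
post-chemotherapy DEGs reflect resistance genes, as ID_clinical should);
each dataset receives an independent per-gene batch shift (sd 0.5). The
attenuation and heterogeneity defaults were chosen once so that pipeline
consistency scores fall in the 70-100% range a realistic analysis would
show; they are a modelling choice, not an empirical estimate.

What the generator does **not** emulate: probe-level structure and
cross-hybridization, gene-gene correlation (effects are independent
across genes given class), tumor cellular composition (patient
heterogeneity is a single scalar per patient), dose-response, and
survival outcomes. Tests passing on this generator therefore demonstrate
correctness of the pipeline's logic and calibration under its assumed
structure, not performance on real tumor transcriptomes.

## Problem sizes used in the packaged analyses

Exact-tail checks run to k ≤ 200 (binomial) and universe ≤ 500
(hypergeometric) against rational brute-force oracles. Null calibration
uses 500 genes, one 4v4 cohort, 1000 permutations. Recovery and bias
checks run on the full 5000-gene default experiment (no permutations
needed). The end-to-end clinical recovery uses 2000 genes, pre-chemo
datasets (8,8), (6,6), (4,4) and 300 permutations — sizes at which the
permutation resolution comfortably supports the 0.2/0.05 thresholds.

## Numerical choices and degenerate inputs

Log-space summation for binomial tails; average ranks for ties in
pairwise differences; stable (magnitude desc, gene id asc) ordering in
top-N; thresholds inclusive; k = 0 overlaps and single-sample
normalization degrade to flagged results rather than errors; empty
universes, missing sample groups, and regimens without shared drugs are
errors (the pipeline driver converts missing-group errors into logged
step skips). Seeds are mandatory for every stochastic operation and all
outputs are deterministic given (config, seed).

## Known limitations

- FC/AD ranking has no error model; list sizes (N) are analysis choices,
  and conclusions can shift with N — the package exposes N everywhere
  rather than hiding a default.
- The rank-product permutation test is exact only up to Monte-Carlo error
  and label-assignment granularity; very small cohorts cannot reach
  stringent thresholds (see above).
- The no-antagonism assumption behind regimen intersection is not
  testable from expression data alone; direction conflicts between
  regimens are reported as a partial diagnostic.
- The one-sided binomial null treats genes as independent; overlapping
  gene lists derived from correlated comparisons can inflate apparent
  significance.
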