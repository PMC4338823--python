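# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
fixtures do and do not establish.

## Coordinates, strands and windows

All internal coordinates are 0-based. BED input is 0-based half-open; VCF
positions are 1-based and converted on read; only single-base SNV records
are kept from VCFs. Sites on the minus strand are stored on forward-strand
coordinates; orientation is applied only at window extraction, where the
forward slice is reverse-complemented so that the window's central base is
adenosine in window orientation (the reference base must be A on '+' and T
on '−'). Windows containing N or any other ambiguity code are excluded from
training and rejected at prediction with a dedicated error: the positional
probabilities are defined over the four-letter alphabet only, and silently
redistributing ambiguous mass would bias the profiles. Duplicate site
records collapse with a warning rather than an error, because public
editing catalogues routinely contain redundant rows.

## Edited regions and the δ breakpoint

δ is the weighted average distance between consecutive catalogued sites:
all consecutive-site gaps are pooled within each (chromosome, strand) group
and averaged, which is identical to weighting per-group mean gaps by their
gap counts. Groups with a single site contribute nothing; if no group has
two sites, δ is undefined and an error is raised. Region construction is a
greedy left-to-right pass per group: the current region extends while the
next site lies within δ (inclusive) and a new region starts otherwise, so
the output is a partition of the input and the within-region gap bound is
exact. Segmentation is strand-aware by default — published ER counts are
reported separately per strand, which implies per-strand construction — and
a flag allows strand-agnostic grouping for sensitivity analysis. The ER
span runs from first to last member site with no flank padding. A region is
*repetitive* when its span [start, end+1) overlaps any repeat interval by
at least one base (interval trees; invariant to interval order and
merging). The training filter keeps non-repetitive ERs of 2,000–6,000 nt
holding at least 10 sites — the selection used to assemble motif-discovery
regions.

## Positional profiles and the logistic model

P(j, i) and P′(j, i) are estimated with a Laplace pseudocount α (default 1,
configurable including 0): probs = (count + α) / (n + 4α). Smoothing is our
addition; it keeps 0/1 cells from injecting unbounded logits downstream. A
window featurizes to the 2(2r+1)-vector of its own-position probabilities
under each matrix, central position included — the model's sums run over
every window position, and the near-constant central-A feature is left in,
its collinearity with the intercept absorbed by the ridge penalty rather
than by dropping the column.

The linear predictor is β₀ + Σ βᵢP(s[i],i) − Σ β′ᵢP′(s[i],i). The minus
sign is treated as a parameterization: the P′ block is negated before an
unconstrained fit, leaving β′ᵢ free in sign (nothing requires them
non-negative). Fitting minimizes the negative binomial log-likelihood plus
(λ/2)‖(β, β′)‖² — intercept unpenalized, λ = 1e−3 by default — by damped
Newton from a zero start: analytic gradient and Hessian, backtracking line
search with a float-resolution slack so quadratic convergence can finish,
stopping at gradient norm ≤ 1e−8 or 500 iterations. The fit is fully
deterministic; identical inputs give bit-identical coefficients. On
separable data with λ = 0 the iteration either converges to a numerically
saturated solution or stops at the cap with a warning — the default ridge
exists precisely to avoid that regime. Approximate standard errors come
from the inverse penalized Hessian at the solution and are reported in
`summary()`; they are curvature-based diagnostics, not exact sampling
variances under penalization. The decision rule is strict: a window is
called edited only when the predicted probability exceeds the threshold
(default 0.5), so a probability of exactly 0.5 is un-edited. The 4-nt
variant is the same code path at radius 4.

The multiplicative baseline mirrors the structure of neighbor-multiplier
editing predictors: a percent base rate times one positive coefficient per
configured flank offset (offset 0 excluded), thresholded at 9.6 % by
default. Published coefficient tables are not bundled; tables load from a
TSV of (offset, nucleotide, multiplier).

## Evaluation protocol

Cross-validation uses stratified folds from a seeded shuffle (default seed
42) dealt round-robin with a cursor carried across classes, so k = n
degenerates to leave-one-out. Within every fold, both probability matrices
and the coefficients are estimated from the training folds only; building
matrices from all data leaks label information into held-out scores, and a
`leak_all_data` flag reproduces that naive variant solely for comparison.
"Mean error" is the mean over folds of the misclassification rate at the
0.5 threshold — the only reading the protocol supports. ROC curves are
computed from pooled out-of-fold scores with tied scores grouped into
single threshold steps; per-fold AUCs are reported alongside and their mean
is the "average AUC". Confusion matrices are row-normalized percentages
(actual class in rows). The comparison protocol scores the logistic model
normally and the baseline either from a single table or, when the acting
deaminase is unknown, as the maximum over tables for truly edited windows
and the minimum for random windows. Note that the max/min selection is
itself favourable to the baseline: with k random tables it manufactures
separation even when no table is informative, which is why the acceptance
script reports both the single-table and the max/min baseline AUCs.

## Motif filtering and the permutation test

Motif consensus strings are IUPAC; matching is exact symbol-set containment
with no mismatch tolerance (none is defined for the screen), counted over
all overlapping offsets and, by default, on both strands (a palindromic
consensus is not double-counted). Lowercase and N bases never match, which
makes soft-masked background FASTA behave as repeat-masked. The E-value
filter is strictly < 0.05; the ultraconserved filter drops any motif with
at least one match, either strand, inside any ultraconserved sequence. The
permutation statistic is the fraction of sequences containing at least one
match — presence/absence is robust to length variation across UTR pools; a
total-count mode is available behind a flag. The null re-computes the
statistic on n = 100 seeded draws of 1,000 sequences, each drawn without
replacement from the background pool, and the p-value uses the add-one
estimator (1 + #{null ≥ observed}) / (n + 1), never exactly zero;
significance is p < 0.01. Per-sequence match results are computed once per
pool, so the 100 draws cost a single scan.

## Synthetic fixtures

`generate_window_sets` samples each window position independently from
per-class positional distributions — deliberately the same independence
structure the model assumes, so ground truth stays analytic. Three stock
specifications are used throughout: `separated` (disjoint-support flanks,
all-T vs all-C — perfectly separable), `null` (identical uniform profiles —
no signal), and `adar_like` (uniform background vs a mild bias echoing
documented deaminase preferences: G depleted immediately 5′ of the edited
adenosine with a U ≈ A > G > C ordering, G enriched immediately 3′, and a
gentle U/A lean elsewhere). Default sizes are 1,000 windows per class
(2,000 total) at radius 10 — large enough for stable AUCs at desk scale.

`generate_genome_with_sites` plants clustered sites on both strands of a
random genome: within-cluster gaps are geometric with the requested mean,
truncated at 3× the mean so that any δ between that cap and the
between-cluster separation (default 50× the mean) recovers the planted
clusters exactly; the reference base under each site is forced to match its
strand. Repeats are interval annotations only (no Alu-like sequence
content — sufficient for overlap logic, nothing more), and a configurable
fraction of sites is copied into the SNP track.

What passing these tests shows: the segmentation, estimation, fitting,
scoring and testing machinery is correct against independent oracles and
recovers planted signal at the expected operating points. What it does not
show: performance on real editing catalogues, where flanking positions are
correlated, class balance is artificial, and the un-edited class is only
putatively un-edited. Genome-scale figures (δ ≈ 6,057 nt, tens of
thousands of ERs, AUC ≈ 0.75 vs ≈ 0.51 for the multiplicative baseline)
require the RADAR catalogue, dbSNP, hg19 repeat annotations and published
baseline coefficient tables, none of which are bundled.

## Numerical choices and limitations

- Pseudocount α = 1; ridge λ = 1e−3; Newton tolerance 1e−8, cap 500.
- ROC ties are grouped; AUC is the trapezoid area (equals Mann–Whitney
  concordance with half credit for ties — asserted exactly in tests).
- Problem sizes in tests and the acceptance script (2,000-window CV sets,
  3,000-sequence permutation pools, 200 calibration repetitions, 50
  fit-oracle instances) were chosen as the smallest sizes at which the
  statistical checks are stable.
- The model is strictly positional-independent; no dinucleotide or
  higher-order context features, and no per-deaminase model selection.
- Ultraconserved "containment" is exact IUPAC matching, not alignment.
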