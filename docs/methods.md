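# Methods

`apa_regulon` implements an integrative analysis for inferring which
RNA-binding proteins (RBPs) regulate alternative polyadenylation (APA) at
individual poly(A) sites (PAS), combining three data modalities: a tumor
cohort with per-PAS read counts and RBP expression, a panel of single-RBP
depletion experiments, and CLIP binding evidence. This note documents the
models, the defaults and why they are set where they are, what the
synthetic-data generator does and does not emulate, and the numerical
choices.

## Usage quantification and the PAS score

Within a terminal exon carrying k tandem PAS, the usage of site *i* in a
sample is PAU_i = M_i / N, the count supporting the site over the exon
total. PAU is undefined (NaN) for zero-coverage exons rather than imputed.

Raw PAU is noisy exactly where it is least informative (shallow exons), so
inference runs on a signed score contrasting two strict binomial tails under
an even split:

    score(M, N) = -log10 P(m > M | N, 1/2) + log10 P(m < M | N, 1/2)

A site carrying most of the exon's reads drives the score toward +inf, a
minor site toward -inf, and M = N/2 gives exactly 0. At low N both tails are
moderate and the score stays near zero — the score encodes *evidence* of
major/minor usage, not the point estimate. Numerics: the point mass at M
belongs to neither tail (strict inequalities); tails are clamped to
[tiny, 1] (smallest positive normal double) so scores stay finite for
downstream PCA and rank tests; the lower tail is evaluated through the
exact symmetry P(m < M) = P(m > N - M), which makes the antisymmetry
score(N-M, N) = -score(M, N) hold bit-exactly rather than to rounding.

**Size factors** follow the median-of-ratios recipe on the PAS count
matrix: each row is divided by its row median, and the factor of sample k is
the median of column k. Rows without a positive median are excluded.
(Note this is the row-*median* variant, not the geometric-mean reference;
the two agree in spirit but not numerically.)

**Library-size control.** Deeper libraries produce larger |score| at the
same underlying usage. Per PAS, a median (tau = 0.5) quantile regression of
|score| on library size (with intercept) is fitted across samples; positive
residuals become the normalized magnitudes, negative residuals are zeroed,
and the original sign is restored. A PAS needs at least 8 defined scores for
the fit (below that the quantile fit is unstable and the PAS is left
undefined). A constant-|score| PAS degenerates to a flat fit and normalizes
to all zeros, which is the desired "no evidence" behavior. Library size
defaults to the column sum of the PAS count matrix, the available depth
proxy when only the PAS quantification is at hand.

## Cohort differential APA (dAPA)

Cohort comparisons involve dozens of heterogeneous samples per condition,
where moment-based exon-usage models are fragile; the test is therefore a
per-proximal-PAS no-intercept median quantile regression

    r_PAS = b0 * r_other + b1 * D_cond * r_other

with r_PAS, r_other the size-factor-normalized counts of the site and of the
exon's other sites, and D_cond the condition dummy. Significance takes the
*maximum* of the two coefficient t-test p-values — requiring both the
expected coupling to host expression (b0) and a condition effect (b1) —
followed by Benjamini-Hochberg over all tested PAS. The fitted betas give
the per-condition median usage directly:

    PAU_0 = b0/(1+b0),  PAU_1 = (b0+b1)/(1+b0+b1),  dPAU = PAU_1 - PAU_0

Fits with negative implied usage are flagged invalid but reported. tau is
0.5 (the median; no reason to privilege another quantile), and both t-tests
are two-sided. On numerically exact fits the bandwidth-based standard error
can degenerate; a zero standard error is mapped to p = 0.

**Direction.** Shortening vs lengthening of the terminal exon is called
from the PAU-weighted mean PAS rank in transcript orientation (rank weights,
not genomic coordinates, so the call is strand-invariant): the condition
with the smaller median weighted rank uses more 5' sites and has shorter
exons. dPAU signs of proximal sites are then adjusted so positive proximal
dPAU always means shortening. Single-PAS exons get direction "none".

## Perturbation-panel dAPA

Depletion experiments have 2-3 replicates per arm. Two testers are
provided:

* **pooled** — arm-pooled 2x2 table (site vs other-site counts) with a
  continuity-corrected chi-square, Fisher's exact test when any expected
  cell is below 5. Simple, but blind to replicate-to-replicate variability:
  with realistic biological noise it is strongly anti-conservative (in
  simulation it called ~30% of null sites significant), because pooling
  treats hundreds of reads as independent Bernoulli trials.
* **logit** (used by the pipeline) — per-replicate empirical logits
  log((M+0.5)/(O+0.5)) compared between arms with a moderated t-test whose
  per-PAS variance is shrunk toward the experiment-wide median (prior df
  20). Sharing dispersion information across features is the same idea
  exon-usage models rely on to be usable at n = 2-3; it restores both
  calibration and power. The tester interface is pluggable so a full
  negative-binomial exon-usage model can be dropped in.

dPAU is always the raw pooled PAU(depleted) - PAU(control); q-values are BH
within the experiment.

**Per-RBP effect summaries** count significant proximal PAS (q < 0.05),
collapse them to terminal exons (one vote per exon by its dominant
direction; |dPAU| sums break ties, exact ties abstain), and test the
shortening/lengthening skew with a two-sided binomial test against 0.5,
BH-flagged across RBPs at FDR < 10%. Cross-cell-line concordance is the
cosine similarity of the signed dPAU vectors over sites tested in both
panels (>= 3 shared sites; undefined for all-zero vectors).

**Differential expression** (for the CO axis and the depletion gate) uses a
deliberately transparent caller: size-factor-normalized log2 counts
(pseudocount 0.5), a moderated two-sample t-test (per-gene variance shrunk
toward the across-gene median, prior df 4), and an up/down call requiring
both q < 0.05 and |log2FC| > 1. With 2-3 replicates an unmoderated t-test
misses even 4-fold knockdowns regularly; moderation is the standard remedy.
Experiments whose target RBP is not called "down" fail the depletion sanity
gate and are excluded from evidence. The caller is pluggable.

## Evidence classification

For every (proximal PAS, RBP) pair quantified in the cohort:

* **CLIP** — the RBP has a binding footprint on the site's host terminal
  exon.
* **PERT** — the site responds significantly (q < 0.05) in a gate-passing
  depletion experiment targeting the RBP; the direction is the dPAU sign of
  the strongest response. Panels from different cell lines are classified
  separately.
* **CO** — across all panel experiments, a chi-square test of independence
  between the pair's {up, down, nonsig} dAPA statuses and the RBP's DE
  statuses (3x3 table, both margins trichotomized; empty levels collapsed,
  tables below 2x2 untested, no continuity correction), BH-flagged at
  FDR < 0.05, requiring >= 20 experiments.
* **significant** — two-sided Mann-Whitney test of normalized PAS scores
  between low- and high-RBP-expression cohorts (median split by default;
  tertile split available), BH over all pairs, q < 0.05. Direction is the
  sign of (median low - median high), deliberately oriented so that
  depletion — the extreme of low expression — should match it.
* **consistent** — PERT holds and the depletion dPAU sign equals the cohort
  direction.

The category label is the exact set of experimental evidence flags
(CLIP/PERT/CO joined with "+"), or OTHER when none holds. The inferred
regulations are the PERT & significant & consistent pairs.

## Survival association

Feature sets are matched in size across modalities: genes ranked by median
normalized expression, proximal-PAS score rows ranked by fewest
zero/undefined entries, or a half-and-half combination (e.g. 493 + 494 for
987 features); ties break lexicographically so selection is deterministic.
PCA is centered but unscaled by default (scores and log-expression are
already on comparable scales; scaling is a flag), with a deterministic sign
convention (largest-|loading| positive). Confounding with tumor purity is
Kendall tau-b with a seeded percentile-bootstrap 95% CI (1000 resamples).

The **log-rank threshold scan** rank-transforms a candidate axis
(ascending, ties broken by sample id) and tests every two-group split at
rank thresholds t in [min_group, n - min_group] (min_group = 30, giving
thresholds 30..92 for n = 122) with the two-sample log-rank test; profiles
of p across thresholds distinguish robustly prognostic axes from
single-threshold flukes. Thresholds leaving a group without events record
p = 1 with a flag. Being rank-based, the scan is invariant to monotone
transforms. The **four-group stratification** crosses a purity threshold
with an APA-component threshold (each chosen by its scan argmin when not
supplied) and compares the groups with the K-sample log-rank test; empty
cells are tolerated as long as two groups remain (identical axes collapse
to the two-sample test), fewer than two is an error.

## Replicate and PAS quality control

Control/bioreplicate pairs are embedded (PCA, 2 components by default; any
precomputed embedding such as UMAP coordinates can be supplied instead) and
pairs whose Euclidean distance exceeds the boxplot upper fence
q75 + 1.5*IQR of all pair distances are removed — strictly "higher than",
so a pair at the fence survives; at least 4 pairs are required for the
fence to mean anything. PAS whose normalized scores fluctuate within
control groups (default statistic: IQR; default cutoff: the 90th percentile
of per-PAS maxima across groups; >= 4 control samples per group) are
dropped before differential testing, with a per-PAS report of the
triggering rule.

## Synthetic data generator

The generator plants known structure so every stage can be validated
without external data. Exon totals are negative binomial (dispersion 0.05)
with per-exon lognormal expression factors and per-sample lognormal
library-size factors (sigma 0.3); within-exon usage is logistic-normal
(per-site logit noise sd 0.25), chosen over a Dirichlet so that regulator
effects are *additive on the logit scale* — the natural scale of the
shift-detection tests. A planted regulation adds
-d * effect * z_RBP to the proximal logit in the cohort (z_RBP the RBP's
expression z-score) and +d * effect in depleted arms of that RBP's
experiment, so cohort and depletion directions agree by construction
(d = +1 means proximal usage rises on depletion). Condition effects on
usage flow through RBP expression offsets (sd 0.2) plus an optional direct
condition shift on a disjoint 10% of proximal sites. Survival is
exponential with log-linear hazard in purity and a latent APA factor that
also loads on a subset of exon logits (proportional hazards is all the
rank-based scan requires). One global seed drives named sub-streams, so
outputs are bit-identical across runs.

Defaults (set once to emulate the target study's shape): 150 exons with 2-3
PAS, 2 conditions x 60 samples, 20 RBPs, 30 planted regulations, logit
effect 1.5, knockdown factor 0.25, 3 replicates per arm, CLIP false
positive/negative rates 0.05/0.2.

What it does **not** emulate: read-level artifacts (fragment-length,
positional and GC bias), annotation errors, correlated RBP co-regulation
networks, batch effects, non-proportional hazards, and the coverage-based
PAS quantification step itself (the package consumes a PAS count matrix).
Passing tests therefore demonstrate correctness of the inference chain
under the stated generative assumptions, not robustness to everything real
data can do.

A note on evaluation: usage is compositional, so a shift planted on one
site of a multi-PAS exon genuinely moves its siblings' usage. Planted-shift
sensitivity/FDR are therefore scored at the terminal-exon level (or with
two-PAS exons, where site and exon coincide).

## Problem sizes in tests and the acceptance script

Simulation-based checks use cohorts of 60-120 samples, 150-200 proximal
sites, 10-50 replicate datasets and 5-20 seeds — sizes at which the checked
properties (calibration, power, recovery) are statistically meaningful while
the whole suite stays desk-scale. `scripts/acceptance.py` re-runs the same
computations from scratch at comparable sizes.

## Known limitations

* The DE caller and perturbation tester are transparent stand-ins, not
  negative-binomial GLMs; both are pluggable.
* The CO test treats experiments as exchangeable draws; shared control
  samples across experiments (common in real panels) violate independence
  and would inflate the chi-square.
* The cohort association is marginal per pair: co-expressed RBPs produce
  correlated evidence that the classification does not deconvolve.
* The quantile-regression dAPA model tests medians; it will miss effects
  confined to a tail of the cohort.
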