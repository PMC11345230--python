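# apa-regulon

Inference of RNA-binding-protein (RBP) regulators of alternative
polyadenylation (APA) from tumor cohorts and RBP-depletion panels.

## The problem

Most human genes carry several tandem poly(A) sites (PAS) in their terminal
exons; shifting usage toward the coding-region-proximal site (pPAS) shortens
the 3'UTR, a hallmark of many tumors. Which RBPs drive these shifts in a
given cancer is largely unknown. This package implements the inference
chain for that question, aimed at computational biologists working with
PAS-level count matrices:

1. **Usage scoring** — per-PAS usage (PAU = M/N within the exon) and a
   signed binomial score
   `score(M, N) = -log10 P(m > M | N, ½) + log10 P(m < M | N, ½)`
   that encodes evidence of major/minor isoform usage while damping
   low-coverage noise, followed by median-of-ratios size factors and a
   per-PAS quantile-regression normalization that removes the library-size
   trend from |score|.
2. **Differential APA** — cohort level: a no-intercept median quantile
   regression `r_PAS = β₀·r_other + β₁·D_cond·r_other` per proximal PAS,
   with max-of-p over the two coefficients, BH correction, and
   per-condition usage recovered from the fit
   (`PAU₀ = β₀/(1+β₀)`, `PAU₁ = (β₀+β₁)/(1+β₀+β₁)`); perturbation level: a
   replicate-aware test per depletion experiment with exon-level
   shortening/lengthening calls.
3. **Evidence classification** — every (pPAS, RBP) pair is labelled by
   CLIP binding, depletion response (PERT), panel-wide contingency (CO),
   cohort significance (Mann-Whitney on scores between high/low-RBP
   cohorts) and direction consistency; pairs that are PERT, significant and
   consistent are the inferred regulations.
4. **Survival association** — PCA feature sets from expression and/or APA
   scores, Kendall-tau confounding with tumor purity (bootstrap CI), a
   rank-threshold log-rank scan, and a purity × APA-component four-group
   stratification.

A fully seeded synthetic-data module generates cohorts, depletion panels,
CLIP tables and survival with planted ground truth, so the whole chain is
testable end to end.

## Worked example

`examples/04_regulator_evidence.py` simulates the default study — a
120-sample two-condition cohort with 30 planted regulations among 20 RBPs,
a 20-experiment depletion panel, and CLIP evidence at 5% false-positive /
20% false-negative rates — and runs the full inference:

```
pairs per evidence category (significant: cohort FDR < 5%; consistent:
depletion response matches the low-RBP cohort direction):
 category  n_pairs  n_significant  n_consistent
     CLIP      255             14             0
CLIP+PERT       26             24            25
    OTHER     4291              7             0
     PERT        8              5             7

inferred regulations (PERT & significant & consistent): 29
planted regulations: 30
precision 0.93, recall 0.90
```

Reading this: of ~4,500 candidate (pPAS, RBP) pairs, experimental evidence
concentrates the cohort-significant ones (24/26 of CLIP+PERT pairs vs
7/4,291 of OTHER), and the pairs passing all three filters recover the
planted regulations with high precision — the qualitative behavior the
method is designed for. The other example scripts walk through scoring
(`01`), cohort dAPA (`02`), the depletion panel (`03`) and the survival
scan (`05`).

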