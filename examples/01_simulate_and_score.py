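"""Simulate a small tumor cohort and compute PAS usage scores.

Builds a two-condition cohort with planted RBP regulations, then runs the
quantification stack: PAU (per-exon usage fractions), the signed binomial
PAS score, median-of-ratios size factors, and library-size-controlled
normalized scores.
"""

import numpy as np

from apa_regulon import SimulationConfig, simulate_cohort
from apa_regulon.pipeline import score_cohort

cfg = SimulationConfig(n_exons=60, n_samples_per_condition=30, n_rbps=8,
                       n_true_regulations=10, seed=1)
counts, rbp_expr, clinical, truth = simulate_cohort(cfg)
pau, norm, sf = score_cohort(counts)

print(f"cohort: {len(counts.pas_ids)} PAS in "
      f"{len({a.exon_id for a in counts.annotations})} terminal exons, "
      f"{len(counts.samples)} samples")
print(f"size factors: min {sf.min():.3f}, median {np.median(sf):.3f}, "
      f"max {sf.max():.3f}")

pas = truth.regulations.iloc[0]["pas_id"]
print(f"\nexample proximal PAS {pas} (regulated by "
      f"{truth.regulations.iloc[0]['rbp_id']}):")
print(f"  PAU across samples:  mean {pau.loc[pas].mean():.3f}")
print(f"  raw score:           mean {norm.score.loc[pas].mean():+.2f} "
      "(signed log-p contrast: positive = major isoform)")
print(f"  normalized score:    mean {norm.normalized_score.loc[pas].mean():+.2f} "
      "(library-size trend removed, zeros where usage is unremarkable)")
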