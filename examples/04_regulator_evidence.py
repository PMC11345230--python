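"""Full regulator inference: combine cohort, depletion-panel and CLIP evidence.

Every (proximal PAS, RBP) pair is classified by which evidence supports it —
CLIP binding on the host exon, a significant depletion response (PERT), and
panel-wide contingency between the pair's dAPA and DE statuses (CO) — next
to its cohort-level significance and direction. Pairs that are PERT,
cohort-significant and direction-consistent are the inferred regulations,
compared here against the planted ground truth.
"""

from apa_regulon import (
    SimulationConfig,
    simulate_clip,
    simulate_cohort,
    simulate_perturbation_panel,
)
from apa_regulon.pipeline import infer_regulators, run_perturbation_panel, score_cohort
from apa_regulon.rbp_assoc import category_summary

cfg = SimulationConfig(seed=4)
counts, rbp_expr, clinical, truth = simulate_cohort(cfg)
_, norm, _ = score_cohort(counts)
pc, pe, design = simulate_perturbation_panel(cfg, truth)
panel = run_perturbation_panel(pc, pe, design)
clip = simulate_clip(truth)

records = infer_regulators(counts, norm.normalized_score, rbp_expr, panel, clip)
print("pairs per evidence category (significant: cohort FDR < 5%; "
      "consistent: depletion response matches the low-RBP cohort direction):")
print(category_summary(records).to_string(index=False))

final = records[records["pert"] & records["significant"] & records["consistent"]]
true_pairs = set(zip(truth.regulations["pas_id"], truth.regulations["rbp_id"]))
got = set(zip(final["pas_id"], final["rbp_id"]))
tp = len(got & true_pairs)
print(f"\ninferred regulations (PERT & significant & consistent): {len(got)}")
print(f"planted regulations: {len(true_pairs)}")
print(f"precision {tp / max(len(got), 1):.2f}, recall {tp / len(true_pairs):.2f}")
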