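"""End-to-end orchestration: from count matrices to classified regulator pairs.

Ties the stage modules together the way the full analysis runs them:

1. score the cohort (PAU, binomial scores, size factors, library-size
   normalization);
2. run every depletion experiment of the panel (replicate-aware dAPA test,
   differential expression with the depletion sanity gate);
3. associate every (proximal PAS, RBP) pair across the cohort;
4. assemble CLIP / PERT / CO evidence into classified association records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import dapa, pas_quant, rbp_assoc
from .io_formats import PasCountMatrix

logger = logging.getLogger(__name__)

__all__ = ["PanelResult", "run_perturbation_panel", "score_cohort", "infer_regulators"]


@dataclass
class PanelResult:
    """Per-experiment dAPA and DE tables plus depletion-gate outcomes."""

    pert_tables: dict = field(default_factory=dict)
    de_tables: dict = field(default_factory=dict)
    gate_passed: dict = field(default_factory=dict)
    design: pd.DataFrame = None

    @property
    def retained_experiments(self) -> list[str]:
        return [e for e, ok in self.gate_passed.items() if ok]


def score_cohort(matrix: PasCountMatrix):
    """PAU, normalized PAS scores and size factors for one cohort.

    Returns (pau, score_matrix_with_normalization, size_factors).
    """
    pau = pas_quant.pau_table(matrix)
    scores = pas_quant.score_matrix(matrix)
    sf = pas_quant.size_factors(matrix.counts)
    norm = pas_quant.normalize_scores(scores, matrix.library_size)
    return pau, norm, sf


def run_perturbation_panel(
    matrix: PasCountMatrix,
    expression: pd.DataFrame,
    design: pd.DataFrame,
    dapa_method: str = "logit",
    enforce_gate: bool = True,
) -> PanelResult:
    """Run dAPA and DE testing for every experiment of a depletion panel.

    Experiments whose target RBP is not called significantly down (the
    depletion sanity gate) are excluded from downstream evidence when
    ``enforce_gate`` is set; their tables are still returned for inspection.
    The replicate-aware moderated-logit dAPA test is the default here: panel
    experiments have few replicates and the arm-pooled test is
    anti-conservative under biological noise.
    """
    meta = design.drop_duplicates("experiment_id").set_index("experiment_id")
    result = PanelResult(design=design)
    for exp_id in meta.index:
        result.pert_tables[exp_id] = dapa.dapa_perturbation(
            matrix, design, exp_id, method=dapa_method
        )
        de_tab = rbp_assoc.de_status(expression, design, exp_id)
        result.de_tables[exp_id] = de_tab
        target = meta.loc[exp_id, "target_rbp"]
        ok = target in de_tab.index and de_tab.loc[target, "status"] == "down"
        result.gate_passed[exp_id] = bool(ok)
        if not ok:
            logger.info("experiment %s: target %s not significantly down", exp_id,
                        target)
    if not enforce_gate:
        result.gate_passed = {e: True for e in result.gate_passed}
    return result


def infer_regulators(
    matrix: PasCountMatrix,
    normalized_scores: pd.DataFrame,
    rbp_expr: pd.DataFrame,
    panel: PanelResult,
    clip_table: pd.DataFrame,
    alpha: float = 0.05,
    min_experiments_co: int = 20,
) -> pd.DataFrame:
    """Classify every (proximal PAS, RBP) pair by its evidence.

    Only gate-passing experiments contribute PERT and CO evidence. The
    cohort association is restricted to proximal PAS (the pair universe is
    (pPAS, RBP)). Returns the association-record table; the Fig-3C-style
    category summary comes from :func:`rbp_assoc.category_summary`.
    """
    proximal = [a.pas_id for a in matrix.annotations if not a.is_distal]
    scores_prox = normalized_scores.loc[
        normalized_scores.index.intersection(proximal)
    ]
    cohort = rbp_assoc.cohort_association(scores_prox, rbp_expr)

    retained = panel.retained_experiments
    pert_tables = {e: panel.pert_tables[e] for e in retained}
    co_results = None
    if len(retained) >= min_experiments_co:
        dapa_status = rbp_assoc.status_from_tables(pert_tables, "delta_pau")
        de_status_df = rbp_assoc.status_from_tables(
            {e: panel.de_tables[e] for e in retained}, "lfc"
        ).loc[rbp_expr.index.intersection(
            next(iter(panel.de_tables.values())).index)]
        co_results = rbp_assoc.co_tests(
            dapa_status, de_status_df, min_experiments=min_experiments_co
        )
    else:
        logger.info(
            "only %d gate-passing experiments (< %d): CO evidence skipped",
            len(retained), min_experiments_co,
        )

    return rbp_assoc.classify_pairs(
        cohort, clip_table, pert_tables, panel.design, co_results,
        matrix.annotations, alpha_cohort=alpha, alpha_pert=alpha,
    )
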