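"""Multi-evidence classification of (proximal PAS, RBP) regulatory pairs.

Each candidate pair is annotated with up to three lines of experimental
evidence from the depletion panel and binding data:

* CLIP — the RBP has a binding footprint on the site's host terminal exon;
* PERT — the site's usage responds significantly to depletion of the RBP;
* CO   — across the whole panel, the site's dAPA status is contingent on the
  RBP's differential-expression status (chi-square of the status table).

Independently, the tumor cohort provides a significance call (Mann-Whitney
test of normalized PAS scores between high- and low-RBP-expression cohorts)
and a direction. A pair is *consistent* when the usage change upon depletion
matches the change seen in low-RBP-expression tumors — depletion being the
extreme of low expression. Pairs with no experimental evidence are OTHER.
"""

from __future__ import annotations

import logging
import warnings
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_adjust
from .io_formats import PasAnnotation
from .pas_quant import size_factors as _size_factors

logger = logging.getLogger(__name__)

__all__ = [
    "cohort_association",
    "co_test",
    "co_tests",
    "de_status",
    "status_from_tables",
    "classify_pairs",
    "category_summary",
]

_STATUS_LEVELS = ("up", "down", "nonsig")


def cohort_association(
    scores: pd.DataFrame,
    rbp_expr: pd.DataFrame,
    split: str = "median",
    min_per_cohort: int = 10,
) -> pd.DataFrame:
    """Associate every (PAS, RBP) pair across the tumor cohort.

    Samples are split per RBP into low/high expression cohorts (``median``
    split by default, ``tertile`` for bottom vs top thirds); normalized PAS
    scores are compared with a two-sided Mann-Whitney test, BH-adjusted over
    all tested pairs. Direction is the sign of (median score in the low
    cohort minus the high cohort), so it matches the depletion orientation.
    """
    if split not in ("median", "tertile"):
        raise ValueError("split must be 'median' or 'tertile'")
    common = scores.columns.intersection(rbp_expr.columns)
    if len(common) < 2 * min_per_cohort:
        raise ValueError("too few shared samples for the requested cohort size")
    scores = scores[common]
    rbp_expr = rbp_expr[common]

    score_arr = scores.to_numpy(dtype=float)
    rows = []
    for rbp in rbp_expr.index:
        expr = rbp_expr.loc[rbp]
        if split == "median":
            low_mask = (expr <= expr.median()).to_numpy()
            high_mask = ~low_mask
        else:
            lo_q, hi_q = expr.quantile([1 / 3, 2 / 3])
            low_mask = (expr <= lo_q).to_numpy()
            high_mask = (expr > hi_q).to_numpy()
        if low_mask.sum() < min_per_cohort or high_mask.sum() < min_per_cohort:
            logger.info("RBP %s: cohorts below %d samples, skipped", rbp,
                        min_per_cohort)
            continue
        low = score_arr[:, low_mask]
        high = score_arr[:, high_mask]
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(
                low, high, axis=1, nan_policy="omit", alternative="two-sided"
            )
            p = np.asarray(res.pvalue, dtype=float)
        med_low = np.nanmedian(low, axis=1)
        med_high = np.nanmedian(high, axis=1)
        direction = np.sign(med_low - med_high)
        # constant / all-tied scores: no evidence either way
        p = np.where(np.isnan(p), 1.0, p)
        for i, pas_id in enumerate(scores.index):
            rows.append(
                {
                    "pas_id": pas_id, "rbp_id": rbp,
                    "p": p[i],
                    "direction": 0.0 if not np.isfinite(direction[i]) else direction[i],
                }
            )
    result = pd.DataFrame(rows)
    result["q"] = bh_adjust(result["p"])
    return result


def co_test(
    dapa_status: pd.Series, de_status: pd.Series, min_experiments: int = 20
) -> tuple[float, float]:
    """Chi-square of independence between a site's dAPA status and an RBP's
    differential-expression status over the panel's experiments.

    Both series take values in {up, down, nonsig} over the same experiment
    set. Empty levels are collapsed; a table below 2x2 is untested (NaN).
    """
    dapa_status = pd.Series(dapa_status)
    de_status = pd.Series(de_status).reindex(dapa_status.index)
    if de_status.isna().any():
        raise ValueError("statuses must cover the same experiments")
    if len(dapa_status) < min_experiments:
        raise ValueError(f"fewer than {min_experiments} experiments")
    bad = set(dapa_status) | set(de_status)
    if not bad <= set(_STATUS_LEVELS):
        raise ValueError(f"statuses must be in {_STATUS_LEVELS}")
    table = pd.crosstab(de_status, dapa_status)
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return np.nan, np.nan
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(chi2), float(p)


def co_tests(
    dapa_status_df: pd.DataFrame,
    de_status_df: pd.DataFrame,
    fdr_level: float = 0.05,
    min_experiments: int = 20,
) -> pd.DataFrame:
    """Run :func:`co_test` for every (PAS, RBP) combination and BH-flag.

    ``dapa_status_df`` is PAS x experiments, ``de_status_df`` RBP x
    experiments, both with {up, down, nonsig} entries.
    """
    common = dapa_status_df.columns.intersection(de_status_df.columns)
    rows = []
    for pas_id in dapa_status_df.index:
        for rbp in de_status_df.index:
            chi2, p = co_test(
                dapa_status_df.loc[pas_id, common],
                de_status_df.loc[rbp, common],
                min_experiments=min_experiments,
            )
            rows.append({"pas_id": pas_id, "rbp_id": rbp, "chi2": chi2, "p": p})
    result = pd.DataFrame(rows)
    result["q"] = bh_adjust(result["p"])
    result["co"] = (result["q"] < fdr_level).fillna(False)
    return result


def de_status(
    expression: pd.DataFrame,
    design: pd.DataFrame,
    experiment_id: str | None = None,
    caller: Callable[[pd.DataFrame, list, list], pd.DataFrame] | None = None,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Differential-expression status per gene for one depletion experiment.

    The default caller size-factor-normalizes the counts, takes log2 with a
    0.5 pseudocount, runs a moderated two-sample t-test per gene between
    arms (per-gene variance shrunk toward the across-gene median with prior
    df ``prior_df`` — depletion panels rarely have more than 2-3 replicates
    per arm, where raw per-gene variances are too noisy to rank on), and
    gates on BH-adjusted q < ``alpha`` AND |log2 fold change| >
    ``lfc_threshold``. Returns a frame with lfc, p, q, status; the caller is
    pluggable for a full negative-binomial model.
    """
    if experiment_id is not None:
        design = design[design["experiment_id"] == experiment_id]
    if design["experiment_id"].nunique() != 1:
        raise ValueError("design rows span multiple experiments; pass experiment_id")
    ctrl = design.loc[design["arm"] == "control", "sample_id"].tolist()
    depl = design.loc[design["arm"] == "depleted", "sample_id"].tolist()
    if len(ctrl) < 2 or len(depl) < 2:
        raise ValueError("need >= 2 replicates per arm")
    if caller is not None:
        return caller(expression, ctrl, depl)

    counts = expression[ctrl + depl]
    sf = _size_factors(counts)
    log2n = np.log2(counts / sf + 0.5)
    x = log2n[ctrl].to_numpy()
    y = log2n[depl].to_numpy()
    n_c, n_d = x.shape[1], y.shape[1]
    lfc = y.mean(axis=1) - x.mean(axis=1)
    df_g = n_c + n_d - 2
    s2 = (x.var(axis=1, ddof=1) * (n_c - 1) + y.var(axis=1, ddof=1) * (n_d - 1)) / df_g
    s2_0 = float(np.median(s2[np.isfinite(s2)]))
    s2_mod = (prior_df * s2_0 + df_g * s2) / (prior_df + df_g)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat = lfc / np.sqrt(s2_mod * (1.0 / n_c + 1.0 / n_d))
    p = 2.0 * stats.t.sf(np.abs(t_stat), df=prior_df + df_g)
    p = np.where(np.isnan(p), 1.0, p)
    q = bh_adjust(p)
    status = np.where(
        (q < alpha) & (lfc > lfc_threshold), "up",
        np.where((q < alpha) & (lfc < -lfc_threshold), "down", "nonsig"),
    )
    return pd.DataFrame(
        {"lfc": lfc, "p": p, "q": q, "status": status}, index=expression.index
    )


def status_from_tables(
    tables: Mapping[str, pd.DataFrame],
    value_col: str,
    q_col: str = "q",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Collapse per-experiment result tables to an {up, down, nonsig} matrix.

    ``tables`` maps experiment_id to a frame indexed by feature id carrying a
    signed ``value_col`` and an FDR column. Used for both the dAPA axis
    (value = dPAU) and the DE axis (value = lfc) of the CO contingency.
    """
    cols = {}
    for exp_id, tab in tables.items():
        sig = (tab[q_col] < alpha) & tab[q_col].notna()
        val = tab[value_col]
        cols[exp_id] = np.where(
            sig & (val > 0), "up", np.where(sig & (val < 0), "down", "nonsig")
        )
    first = next(iter(tables.values()))
    return pd.DataFrame(cols, index=first.index)


def classify_pairs(
    cohort_results: pd.DataFrame,
    clip_table: pd.DataFrame,
    pert_tables: Mapping[str, pd.DataFrame],
    experiment_meta: pd.DataFrame,
    co_results: pd.DataFrame | None,
    annotations: list[PasAnnotation],
    alpha_cohort: float = 0.05,
    alpha_pert: float = 0.05,
) -> pd.DataFrame:
    """Assemble the evidence record for every cohort-quantified pair.

    PERT is granted when the pair's site is significant (q < ``alpha_pert``)
    in any depletion experiment targeting the RBP; its direction is the dPAU
    sign of the strongest such response. The depletion-vs-cohort consistency
    check compares that sign with the cohort's low-minus-high direction.
    Category is the '+'-joined set of evidence flags, or OTHER when no
    experimental evidence exists.
    """
    exon_of = {a.pas_id: a.exon_id for a in annotations}
    clip_pairs = set(zip(clip_table["rbp_id"], clip_table["exon_id"]))

    meta = experiment_meta.drop_duplicates("experiment_id").set_index("experiment_id")
    # per (pas, rbp): strongest significant depletion response
    pert_sig: dict[tuple[str, str], float] = {}
    pert_best_q: dict[tuple[str, str], float] = {}
    for exp_id, tab in pert_tables.items():
        rbp = meta.loc[exp_id, "target_rbp"]
        sig = tab[(tab["q"] < alpha_pert) & tab["q"].notna()]
        for _, r in sig.iterrows():
            key = (r["pas_id"], rbp)
            if key not in pert_best_q or r["q"] < pert_best_q[key]:
                pert_best_q[key] = r["q"]
                pert_sig[key] = float(np.sign(r["delta_pau"]))

    co_map: dict[tuple[str, str], bool] = {}
    if co_results is not None:
        co_map = {
            (r["pas_id"], r["rbp_id"]): bool(r["co"])
            for _, r in co_results.iterrows()
        }

    rows = []
    for _, r in cohort_results.iterrows():
        pas_id, rbp = r["pas_id"], r["rbp_id"]
        exon = exon_of.get(pas_id)
        clip = (rbp, exon) in clip_pairs
        key = (pas_id, rbp)
        pert = key in pert_sig
        pert_direction = pert_sig.get(key, np.nan)
        co = co_map.get(key, False)
        significant = bool(r["q"] < alpha_cohort) if np.isfinite(r["q"]) else False
        consistent = bool(
            pert
            and np.isfinite(pert_direction)
            and pert_direction != 0
            and pert_direction == r["direction"]
        )
        flags = [name for name, on in
                 (("CLIP", clip), ("PERT", pert), ("CO", co)) if on]
        category = "+".join(flags) if flags else "OTHER"
        rows.append(
            {
                "pas_id": pas_id, "rbp_id": rbp, "clip": clip, "pert": pert,
                "pert_direction": pert_direction, "co": co,
                "cohort_p": r["p"], "cohort_q": r["q"],
                "cohort_direction": r["direction"],
                "significant": significant, "consistent": consistent,
                "category": category,
            }
        )
    return pd.DataFrame(rows)


def category_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Counts of pairs per evidence category, split by cohort significance
    and depletion-cohort consistency."""
    return (
        records.groupby("category")
        .agg(
            n_pairs=("category", "size"),
            n_significant=("significant", "sum"),
            n_consistent=("consistent", "sum"),
        )
        .reset_index()
    )
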