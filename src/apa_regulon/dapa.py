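"""Differential alternative polyadenylation (dAPA) testing.

Cohort test
-----------
For each proximal PAS, usage is contrasted between two sample cohorts with a
no-intercept median (tau = 0.5) quantile regression

    r_PAS = beta0 * r_other + beta1 * D_cond * r_other

where ``r_PAS`` and ``r_other`` are size-factor-normalized read counts
supporting the site and the exon's other sites, and ``D_cond`` is the
condition dummy. beta0 captures the association of the site's usage with host
expression, beta1 the condition-dependent change; significance requires both
(max of the two t-test p-values), adjusted with Benjamini-Hochberg over all
tested PAS. The per-condition median usage comes straight out of the fit:

    PAU_0 = b0 / (1 + b0),   PAU_1 = (b0 + b1) / (1 + b0 + b1)

and dPAU = PAU_1 - PAU_0. A quantile fit is used instead of moment-based
exon-usage models because cohort comparisons of dozens of heterogeneous
samples are better served by tests on medians.

Perturbation test
-----------------
Individual depletion experiments have few replicates; usage change is tested
per proximal PAS on the pooled 2x2 table (site vs other-site counts, control
vs depleted arm) with a continuity-corrected chi-square, switching to
Fisher's exact test when any expected cell is below 5. The tester is
pluggable so an exon-usage model fitted per experiment can be dropped in.

Direction
---------
Terminal-exon shortening vs lengthening is decided by the PAU-weighted mean
PAS rank in transcript orientation: the condition whose weighted rank is
smaller uses more 5' sites, i.e. has shorter terminal exons. dPAU signs are
then adjusted so that positive proximal dPAU always means shortening.
"""

from __future__ import annotations

import logging
import warnings
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._utils import bh_adjust
from .io_formats import PasAnnotation, PasCountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "dapa_cohort",
    "adjust_direction",
    "dapa_perturbation",
    "pooled_chi2_tester",
    "rbp_effect_summary",
    "cross_cellline_consistency",
    "pau_from_betas",
]

DAPA_COLUMNS = [
    "pas_id", "exon_id", "beta0", "beta1", "p_beta0", "p_beta1",
    "p_max", "q", "pau0", "pau1", "delta_pau", "direction", "valid", "reason",
]


def pau_from_betas(beta0: float, beta1: float) -> tuple[float, float, float]:
    """Per-condition median PAU and dPAU recovered from the fitted betas."""
    pau0 = beta0 / (1.0 + beta0)
    pau1 = (beta0 + beta1) / (1.0 + beta0 + beta1)
    return pau0, pau1, pau1 - pau0


def _other_counts(matrix: PasCountMatrix) -> pd.DataFrame:
    """Per PAS, the summed counts of the other PAS of its host exon."""
    counts = matrix.counts
    exon_of = {a.pas_id: a.exon_id for a in matrix.annotations}
    exon_tot = counts.groupby(pd.Series(exon_of)).transform("sum")
    return exon_tot - counts


def dapa_cohort(
    matrix: PasCountMatrix,
    condition: pd.Series,
    size_factors: pd.Series,
    min_samples_per_condition: int = 10,
) -> pd.DataFrame:
    """Cohort-level differential PAS usage via no-intercept quantile regression.

    ``condition`` holds binary labels (0/1) per sample. Only proximal PAS are
    tested. Returns one row per proximal PAS with the fixed ``DAPA_COLUMNS``
    (direction is filled by :func:`adjust_direction`). PAS whose fitted betas
    leave the valid usage range (negative) are flagged, not dropped; PAS
    untestable for data reasons carry a ``reason`` and NaN statistics.
    """
    condition = pd.Series(condition).reindex(matrix.samples)
    if condition.isna().any():
        raise ValueError("condition labels missing for some samples")
    levels = np.unique(condition)
    if len(levels) != 2:
        raise ValueError("condition must be binary")
    D = (condition == levels[1]).to_numpy(dtype=float)
    for lvl in levels:
        if (condition == lvl).sum() < min_samples_per_condition:
            raise ValueError(
                f"condition {lvl!r} has fewer than {min_samples_per_condition} samples"
            )
    sf = pd.Series(size_factors).reindex(matrix.samples)
    if sf.isna().any() or (sf <= 0).any():
        raise ValueError("size factors must be positive for every sample")

    norm = matrix.counts / sf
    other = _other_counts(matrix) / sf
    exon_of = {a.pas_id: a.exon_id for a in matrix.annotations}

    rows = []
    for ann in matrix.annotations:
        if ann.is_distal:
            continue
        pid = ann.pas_id
        r_pas = norm.loc[pid].to_numpy(dtype=float)
        r_other = other.loc[pid].to_numpy(dtype=float)
        row = {
            "pas_id": pid, "exon_id": exon_of[pid],
            "beta0": np.nan, "beta1": np.nan, "p_beta0": np.nan,
            "p_beta1": np.nan, "p_max": np.nan, "q": np.nan,
            "pau0": np.nan, "pau1": np.nan, "delta_pau": np.nan,
            "direction": "none", "valid": False, "reason": "",
        }
        zero0 = np.all(r_other[D == 0] == 0)
        zero1 = np.all(r_other[D == 1] == 0)
        if zero0 or zero1:
            row["reason"] = "all-zero r_other in a condition"
            rows.append(row)
            continue
        X = np.column_stack([r_other, D * r_other])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.QuantReg(r_pas, X).fit(q=0.5)
        except Exception as exc:  # singular designs on degenerate data
            row["reason"] = f"fit failed: {exc}"
            rows.append(row)
            continue
        b0, b1 = fit.params
        p0, p1 = fit.pvalues
        # a numerically exact fit can defeat the bandwidth estimate
        if not np.isfinite(p0):
            p0 = 0.0 if fit.bse[0] == 0 else 1.0
        if not np.isfinite(p1):
            p1 = 0.0 if fit.bse[1] == 0 else 1.0
        pau0, pau1, dpau = pau_from_betas(b0, b1)
        row.update(
            beta0=b0, beta1=b1, p_beta0=p0, p_beta1=p1,
            p_max=max(p0, p1), pau0=pau0, pau1=pau1, delta_pau=dpau,
            valid=bool(b0 >= 0 and b0 + b1 >= 0),
        )
        if not row["valid"]:
            row["reason"] = "beta outside valid usage range"
        rows.append(row)

    result = pd.DataFrame(rows, columns=DAPA_COLUMNS)
    result["q"] = bh_adjust(result["p_max"])
    return result


def weighted_pas_rank(
    pau: pd.DataFrame, annotations: list[PasAnnotation]
) -> pd.DataFrame:
    """PAU-weighted mean PAS rank per (exon, sample), transcript orientation.

    Smaller values mean usage concentrated on 5' sites, i.e. shorter
    terminal exons. NaN where the exon has no defined usage in a sample.
    """
    rank = pd.Series({a.pas_id: a.rank_from_5p for a in annotations})
    exon_of = pd.Series({a.pas_id: a.exon_id for a in annotations})
    weighted = pau.mul(rank.reindex(pau.index), axis=0)
    return weighted.groupby(exon_of.reindex(pau.index)).sum(min_count=1)


def adjust_direction(
    results: pd.DataFrame,
    annotations: list[PasAnnotation],
    pau: pd.DataFrame,
    condition: pd.Series,
) -> pd.DataFrame:
    """Fill ``direction`` and fix dPAU signs so positive proximal dPAU means
    terminal-exon shortening.

    Per exon, the condition whose median PAU-weighted PAS rank is smaller has
    the shorter terminal exons; an exon-level shortening call (condition 1 vs
    condition 0) propagates to its proximal PAS, whose dPAU magnitudes keep
    their size but take the direction's sign. Single-PAS exons and exons with
    equal weighted ranks stay ``none``.
    """
    condition = pd.Series(condition).reindex(pau.columns)
    levels = np.unique(condition)
    if len(levels) != 2:
        raise ValueError("condition must be binary")
    wrank = weighted_pas_rank(pau, annotations)
    med0 = wrank.loc[:, condition == levels[0]].median(axis=1)
    med1 = wrank.loc[:, condition == levels[1]].median(axis=1)

    n_pas_per_exon = pd.Series({a.pas_id: a.exon_id for a in annotations}).value_counts()
    out = results.copy()
    for i, row in out.iterrows():
        exon = row["exon_id"]
        if n_pas_per_exon.get(exon, 0) < 2:
            out.at[i, "direction"] = "none"
            continue
        m0, m1 = med0.get(exon, np.nan), med1.get(exon, np.nan)
        if not (np.isfinite(m0) and np.isfinite(m1)) or m0 == m1:
            out.at[i, "direction"] = "none"
            continue
        shortening = m1 < m0
        out.at[i, "direction"] = "shortening" if shortening else "lengthening"
        d = row["delta_pau"]
        if np.isfinite(d) and d != 0:
            out.at[i, "delta_pau"] = abs(d) if shortening else -abs(d)
        elif d == 0:
            out.at[i, "direction"] = "none"
    return out


def pooled_chi2_tester(table: np.ndarray, correction: bool = True) -> float:
    """p-value of a 2x2 site-vs-other by arm table.

    Continuity-corrected chi-square by default; Fisher's exact test when any
    expected cell is below 5.
    """
    table = np.asarray(table, dtype=float)
    if table.sum() == 0:
        return np.nan
    row_tot = table.sum(axis=1, keepdims=True)
    col_tot = table.sum(axis=0, keepdims=True)
    expected = row_tot * col_tot / table.sum()
    if (expected < 5).any():
        return float(stats.fisher_exact(table)[1])
    return float(stats.chi2_contingency(table, correction=correction)[1])


def dapa_perturbation(
    matrix: PasCountMatrix,
    design: pd.DataFrame,
    experiment_id: str | None = None,
    method: str = "pooled",
    tester: Callable[[np.ndarray], float] | None = None,
    min_replicates: int = 2,
    prior_df: float = 20.0,
) -> pd.DataFrame:
    """Per-proximal-PAS usage change in one depletion experiment.

    dPAU = PAU(depleted) - PAU(control) from arm-pooled counts. Two testing
    methods are offered:

    ``pooled`` (default): p-value from ``tester`` on the arm-pooled 2x2
    table (site vs other-site counts; default :func:`pooled_chi2_tester`).
    Fast and simple, but blind to replicate-to-replicate variability, hence
    anti-conservative when biological noise is present.

    ``logit``: moderated t-test on per-replicate empirical logits
    log((M + 0.5) / (O + 0.5)), with the per-PAS variance shrunk toward the
    experiment-wide median (prior df ``prior_df``) — the same
    information-sharing idea exon-usage models rely on with few replicates.

    q is BH-adjusted within the experiment. Exon-level direction is called
    from arm-wise pooled PAU-weighted ranks. PAS with a zero-coverage arm
    are untested.
    """
    if method not in ("pooled", "logit"):
        raise ValueError("method must be 'pooled' or 'logit'")
    if tester is None and method == "pooled":
        tester = pooled_chi2_tester
    if experiment_id is not None:
        design = design[design["experiment_id"] == experiment_id]
    if design.empty:
        raise ValueError("no design rows for the requested experiment")
    if design["experiment_id"].nunique() != 1:
        raise ValueError("design rows span multiple experiments; pass experiment_id")
    for arm in ("control", "depleted"):
        if (design["arm"] == arm).sum() < min_replicates:
            raise ValueError(f"fewer than {min_replicates} {arm} replicates")

    ctrl = design.loc[design["arm"] == "control", "sample_id"].tolist()
    depl = design.loc[design["arm"] == "depleted", "sample_id"].tolist()
    pooled = pd.DataFrame(
        {
            "control": matrix.counts[ctrl].sum(axis=1),
            "depleted": matrix.counts[depl].sum(axis=1),
        }
    )
    exon_of = pd.Series({a.pas_id: a.exon_id for a in matrix.annotations})
    other = pooled.groupby(exon_of.reindex(pooled.index)).transform("sum") - pooled

    logit_p: dict[str, float] = {}
    if method == "logit":
        sub = matrix.counts[ctrl + depl]
        other_rep = sub.groupby(exon_of.reindex(sub.index)).transform("sum") - sub
        logits = np.log((sub + 0.5) / (other_rep + 0.5))
        lc = logits[ctrl].to_numpy(dtype=float)
        ld = logits[depl].to_numpy(dtype=float)
        n_c, n_d = len(ctrl), len(depl)
        diff = ld.mean(axis=1) - lc.mean(axis=1)
        df_g = n_c + n_d - 2
        s2 = (lc.var(axis=1, ddof=1) * (n_c - 1) + ld.var(axis=1, ddof=1) * (n_d - 1)) / df_g
        testable = np.isfinite(s2)
        s2_0 = float(np.median(s2[testable])) if testable.any() else np.nan
        s2_mod = (prior_df * s2_0 + df_g * s2) / (prior_df + df_g)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_stat = diff / np.sqrt(s2_mod * (1.0 / n_c + 1.0 / n_d))
        p_arr = 2.0 * stats.t.sf(np.abs(t_stat), df=prior_df + df_g)
        logit_p = dict(zip(sub.index, p_arr))

    # arm-level pooled PAU and weighted ranks for direction calls
    exon_tot = pooled + other
    with np.errstate(invalid="ignore", divide="ignore"):
        pau_pooled = pooled / exon_tot
    wrank = weighted_pas_rank(pau_pooled, matrix.annotations)
    n_pas_per_exon = exon_of.value_counts()

    rows = []
    for ann in matrix.annotations:
        if ann.is_distal:
            continue
        pid = ann.pas_id
        m_c, m_d = pooled.loc[pid, "control"], pooled.loc[pid, "depleted"]
        o_c, o_d = other.loc[pid, "control"], other.loc[pid, "depleted"]
        row = {
            "pas_id": pid, "exon_id": ann.exon_id, "delta_pau": np.nan,
            "p": np.nan, "q": np.nan, "direction": "none", "reason": "",
        }
        if m_c + o_c == 0 or m_d + o_d == 0:
            row["reason"] = "zero exon coverage in an arm"
            rows.append(row)
            continue
        row["delta_pau"] = m_d / (m_d + o_d) - m_c / (m_c + o_c)
        if method == "logit" and tester is None:
            row["p"] = logit_p.get(pid, np.nan)
        else:
            row["p"] = tester(np.array([[m_c, o_c], [m_d, o_d]]))
        exon = ann.exon_id
        if n_pas_per_exon[exon] >= 2:
            w_c = wrank.loc[exon, "control"]
            w_d = wrank.loc[exon, "depleted"]
            if np.isfinite(w_c) and np.isfinite(w_d) and w_c != w_d:
                # delta_pau itself stays the raw depleted-minus-control
                # response; the terminal-exon length call is separate
                row["direction"] = "shortening" if w_d < w_c else "lengthening"
        rows.append(row)
    result = pd.DataFrame(rows)
    result["q"] = bh_adjust(result["p"])
    return result


def rbp_effect_summary(
    experiment_tables: Mapping[str, pd.DataFrame],
    experiment_meta: pd.DataFrame,
    sig_threshold: float = 0.05,
    fdr_flag_level: float = 0.10,
) -> pd.DataFrame:
    """Per-experiment shortening/lengthening tallies with a binomial skew test.

    ``experiment_tables`` maps experiment_id to a :func:`dapa_perturbation`
    result; ``experiment_meta`` needs experiment_id, target_rbp, cell_line.
    Significant proximal PAS (q < ``sig_threshold``) are grouped by terminal
    exon and each exon votes once with its dominant direction (majority of
    significant PAS, |dPAU| sum breaking ties; exact ties abstain). The skew
    of shortening vs lengthening exons is tested two-sided against a fair
    coin and BH-flagged across experiments at FDR < ``fdr_flag_level``.
    """
    meta = experiment_meta.drop_duplicates("experiment_id").set_index("experiment_id")
    rows = []
    effect_vectors = {}
    for exp_id, table in experiment_tables.items():
        sig = table[(table["q"] < sig_threshold) & table["q"].notna()]
        n_short = n_leng = 0
        for exon, grp in sig.groupby("exon_id"):
            votes = grp["direction"].value_counts()
            s, l = votes.get("shortening", 0), votes.get("lengthening", 0)
            if s == l:
                mag = grp.groupby("direction")["delta_pau"].apply(
                    lambda d: d.abs().sum()
                )
                s, l = mag.get("shortening", 0.0), mag.get("lengthening", 0.0)
            if s > l:
                n_short += 1
            elif l > s:
                n_leng += 1
        n_dir = n_short + n_leng
        if n_dir > 0:
            p_binom = stats.binomtest(n_short, n_dir, 0.5).pvalue
        else:
            p_binom = np.nan
        log2_ratio = (
            np.log2(n_short / n_leng) if n_short > 0 and n_leng > 0 else np.nan
        )
        rows.append(
            {
                "experiment_id": exp_id,
                "rbp_id": meta.loc[exp_id, "target_rbp"],
                "cell_line": meta.loc[exp_id, "cell_line"],
                "n_significant": int(len(sig)),
                "n_shortening": n_short,
                "n_lengthening": n_leng,
                "log2_ratio": log2_ratio,
                "log2_ratio_pseudo": np.log2((n_short + 0.5) / (n_leng + 0.5)),
                "p_binomial": p_binom,
            }
        )
        effect_vectors[exp_id] = table.set_index("pas_id")["delta_pau"].dropna()
    summary = pd.DataFrame(rows)
    summary["q_binomial"] = bh_adjust(summary["p_binomial"])
    summary["fdr_flag"] = (summary["q_binomial"] < fdr_flag_level).fillna(False)
    summary.attrs["effect_vectors"] = effect_vectors
    return summary


def cross_cellline_consistency(
    summary_a: pd.DataFrame,
    summary_b: pd.DataFrame,
    min_shared: int = 3,
) -> pd.DataFrame:
    """Cosine similarity of signed dPAU effect vectors between two cell lines.

    Vectors are restricted to proximal PAS tested in both panels; similarity
    is undefined (NaN, with reason) below ``min_shared`` shared sites or when
    either restricted vector is all-zero.
    """
    vec_a = summary_a.attrs["effect_vectors"]
    vec_b = summary_b.attrs["effect_vectors"]
    rbp_of_a = summary_a.set_index("experiment_id")["rbp_id"]
    rbp_of_b = summary_b.set_index("experiment_id")["rbp_id"]
    by_rbp_a = {rbp_of_a[e]: v for e, v in vec_a.items()}
    by_rbp_b = {rbp_of_b[e]: v for e, v in vec_b.items()}

    rows = []
    for rbp in sorted(set(by_rbp_a) & set(by_rbp_b)):
        a, b = by_rbp_a[rbp], by_rbp_b[rbp]
        shared = a.index.intersection(b.index)
        row = {"rbp_id": rbp, "n_shared": len(shared), "cosine": np.nan, "reason": ""}
        if len(shared) < min_shared:
            row["reason"] = f"fewer than {min_shared} shared pPAS"
        else:
            x, y = a[shared].to_numpy(), b[shared].to_numpy()
            nx, ny = np.linalg.norm(x), np.linalg.norm(y)
            if nx == 0 or ny == 0:
                row["reason"] = "all-zero effect vector"
            else:
                row["cosine"] = float(x @ y / (nx * ny))
        rows.append(row)
    return pd.DataFrame(rows)
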