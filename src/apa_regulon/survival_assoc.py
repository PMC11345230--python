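"""Survival association of expression- and APA-derived principal components.

The analysis asks whether latent axes of the transcriptome — principal
components of gene expression, of proximal-PAS usage scores, or of both
combined — stratify patient survival beyond tumor purity. Sample coordinates
along a candidate axis are rank-transformed and every admissible rank
threshold is tried as a two-group split, scored with a two-sample log-rank
test; a flat, low p-value profile across thresholds marks a robustly
prognostic axis. Confounding with purity is measured by Kendall tau with a
percentile-bootstrap confidence interval. Finally, crossing a purity
threshold with an APA-axis threshold yields a four-group stratification
scored with the K-sample log-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "PcResult",
    "ScanResult",
    "select_features",
    "pca_embed",
    "kendall_with_ci",
    "logrank_scan",
    "four_group_split",
]


@dataclass
class PcResult:
    """PCA embedding: sample coordinates and per-component variance shares."""

    coordinates: pd.DataFrame  # samples x components
    variance_explained: np.ndarray
    feature_set: str = ""


@dataclass
class ScanResult:
    """Rank-threshold log-rank scan output."""

    thresholds: np.ndarray
    p_values: np.ndarray
    no_event_flags: np.ndarray
    ranks: pd.Series = field(repr=False, default=None)

    @property
    def median_p(self) -> float:
        return float(np.median(self.p_values))

    @property
    def best_threshold(self) -> int:
        return int(self.thresholds[int(np.argmin(self.p_values))])


def select_features(
    expr: pd.DataFrame,
    scores: pd.DataFrame,
    mode: str,
    n_features: int,
) -> pd.DataFrame:
    """Pick the feature rows for a PCA feature set.

    ``expression``: the n genes with highest median normalized expression.
    ``apa``: the n proximal-PAS score rows with fewest zero/undefined scores.
    ``combined``: floor(n/2) pPAS by fewest zeros plus ceil(n/2) genes by
    median expression (e.g. 493 + 494 for n = 987). Ties at a cutoff break
    lexicographically by feature id, so selection is deterministic.
    """
    if mode not in ("expression", "apa", "combined"):
        raise ValueError("mode must be 'expression', 'apa' or 'combined'")

    def top_expr(n):
        if n > expr.shape[0]:
            raise ValueError("n_features exceeds available genes")
        med = expr.median(axis=1)
        order = sorted(expr.index, key=lambda g: (-med[g], g))
        return expr.loc[order[:n]]

    def top_apa(n):
        if n > scores.shape[0]:
            raise ValueError("n_features exceeds available pPAS")
        n_zero = ((scores == 0) | scores.isna()).sum(axis=1)
        order = sorted(scores.index, key=lambda p: (n_zero[p], p))
        return scores.loc[order[:n]]

    if mode == "expression":
        return top_expr(n_features)
    if mode == "apa":
        return top_apa(n_features)
    n_apa = n_features // 2
    n_expr = n_features - n_apa
    return pd.concat([top_apa(n_apa), top_expr(n_expr)])


def pca_embed(
    features: pd.DataFrame, n_components: int = 8, scale: bool = False,
    feature_set: str = "",
) -> PcResult:
    """Centered PCA of a features x samples matrix.

    Features with any missing value are dropped (logged). Standardization is
    off by default and configurable. Sign convention: each component is
    oriented so its largest-magnitude loading is positive, making
    coordinates reproducible across runs and library versions.
    """
    complete = features.dropna(axis=0)
    n_dropped = features.shape[0] - complete.shape[0]
    if n_dropped:
        logger.info("pca_embed: dropped %d features with missing values", n_dropped)
    X = complete.to_numpy(dtype=float).T  # samples x features
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    n_comp = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(X)
    for j in range(n_comp):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1
            pca.components_[j] *= -1
    coordinates = pd.DataFrame(
        coords, index=features.columns,
        columns=[f"PC{j + 1}" for j in range(n_comp)],
    )
    return PcResult(
        coordinates=coordinates,
        variance_explained=pca.explained_variance_ratio_.copy(),
        feature_set=feature_set,
    )


def kendall_with_ci(
    x, y, n_boot: int = 1000, seed: int = 0, ci_level: float = 0.95
) -> tuple[float, float, float]:
    """Kendall tau-b with a seeded percentile-bootstrap confidence interval.

    Returns (tau, ci_low, ci_high); all NaN when either variable is constant
    (tau undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and aligned")
    if len(x) < 10:
        raise ValueError("need at least 10 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan, np.nan
    tau = stats.kendalltau(x, y).statistic
    rng = np.random.default_rng(seed)
    n = len(x)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if np.ptp(x[idx]) == 0 or np.ptp(y[idx]) == 0:
            boot[b] = np.nan
            continue
        boot[b] = stats.kendalltau(x[idx], y[idx]).statistic
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.nanpercentile(boot, [100 * alpha, 100 * (1 - alpha)])
    return float(tau), float(lo), float(hi)


def _ranks_with_id_tiebreak(values: pd.Series) -> pd.Series:
    """Ascending 1..n ranks; ties broken deterministically by sample id."""
    order = np.lexsort((values.index.to_numpy(), values.to_numpy()))
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(1, len(values) + 1)
    return pd.Series(ranks, index=values.index)


def logrank_scan(
    values: pd.Series,
    time: pd.Series,
    event: pd.Series,
    min_group: int = 30,
) -> ScanResult:
    """Two-sample log-rank p-value at every admissible rank threshold.

    Sample values are rank-transformed (ascending, id tie-break) and every
    threshold t in [min_group, n - min_group] splits the cohort into
    {rank <= t} vs {rank > t}. Thresholds where either group has no events
    record p = 1 with a flag. The scan only sees ranks, so it is invariant
    to strictly monotone transforms of the values.
    """
    values = pd.Series(values)
    time = pd.Series(time).reindex(values.index)
    event = pd.Series(event).reindex(values.index)
    if time.isna().any() or event.isna().any():
        raise ValueError("time/event missing for some samples")
    n = len(values)
    if n < 2 * min_group:
        raise ValueError("need at least 2*min_group samples")
    ranks = _ranks_with_id_tiebreak(values)
    thresholds = np.arange(min_group, n - min_group + 1)
    p_values = np.empty(len(thresholds))
    flags = np.zeros(len(thresholds), dtype=bool)
    t_arr = time.to_numpy(dtype=float)
    e_arr = event.to_numpy(dtype=int)
    r_arr = ranks.to_numpy()
    for i, t in enumerate(thresholds):
        low = r_arr <= t
        if e_arr[low].sum() == 0 or e_arr[~low].sum() == 0:
            p_values[i] = 1.0
            flags[i] = True
            continue
        res = logrank_test(t_arr[low], t_arr[~low], e_arr[low], e_arr[~low])
        p_values[i] = res.p_value
    return ScanResult(
        thresholds=thresholds, p_values=p_values, no_event_flags=flags, ranks=ranks
    )


def four_group_split(
    purity: pd.Series,
    pc_values: pd.Series,
    time: pd.Series,
    event: pd.Series,
    t_purity: float | None = None,
    t_pc: float | None = None,
    min_group: int = 30,
) -> tuple[pd.Series, float]:
    """Cross two thresholded axes into (up to) four survival groups.

    Thresholds are values on each axis; when omitted, each axis is scanned
    with :func:`logrank_scan` and its argmin-p rank threshold is converted
    to a value threshold. Groups are the 2x2 cross of (purity <= / >
    t_purity) x (pc <= / > t_pc), compared with the K-sample log-rank test.
    Empty cells are allowed as long as at least two groups remain (identical
    axes collapse to a two-group comparison, where the K-sample test reduces
    to the two-sample one); fewer than two raises an error naming the group.
    """
    purity = pd.Series(purity)
    pc_values = pd.Series(pc_values).reindex(purity.index)
    time = pd.Series(time).reindex(purity.index)
    event = pd.Series(event).reindex(purity.index)

    def scan_threshold(vals: pd.Series) -> float:
        scan = logrank_scan(vals, time, event, min_group=min_group)
        best = scan.best_threshold
        # value of the sample holding the argmin rank
        return float(vals[scan.ranks[scan.ranks == best].index[0]])

    if t_purity is None:
        t_purity = scan_threshold(purity)
    if t_pc is None:
        t_pc = scan_threshold(pc_values)
    if not (purity.min() <= t_purity <= purity.max()):
        raise ValueError("t_purity outside the data range")
    if not (pc_values.min() <= t_pc <= pc_values.max()):
        raise ValueError("t_pc outside the data range")

    labels = pd.Series(
        np.where(
            purity <= t_purity,
            np.where(pc_values <= t_pc, "purity-low/pc-low", "purity-low/pc-high"),
            np.where(pc_values <= t_pc, "purity-high/pc-low", "purity-high/pc-high"),
        ),
        index=purity.index,
        name="group",
    )
    counts = labels.value_counts()
    nonempty = counts[counts > 0]
    if len(nonempty) < 2:
        raise ValueError(
            f"only group {nonempty.index.tolist()} is populated; "
            "cannot compare survival"
        )
    if len(nonempty) < 4:
        empty = sorted(
            {"purity-low/pc-low", "purity-low/pc-high",
             "purity-high/pc-low", "purity-high/pc-high"} - set(nonempty.index)
        )
        logger.warning("four_group_split: empty groups %s; comparing %d groups",
                       empty, len(nonempty))
    res = multivariate_logrank_test(time, labels, event)
    return labels, float(res.p_value)
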