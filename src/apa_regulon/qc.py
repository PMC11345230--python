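"""Quality control: replicate-pair outlier removal and unstable-PAS filtering.

Replicate pairs (a control sample and its bioreplicate) are embedded with PCA
and pairs whose Euclidean distance exceeds q75 + 1.5*IQR of all pair
distances are discarded — the standard boxplot upper fence, applied strictly
("higher than", so a distance equal to the fence survives). The embedding is
pluggable: any precomputed sample x dims coordinate matrix can be supplied
instead, and outliers from several embeddings can be unioned by the caller.

PAS whose scores fluctuate strongly within control samples of any group are
unreliable and removed before differential testing; the default fluctuation
statistic is the IQR of the normalized score, with the cutoff at the 90th
percentile of per-PAS statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = ["OutlierRule", "pair_outlier_filter", "unstable_pas_filter"]


@dataclass(frozen=True)
class OutlierRule:
    """Upper-fence rule on replicate-pair distances: q75 + 1.5*IQR."""

    q75: float
    iqr: float

    @property
    def threshold(self) -> float:
        return self.q75 + 1.5 * self.iqr

    def is_outlier(self, distance: float) -> bool:
        return distance > self.threshold


def _iqr(values: np.ndarray) -> float:
    q25, q75 = np.percentile(values, [25, 75])
    return float(q75 - q25)


def pair_outlier_filter(
    features: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    embed_dims: int = 2,
    embedding: pd.DataFrame | None = None,
) -> tuple[list[tuple[str, str]], OutlierRule, pd.Series]:
    """Flag replicate pairs that sit unusually far apart in embedding space.

    Parameters
    ----------
    features : samples x k matrix (rows indexed by sample id).
    pairs : replicate pairs of sample ids; at least 4 are required for the
        fence to be defined.
    embed_dims : number of PCA components (>= 2) used when no precomputed
        ``embedding`` is given.
    embedding : optional precomputed samples x dims coordinates, overriding
        the PCA (e.g. a UMAP layout computed elsewhere).

    Returns (retained pairs, rule, per-pair distances). Pairs at exactly the
    fence are retained.
    """
    if len(pairs) < 4:
        raise ValueError("at least 4 replicate pairs are required to define the rule")
    if embed_dims < 2:
        raise ValueError("embed_dims must be >= 2")
    members = {s for pair in pairs for s in pair}
    missing = members - set(features.index)
    if missing:
        raise ValueError(f"pair members missing from features: {sorted(missing)}")

    if embedding is None:
        n_comp = min(embed_dims, features.shape[0] - 1, features.shape[1])
        coords = PCA(n_components=n_comp).fit_transform(
            features.to_numpy(dtype=float)
        )
        embedding = pd.DataFrame(coords, index=features.index)

    dist = pd.Series(
        {
            f"{a}|{b}": float(
                np.linalg.norm(embedding.loc[a].to_numpy() - embedding.loc[b].to_numpy())
            )
            for a, b in pairs
        }
    )
    rule = OutlierRule(q75=float(np.percentile(dist, 75)), iqr=_iqr(dist.to_numpy()))
    retained = [
        (a, b) for a, b in pairs if not rule.is_outlier(dist[f"{a}|{b}"])
    ]
    n_removed = len(pairs) - len(retained)
    if n_removed:
        logger.info(
            "pair_outlier_filter: removed %d/%d pairs above fence %.4g",
            n_removed, len(pairs), rule.threshold,
        )
    return retained, rule, dist


def unstable_pas_filter(
    scores: pd.DataFrame,
    groups: pd.Series,
    dispersion_stat: Callable[[np.ndarray], float] | None = None,
    cutoff: float | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Drop PAS whose scores fluctuate strongly within control groups.

    Parameters
    ----------
    scores : normalized-score matrix restricted to control samples
        (PAS x samples).
    groups : control-group label per sample (e.g. cell line).
    dispersion_stat : statistic of within-group fluctuation; default IQR.
    cutoff : PAS whose statistic strictly exceeds this in any group are
        dropped. Default: the 90th percentile of the per-PAS maxima of the
        statistic across groups.

    Returns (retained pas ids, report). The report lists every PAS with its
    per-group statistic, the applied cutoff, and the removal reason.
    PAS with a statistic exactly at the cutoff are retained. PAS with no
    defined scores in some group are dropped with reason "no data".

    Requires >= 4 control samples per group.
    """
    groups = pd.Series(groups).reindex(scores.columns)
    if groups.isna().any():
        raise ValueError("every score column needs a group label")
    for g, cols in groups.groupby(groups).groups.items():
        if len(cols) < 4:
            raise ValueError(f"group {g!r} has fewer than 4 control samples")
    stat = dispersion_stat or _iqr

    stats = {}
    no_data = set()
    for g in groups.unique():
        cols = groups.index[groups == g]
        block = scores[cols].to_numpy(dtype=float)
        vals = np.full(block.shape[0], np.nan)
        for i in range(block.shape[0]):
            row = block[i][np.isfinite(block[i])]
            if row.size == 0:
                no_data.add(scores.index[i])
                continue
            vals[i] = stat(row)
        stats[g] = vals
    stat_df = pd.DataFrame(stats, index=scores.index)

    max_stat = stat_df.max(axis=1)
    if cutoff is None:
        cutoff = float(np.nanpercentile(max_stat, 90))
    dropped_fluct = (max_stat > cutoff).fillna(False)

    report = stat_df.copy()
    report["max_stat"] = max_stat
    report["cutoff"] = cutoff
    report["reason"] = ""
    report.loc[dropped_fluct, "reason"] = "fluctuation above cutoff"
    report.loc[sorted(no_data), "reason"] = "no data"
    retained = [
        pid for pid in scores.index
        if not dropped_fluct.get(pid, False) and pid not in no_data
    ]
    logger.info(
        "unstable_pas_filter: retained %d/%d PAS (cutoff %.4g)",
        len(retained), scores.shape[0], cutoff,
    )
    return retained, report
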