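"""PAS usage quantification: PAU, the binomial PAS score, size factors, and
library-size-controlled score normalization.

PAU (poly(A)-site usage) of a site is its read count as a fraction of the
total over all sites of the host terminal exon. The PAS score contrasts two
binomial tail tests of the site's count M against the exon total N under an
even split (p = 0.5):

    score = -log10 P(m > M | N, 0.5) + log10 P(m < M | N, 0.5)

so a dominant (major-isoform) site drives the score to +inf, a minor site to
-inf, and an even split gives exactly 0. Low-coverage exons give scores near
zero rather than extreme usage estimates, which is the point of scoring
instead of using raw PAU.

Because deeper libraries produce larger |score| at the same underlying usage,
a per-PAS median (quantile tau = 0.5) regression of |score| on library size is
fitted and only positive residuals are kept as normalized magnitudes, signed
by the original score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import binom

from .io_formats import PasCountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "compute_pau",
    "pau_table",
    "pas_score",
    "score_matrix",
    "size_factors",
    "normalize_scores",
    "PasScoreMatrix",
]

# smallest positive normal double: p-value clamp keeping scores finite
_EPS = np.finfo(float).tiny


def compute_pau(counts) -> np.ndarray:
    """Relative usage of each PAS of one exon: counts / total.

    Returns NaN for every site when the exon has zero total reads
    (a zero-coverage exon has no defined usage).
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        return np.full_like(c, np.nan)
    return c / total


def pau_table(matrix: PasCountMatrix) -> pd.DataFrame:
    """Per-(PAS, sample) PAU over the full count matrix.

    NaN marks zero-coverage (exon, sample) combinations.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    pau = np.full_like(counts, np.nan)
    pas_index = {pid: i for i, pid in enumerate(matrix.pas_ids)}
    for exon_id, anns in matrix.exon_groups().items():
        rows = [pas_index[a.pas_id] for a in anns]
        block = counts[rows, :]
        totals = block.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = block / totals
        frac[:, totals == 0] = np.nan
        pau[rows, :] = frac
    return pd.DataFrame(pau, index=matrix.counts.index, columns=matrix.counts.columns)


def pas_score(M, N) -> float:
    """Signed binomial usage score of a PAS supported by M of N exon reads.

    Both tails are strict (the point mass at M belongs to neither), and both
    p-values are clamped to [tiny, 1] so the score stays finite.
    """
    M = int(M)
    N = int(N)
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 <= M <= N:
        raise ValueError("require 0 <= M <= N")
    # P(m > M) and P(m < M) under Binomial(N, 0.5); the lower tail is
    # evaluated through the exact symmetry P(m < M) = P(m > N - M), which
    # makes score(N - M, N) == -score(M, N) hold bit-exactly
    pval1 = binom.sf(M, N, 0.5)
    pval2 = binom.sf(N - M, N, 0.5)
    pval1 = min(max(pval1, _EPS), 1.0)
    pval2 = min(max(pval2, _EPS), 1.0)
    return float(-np.log10(pval1) + np.log10(pval2))


def score_matrix(matrix: PasCountMatrix) -> pd.DataFrame:
    """PAS score per (PAS, sample); NaN where the exon has zero coverage."""
    counts = matrix.counts.to_numpy(dtype=np.int64)
    out = np.full(counts.shape, np.nan)
    pas_index = {pid: i for i, pid in enumerate(matrix.pas_ids)}
    for exon_id, anns in matrix.exon_groups().items():
        rows = [pas_index[a.pas_id] for a in anns]
        block = counts[rows, :]
        totals = block.sum(axis=0)
        for j, total in enumerate(totals):
            if total == 0:
                continue
            for r, row in enumerate(rows):
                out[row, j] = pas_score(block[r, j], total)
    return pd.DataFrame(out, index=matrix.counts.index, columns=matrix.counts.columns)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Each row is divided by its median; the size factor of sample k is the
    median of column k of the ratio matrix. Rows without a positive median are
    excluded from the estimate (logged).
    """
    arr = counts.to_numpy(dtype=float)
    row_med = np.median(arr, axis=1)
    keep = row_med > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("size_factors: %d rows without positive median excluded", n_dropped)
    if not keep.any():
        raise ValueError("no informative rows: every row median is zero")
    ratios = arr[keep] / row_med[keep, None]
    sf = np.median(ratios, axis=0)
    if (sf <= 0).any():
        raise ValueError("non-positive size factor; matrix too sparse")
    return pd.Series(sf, index=counts.columns, name="size_factor")


@dataclass
class PasScoreMatrix:
    """Raw and library-size-controlled PAS scores (PAS x samples)."""

    score: pd.DataFrame
    normalized_score: pd.DataFrame | None = None


def _median_fit_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals of a tau=0.5 quantile regression y ~ a + b*x.

    Falls back to a flat median fit when the response is (near-)constant or
    the fit degenerates, giving zero residuals for a constant response.
    """
    if np.ptp(y) < 1e-12 or np.ptp(x) < 1e-12:
        return y - np.median(y)
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.QuantReg(y, X).fit(q=0.5)
        fitted = res.predict(X)
    except Exception:
        fitted = np.full_like(y, np.median(y))
    return y - fitted


def normalize_scores(
    scores: pd.DataFrame | PasScoreMatrix,
    library_size: pd.Series,
    min_samples: int = 8,
) -> PasScoreMatrix:
    """Remove the library-size trend from PAS scores.

    Per PAS, a median regression of |score| on library size is fitted across
    samples; positive residuals become normalized magnitudes (negative ones
    are zeroed) and the sign of the original score is restored. PAS with
    fewer than ``min_samples`` defined scores are left undefined (logged).
    """
    if isinstance(scores, PasScoreMatrix):
        score_df = scores.score
    else:
        score_df = scores
    lib = pd.Series(library_size, dtype=float).reindex(score_df.columns)
    if lib.isna().any():
        raise ValueError("library_size missing for some samples")

    score_arr = score_df.to_numpy(dtype=float)
    lib_arr = lib.to_numpy()
    out = np.full(score_arr.shape, np.nan)
    n_skipped = 0
    for i in range(score_arr.shape[0]):
        row = score_arr[i]
        defined = np.isfinite(row)
        if defined.sum() < min_samples:
            n_skipped += 1
            continue
        resid = _median_fit_residuals(np.abs(row[defined]), lib_arr[defined])
        magnitude = np.maximum(resid, 0.0)
        out[i, defined] = magnitude * np.sign(row[defined])
    if n_skipped:
        logger.info(
            "normalize_scores: %d PAS with < %d defined scores left undefined",
            n_skipped, min_samples,
        )
    normalized = pd.DataFrame(out, index=score_df.index, columns=score_df.columns)
    return PasScoreMatrix(score=score_df, normalized_score=normalized)
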