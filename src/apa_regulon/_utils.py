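"""Small shared helpers: FDR adjustment and seeded child generators."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs pass through as NaN."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.sum() > 0:
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic child generator for a named sub-stream of one global seed.

    str.__hash__ is salted per process, so the stream name is folded into a
    stable integer digest instead.
    """
    digest = sum((i + 1) * b for i, b in enumerate(stream.encode())) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([seed, digest]))
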