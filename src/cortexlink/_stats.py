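"""Small statistical helpers shared across pipeline stages."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values.

    NaN entries (untestable hypotheses) are passed through as NaN and do not
    count toward the number of hypotheses.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def pearson_r(x, y) -> float:
    """Pearson correlation of two 1-d arrays (plain np.corrcoef, NaN-safe shape)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def zscore_columns(X, ddof: int = 1) -> np.ndarray:
    """Column z-scores. Columns with zero variance raise ValueError."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        bad = list(np.flatnonzero(sd == 0))
        raise ValueError(f"zero-variance columns at positions {bad}")
    return (X - mu) / sd
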