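"""Guilt-by-association co-expression screen.

Pearson correlation of every gene against a focal gene across a sample
panel, with the t-transform p-value (n-2 df). Hits must jointly satisfy
|r| >= r_min and p < p_max. Correlations are computed on
log10(abundance + 0.01) by default; the raw scale is available.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from aerlnc.models import ExpressionPanel
from aerlnc.subtype_signature import LOG10_PSEUDO

R_MIN = 0.7
P_MAX = 0.001


def pearson_screen(
    panel: ExpressionPanel,
    focal: str,
    r_min: float = R_MIN,
    p_max: float = P_MAX,
    log_transform: bool = True,
    pseudo: float = LOG10_PSEUDO,
) -> pd.DataFrame:
    """Genes co-expressed (or anti-co-expressed) with the focal gene.

    Returns the hits (focal gene excluded) with columns r, p_value and
    direction, sorted by |r| descending. Constant genes are skipped
    with a warning; a constant focal gene is an error.
    """
    n = panel.n_samples
    if n < 4:
        raise ValueError("at least 4 samples are required")
    if focal not in panel.gene_ids:
        raise ValueError(f"focal gene {focal!r} not in panel")

    X = panel.values.to_numpy(dtype=float)
    if log_transform:
        X = np.log10(X + pseudo)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.sum(Xc**2, axis=1))
    constant = np.ptp(X, axis=1) == 0  # exact-range test, robust to fp residue
    norms[constant] = 0.0

    fi = panel.gene_ids.get_loc(focal)
    if constant[fi]:
        raise ValueError(f"focal gene {focal!r} is constant")
    if constant.any() and constant.sum() > (1 if constant[fi] else 0):
        warnings.warn(f"{int(constant.sum())} constant gene(s) skipped (r undefined)")

    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ Xc[fi]) / (norms * norms[fi])
    r = np.clip(r, -1.0, 1.0)
    r2 = np.minimum(r**2, 1.0 - 1e-15)
    t = r * np.sqrt((n - 2) / (1.0 - r2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)

    keep = (~constant) & (np.abs(r) >= r_min) & (p < p_max)
    keep[fi] = False
    hits = pd.DataFrame(
        {
            "r": r[keep],
            "p_value": p[keep],
            "direction": np.where(r[keep] >= 0, "correlated", "anti_correlated"),
        },
        index=panel.gene_ids[keep],
    )
    return hits.iloc[np.argsort(-np.abs(hits["r"].to_numpy()), kind="stable")]
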