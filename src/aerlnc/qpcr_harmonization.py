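"""Two-run qRT-PCR harmonization and group testing.

The two runs are merged by a rank/log/bootstrap regression: both series
are log-transformed, their order statistics paired through quantiles
(type-7 interpolation), and a least-squares line of run-2 quantiles on
run-1 quantiles is fit — its intercept/slope estimate the location and
scale of the run-2 batch effect. A 200-iteration bootstrap selects the
refit with the smallest out-of-bag mean square error, and series 2 is
adjusted onto the location/scale of series 1 by inverting the fitted
line and back-transforming. Group differences are assessed by the
two-sided Wilcoxon rank-sum test, with Shapiro-Wilk normality checks
per group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from aerlnc.models import CtSeries

N_BOOT = 200


@dataclass
class HarmonizationModel:
    """Estimated run-2 batch transform, fitted on log-quantiles.

    ``alpha_hat``/``beta_hat`` are the intercept and slope of
    log(series2-quantile) = alpha + beta * log(series1-quantile); the
    adjustment inverts this line.
    """

    alpha_hat: float
    beta_hat: float
    boot_mse: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.boot_mse < 0:
            raise ValueError("boot_mse must be >= 0")


def delta_ct(series: CtSeries, convention: str = "ratio") -> pd.Series:
    """Per-sample expression summary from target and reference Ct.

    ``convention='ratio'`` (default) is reference_ct / target_ct;
    ``'power'`` is 2^(reference_ct - target_ct). Under both, a lower
    target Ct (more transcript) gives a larger value.
    """
    if convention not in ("ratio", "power"):
        raise ValueError("convention must be 'ratio' or 'power'")
    target = series.table["target_ct"].astype(float)
    reference = series.table["reference_ct"].astype(float)
    if (target == 0).any():
        raise ValueError("target_ct of 0 is invalid")
    if convention == "ratio":
        out = reference / target
    else:
        out = 2.0 ** (reference - target)
    out.name = f"delta_ct_{convention}"
    out.attrs["convention"] = convention
    return out


def harmonize_runs(
    series1,
    series2,
    n_boot: int = N_BOOT,
    seed: int = 0,
    select: str = "min_oob_mse",
) -> tuple[HarmonizationModel, np.ndarray]:
    """Adjust run-2 values onto the location/scale of run 1.

    Both series (positive expression values) are log-transformed; the
    sorted run-2 values are paired with the type-7 quantiles of run 1 at
    the run-2 plotting positions; a least-squares line y = a + b*x of
    run-2 quantiles (y) on run-1 quantiles (x) is fit by geometric-mean
    (standardized major axis) regression — both axes are order
    statistics with sampling noise of the same relative size, so the
    sd-ratio slope avoids the attenuation an ordinary regression would
    suffer — estimating the run-2 batch location/scale. ``n_boot``
    bootstrap resamples of the
    paired quantiles are refit and, with ``select='min_oob_mse'``
    (default), the refit with the smallest out-of-bag MSE is retained;
    ``select='average'`` averages the bootstrap coefficients instead.
    Adjusted values are exp((log(series2) - a) / b), a monotone
    transform preserving run-2 rank order exactly.
    """
    s1 = np.asarray(series1, dtype=float)
    s2 = np.asarray(series2, dtype=float)
    for name, s in (("series1", s1), ("series2", s2)):
        if len(s) < 5:
            raise ValueError(f"{name} has fewer than 5 values")
        if np.any(s <= 0):
            raise ValueError(f"{name} contains non-positive values (log undefined)")
    if select not in ("min_oob_mse", "average"):
        raise ValueError("select must be 'min_oob_mse' or 'average'")

    l1 = np.log(s1)
    l2 = np.log(s2)
    m = len(l2)
    levels = np.arange(m) / (m - 1)
    y = np.sort(l2)
    x = np.quantile(l1, levels, method="linear")

    def _fit_line(xv: np.ndarray, yv: np.ndarray) -> tuple[float, float]:
        # geometric-mean regression: slope = sign(cov) * sd(y)/sd(x)
        xm, ym = xv.mean(), yv.mean()
        sx = xv.std(ddof=1)
        sy = yv.std(ddof=1)
        if sx == 0 or sy == 0:
            return float(ym - xm), 1.0  # pure location shift
        sgn = np.sign(np.sum((xv - xm) * (yv - ym))) or 1.0
        b = float(sgn * sy / sx)
        return float(ym - b * xm), b

    a_full, b_full = _fit_line(x, y)
    rng = np.random.default_rng(seed)
    best = (np.inf, a_full, b_full)
    coefs = []
    for _ in range(n_boot):
        idx = rng.integers(0, m, size=m)
        oob = np.setdiff1d(np.arange(m), idx)
        a_b, b_b = _fit_line(x[idx], y[idx])
        coefs.append((a_b, b_b))
        if oob.size == 0:
            continue
        resid = y[oob] - (a_b + b_b * x[oob])
        mse = float(np.mean(resid**2))
        if mse < best[0]:
            best = (mse, a_b, b_b)
    if select == "average":
        a_hat = float(np.mean([c[0] for c in coefs]))
        b_hat = float(np.mean([c[1] for c in coefs]))
        resid = y - (a_hat + b_hat * x)
        mse_hat = float(np.mean(resid**2))
    else:
        mse_hat, a_hat, b_hat = best
        if not np.isfinite(mse_hat):  # every resample covered all points
            resid = y - (a_full + b_full * x)
            mse_hat, a_hat, b_hat = float(np.mean(resid**2)), a_full, b_full

    if b_hat <= 0:
        raise ValueError(f"fitted batch scale is non-positive (beta_hat={b_hat:.3g})")
    model = HarmonizationModel(a_hat, b_hat, mse_hat, n_boot, seed)
    adjusted = np.exp((l2 - a_hat) / b_hat)
    return model, adjusted


def group_difference(
    values,
    groups,
) -> tuple[float, dict[str, float]]:
    """Two-sided rank-sum p for a two-group comparison, with per-group
    Shapiro-Wilk normality p-values reported alongside."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = [g for g in pd.unique(groups)]
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups, got {names}")
    g1 = values[groups == names[0]]
    g2 = values[groups == names[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both groups must be non-empty")
    p = float(stats.mannwhitneyu(g1, g2, alternative="two-sided").pvalue)
    shapiro = {}
    for name, g in zip(names, (g1, g2)):
        if len(g) < 3 or np.ptp(g) == 0:
            shapiro[str(name)] = float("nan")
        else:
            shapiro[str(name)] = float(stats.shapiro(g).pvalue)
    return p, shapiro
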