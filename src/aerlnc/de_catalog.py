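"""Differential-expression catalog construction.

A minimal negative-binomial Wald test (median-of-ratios normalization,
method-of-moments dispersion), a consensus operator that integrates DE
calls from several algorithms with sign concordance, the catalog
filters (lncRNA biotypes, 200 bp length threshold, blacklist of
discordant annotations), RPKM conversion from normalized counts, and
Fisher combination of per-time-point p-values.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from aerlnc.models import CountMatrix, GeneModel, LNCRNA_BIOTYPES

#: dispersion floor for the method-of-moments estimate
DISPERSION_FLOOR = 1e-8
#: pseudo-count used for fold changes of low/zero-count genes
PSEUDOCOUNT = 0.5
#: prior degrees of freedom for empirical-Bayes dispersion moderation
PRIOR_DF = 20.0


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes with all-positive counts."""
    pos = counts[(counts > 0).all(axis=1)]
    if pos.empty:
        raise ValueError("no gene has positive counts in every sample")
    log_geo = np.log(pos).mean(axis=1)
    ratios = np.log(pos).sub(log_geo, axis=0)
    return np.exp(ratios.median(axis=0))


def de_test(
    counts: CountMatrix,
    alpha: float = 0.05,
    method_id: str = "nb_wald",
    prior_df: float = PRIOR_DF,
) -> pd.DataFrame:
    """Per-gene negative-binomial Wald test between two conditions.

    Counts are normalized by median-of-ratios size factors. The
    per-gene dispersion is a method-of-moments estimate pooled across
    conditions (floored at 1e-8) and then moderated empirical-Bayes
    style: shrunk toward the across-genes median dispersion with
    ``prior_df`` pseudo-observations against the n1+n2-2 residual df,
    which stabilizes the estimate at small replicate numbers. The Wald
    statistic on the log2 ratio of normalized condition means
    (pseudo-count 0.5) is referred to a t distribution with
    residual + prior df, and p-values are BH-adjusted. All-zero genes
    get p=1 and lfc=0.
    """
    conds = counts.conditions
    if len(conds) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {conds}")
    groups = [counts.samples_of(c) for c in conds]
    for c, g in zip(conds, groups):
        if len(g) < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 samples")

    sf = size_factors(counts.counts)
    norm = counts.counts / sf

    means = []
    phis = []
    for g in groups:
        sub = norm[g]
        m = sub.mean(axis=1).to_numpy()
        v = sub.var(axis=1, ddof=1).to_numpy()
        means.append(m)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (v - m) / np.square(m)
        phi[~np.isfinite(phi)] = DISPERSION_FLOOR
        phis.append(phi)
    m1, m2 = means
    phi = np.maximum((phis[0] + phis[1]) / 2.0, DISPERSION_FLOOR)
    n1, n2 = len(groups[0]), len(groups[1])
    resid_df = n1 + n2 - 2
    informative = phi > DISPERSION_FLOOR
    trend = float(np.median(phi[informative])) if informative.any() else DISPERSION_FLOOR
    phi = np.maximum(
        (resid_df * phi + prior_df * trend) / (resid_df + prior_df), DISPERSION_FLOOR
    )

    a1, a2 = m1 + PSEUDOCOUNT, m2 + PSEUDOCOUNT
    lfc = np.log2(a2 / a1)
    # Var(log mean) ~= (mu + phi mu^2) / (n mu^2) per condition
    var_log = (a1 + phi * a1**2) / (n1 * a1**2) + (a2 + phi * a2**2) / (n2 * a2**2)
    se_lfc = np.sqrt(var_log) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = lfc / se_lfc
    p = 2.0 * stats.t.sf(np.abs(wald), resid_df + prior_df)

    all_zero = (counts.counts.sum(axis=1) == 0).to_numpy()
    lfc[all_zero] = 0.0
    p[all_zero] = 1.0
    p = np.clip(p, 0.0, 1.0)
    adj = multipletests(p, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "base_mean_" + conds[0]: m1,
            "base_mean_" + conds[1]: m2,
            "log2_fc": lfc,
            "p_value": p,
            "adj_p": np.maximum(adj, p),
            "method_id": method_id,
        },
        index=counts.gene_ids,
    )


def consensus_de(
    results: Sequence[pd.DataFrame],
    alpha: float = 0.05,
    min_methods: Optional[int] = None,
) -> pd.DataFrame:
    """Integrate DE tables from several algorithms into one call set.

    A gene enters the consensus iff adj_p < alpha in at least
    ``min_methods`` tables (default: all provided) and the sign of its
    log2 fold change agrees across every supporting table.
    """
    if len(results) == 0:
        raise ValueError("at least one DE table is required")
    if min_methods is None:
        min_methods = len(results)
    if not (1 <= min_methods <= len(results)):
        raise ValueError("min_methods out of range")

    universe = results[0].index
    for t in results[1:]:
        if not universe.equals(t.index):
            raise ValueError("DE tables must share the gene universe")

    sig = np.column_stack([ (t["adj_p"] < alpha).to_numpy() for t in results ])
    signs = np.column_stack([ np.sign(t["log2_fc"]).to_numpy() for t in results ])

    n_support = sig.sum(axis=1)
    rows = []
    for i, gid in enumerate(universe):
        if n_support[i] < min_methods:
            continue
        s = signs[i, sig[i]]
        if len(np.unique(s)) != 1 or s[0] == 0:
            continue
        rows.append(
            {
                "gene_id": gid,
                "direction": "up" if s[0] > 0 else "down",
                "n_methods_supporting": int(n_support[i]),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "direction", "n_methods_supporting"]).set_index(
        "gene_id"
    )


def filter_lncrnas(
    genes: Iterable[str],
    annotation: Mapping[str, GeneModel],
    min_length_bp: int = 200,
    blacklist: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Apply the catalog filters to a gene set.

    Keeps genes with an lncRNA biotype (antisense, lincRNA,
    processed_transcript, sense_intronic, sense_overlapping), a longest
    transcript of at least ``min_length_bp``, and not on the blacklist
    of discordant annotations. Returns one row per input gene with a
    ``keep`` flag and the comma-joined names of the filters it failed.
    """
    blacklist = set(blacklist or ())
    rows = []
    for gid in genes:
        if gid not in annotation:
            raise ValueError(f"gene id absent from annotation: {gid}")
        g = annotation[gid]
        flags = []
        if g.biotype not in LNCRNA_BIOTYPES:
            flags.append("biotype")
        if max(g.transcript_lengths) < min_length_bp:
            flags.append("length")
        if gid in blacklist:
            flags.append("blacklist")
        rows.append(
            {
                "gene_id": gid,
                "biotype": g.biotype,
                "keep": not flags,
                "filter_flags": ",".join(flags),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "biotype", "keep", "filter_flags"]).set_index(
        "gene_id"
    )


def compute_rpkm(norm_count, longest_isoform_kb, million_reads):
    """RPKM = normalized reads / (longest isoform length in kb x million mapped reads)."""
    norm_count = np.asarray(norm_count, dtype=float)
    longest_isoform_kb = np.asarray(longest_isoform_kb, dtype=float)
    million_reads = np.asarray(million_reads, dtype=float)
    if np.any(norm_count < 0):
        raise ValueError("normalized counts must be >= 0")
    if np.any(longest_isoform_kb <= 0) or np.any(million_reads <= 0):
        raise ValueError("isoform length and million reads must be > 0")
    out = norm_count / (longest_isoform_kb * million_reads)
    return out if out.ndim else float(out)


def combine_timepoints(
    per_timepoint: Sequence[pd.DataFrame], alpha: float = 0.05
) -> pd.DataFrame:
    """Combine per-time-point DE tables into per-gene calls.

    A gene is called DE iff its minimum p-value over time points is
    below ``alpha``; the reported fold change is the arithmetic mean of
    the per-time-point log2 fold changes, and the combined p-value is
    Fisher's: X = -2 sum(ln p_i) ~ chi2(2k). Zero p-values are clamped
    at 1e-300 with a warning.
    """
    if len(per_timepoint) == 0:
        raise ValueError("at least one time-point table is required")
    universe = per_timepoint[0].index
    for t in per_timepoint[1:]:
        if not universe.equals(t.index):
            raise ValueError("time-point tables must share the gene universe")

    pmat = np.column_stack([t["p_value"].to_numpy(dtype=float) for t in per_timepoint])
    if np.any(pmat == 0):
        warnings.warn("zero p-value(s) clamped to 1e-300 before Fisher combination")
        pmat = np.maximum(pmat, 1e-300)
    lfc = np.column_stack([t["log2_fc"].to_numpy(dtype=float) for t in per_timepoint])

    k = pmat.shape[1]
    x = -2.0 * np.log(pmat).sum(axis=1)
    combined = stats.chi2.sf(x, 2 * k)
    return pd.DataFrame(
        {
            "de": pmat.min(axis=1) < alpha,
            "mean_log2_fc": lfc.mean(axis=1),
            "min_p": pmat.min(axis=1),
            "combined_p": combined,
        },
        index=universe,
    )
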