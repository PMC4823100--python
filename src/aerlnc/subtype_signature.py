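"""Luminal-signature selection and evaluation.

Features (genes) are ranked by cross-validated chi-squared merit: on
each training fold, every gene is discretized into equal-frequency bins
and its contingency with the subtype labels summarised by the
chi-squared statistic; the merit is the mean over folds. The signature
(merit above a threshold) is evaluated by cross-validated MLP
classification, Ward (Ward.D2) hierarchical clustering, and PCA.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from aerlnc.models import ExpressionPanel

MERIT_THRESHOLD = 15.0
LOG10_PSEUDO = 0.01


def zscore(panel: ExpressionPanel) -> ExpressionPanel:
    """Per-gene z-scores across samples (sample sd, ddof=1).

    A constant gene maps to all zeros, with a warning.
    """
    vals = panel.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(f"{constant.sum()} constant gene(s) z-scored to zeros")
    sd[sd == 0] = 1.0
    z = (vals - mean) / sd
    out = pd.DataFrame(z, index=panel.values.index, columns=panel.values.columns)
    return ExpressionPanel(out, dict(panel.subtype), None if panel.receptor_status is None else dict(panel.receptor_status))


def discretize(values: np.ndarray, n_bins: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Equal-frequency binning of one feature on training data.

    Provisional bins come from stable ranks (ties broken by value order
    then sample order); the cut-points are the upper-edge values of
    bins 0..n_bins-2 and final bins are assigned through them, so tied
    values always share a bin (a fully tied feature collapses to one
    bin and carries no association). Returns (bin labels, cut-points);
    held-out samples map through :func:`apply_bins` (a value below
    every cut-point maps to bin 0).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    rank_bins = (np.arange(n) * n_bins) // n
    edges = [np.max(np.where(rank_bins == k)) for k in range(n_bins - 1) if np.any(rank_bins == k)]
    cuts = sorted_vals[edges]
    return apply_bins(cuts, values), cuts


def apply_bins(cuts: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Map held-out values onto training cut-points."""
    return np.searchsorted(cuts, np.asarray(values, dtype=float), side="left")


def _fold_chi2(binned: np.ndarray, y: np.ndarray, n_bins: int, n_classes: int) -> np.ndarray:
    """Chi-squared statistic per gene from pre-binned training data.

    ``binned`` is genes x samples of bin labels; empty rows/columns of
    each contingency table contribute nothing (their expected counts are
    restricted to non-empty margins).
    """
    n_genes, n_samples = binned.shape
    table = np.zeros((n_genes, n_bins, n_classes))
    gene_idx = np.repeat(np.arange(n_genes), n_samples)
    np.add.at(table, (gene_idx, binned.ravel(), np.tile(y, n_genes)), 1.0)
    row = table.sum(axis=2, keepdims=True)
    col = table.sum(axis=1, keepdims=True)
    n = float(n_samples)
    expected = row * col / n
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.square(table - expected) / expected
    contrib[expected == 0] = 0.0
    return contrib.sum(axis=(1, 2))


def chi2_merit(
    panel: ExpressionPanel,
    labels: Optional[pd.Series] = None,
    folds: int = 10,
    seed: int = 0,
    n_bins: int = 4,
) -> pd.DataFrame:
    """Cross-validated chi-squared merit of every gene.

    On each stratified training fold (9/10 of samples for ten folds),
    genes are discretized into equal-frequency bins on the training
    samples only and the chi-squared of the bin x class contingency is
    computed; the merit is the mean over folds. Deterministic given the
    seed (which fixes the fold partition).
    """
    labels = panel.subtype if labels is None else labels
    y_raw = labels.loc[panel.sample_ids].to_numpy()
    classes, y = np.unique(y_raw, return_inverse=True)
    class_counts = np.bincount(y)
    if class_counts.min() < folds:
        small = classes[np.argmin(class_counts)]
        raise ValueError(
            f"class {small!r} has {class_counts.min()} samples, fewer than {folds} folds; "
            "use fewer folds"
        )
    vals = panel.values.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold = np.zeros((vals.shape[0], folds))
    for f, (train, _test) in enumerate(skf.split(vals.T, y)):
        sub = vals[:, train]
        n_tr = len(train)
        sorted_vals = np.sort(sub, axis=1)
        rank_bins = (np.arange(n_tr) * n_bins) // n_tr
        edges = [np.max(np.where(rank_bins == k)) for k in range(n_bins - 1) if np.any(rank_bins == k)]
        cuts = sorted_vals[:, edges]  # genes x (n_bins-1) upper edges
        binned = (sub[:, :, None] > cuts[:, None, :]).sum(axis=2)
        per_fold[:, f] = _fold_chi2(binned, y[train], n_bins, len(classes))
    merit = per_fold.mean(axis=1)
    out = pd.DataFrame(
        {f"fold_{f + 1}": per_fold[:, f] for f in range(folds)},
        index=panel.values.index,
    )
    out.insert(0, "merit", merit)
    out["rank"] = (
        pd.Series(-merit, index=out.index).rank(method="first").astype(int)
    )
    return out


def select_signature(merit_table: pd.DataFrame, threshold: float = MERIT_THRESHOLD) -> list[str]:
    """Genes with merit strictly above the threshold, best first.

    Ties in merit are broken by gene id.
    """
    passing = merit_table[merit_table["merit"] > threshold]
    order = np.lexsort((passing.index.to_numpy(), -passing["merit"].to_numpy()))
    return list(passing.index[order])


def crossval_classify(
    panel: ExpressionPanel,
    labels: Optional[pd.Series] = None,
    folds: int = 10,
    seed: int = 0,
    hidden_units: Optional[int] = None,
    max_iter: int = 500,
    log_transform: bool = True,
) -> tuple[float, pd.DataFrame]:
    """Cross-validated accuracy of a single-hidden-layer MLP.

    Abundance features are log10(x + 0.01)-transformed by default
    (disable for panels already on a symmetric scale, e.g. z-scores)
    and then z-scored on the training fold; accuracy is pooled
    correct/total over the held-out folds; the confusion matrix is
    (true x predicted). All randomness derives from the seed.
    """
    labels = panel.subtype if labels is None else labels
    y_raw = labels.loc[panel.sample_ids].to_numpy()
    classes, y = np.unique(y_raw, return_inverse=True)
    X = panel.values.to_numpy(dtype=float).T  # samples x genes
    if not np.all(np.isfinite(X)):
        raise ValueError("panel contains non-finite feature values")
    if log_transform:
        if np.any(X <= -LOG10_PSEUDO):
            raise ValueError("log transform requires values > -0.01; pass log_transform=False")
        X = np.log10(X + LOG10_PSEUDO)
    if hidden_units is None:
        hidden_units = math.ceil((X.shape[1] + len(classes)) / 2)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for f, (train, test) in enumerate(skf.split(X, y)):
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xtr = (X[train] - mu) / sd
        Xte = (X[test] - mu) / sd
        clf = MLPClassifier(
            hidden_layer_sizes=(hidden_units,),
            solver="lbfgs",
            max_iter=max_iter,
            random_state=seed * 1000 + f,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xtr, y[train])
        pred = clf.predict(Xte)
        for t, p in zip(y[test], pred):
            confusion[t, p] += 1
    accuracy = float(np.trace(confusion) / confusion.sum())
    cm = pd.DataFrame(confusion, index=classes, columns=classes)
    return accuracy, cm


def cluster_purity(assignment: np.ndarray, labels: np.ndarray) -> float:
    """Purity: sum over clusters of the majority-class count, over N."""
    assignment = np.asarray(assignment)
    labels = np.asarray(labels)
    total = 0
    for c in np.unique(assignment):
        members = labels[assignment == c]
        _vals, counts = np.unique(members, return_counts=True)
        total += counts.max()
    return float(total / len(labels))


def hierarchical_cluster(
    panel: ExpressionPanel,
    genes: Optional[Sequence[str]] = None,
    k: int = 4,
    pseudo: float = LOG10_PSEUDO,
    log_transform: bool = True,
) -> tuple[np.ndarray, pd.Series, float]:
    """Ward (Ward.D2) clustering of samples on log10 abundances.

    Values are log10(x + pseudo) transformed, samples compared by
    Euclidean distance and agglomerated with the squared-distance
    Lance-Williams update (heights on the distance scale, i.e. scipy's
    ``ward`` = R's Ward.D2). Returns (linkage matrix, cluster
    assignment, purity against the subtype labels).
    """
    vals = panel.values if genes is None else panel.values.loc[list(genes)]
    X = vals.to_numpy(dtype=float).T
    if log_transform:
        X = np.log10(X + pseudo)
    Z = linkage(X, method="ward")
    assign = fcluster(Z, t=k, criterion="maxclust")
    purity = cluster_purity(assign, panel.subtype.to_numpy())
    return Z, pd.Series(assign, index=panel.sample_ids, name="cluster"), purity


def pca(
    panel: ExpressionPanel, genes: Optional[Sequence[str]] = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """SVD-based PCA of samples on (per-gene centered) expression.

    Returns (sample scores, explained-variance ratios summing to 1).
    Sign convention: the largest-magnitude loading of each component is
    positive.
    """
    vals = panel.values if genes is None else panel.values.loc[list(genes)]
    X = vals.to_numpy(dtype=float).T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    scores = u * s
    with np.errstate(invalid="ignore", divide="ignore"):
        evr = s**2 / np.sum(s**2) if np.sum(s**2) > 0 else np.zeros_like(s)
    cols = [f"PC{j + 1}" for j in range(scores.shape[1])]
    return pd.DataFrame(scores, index=panel.sample_ids, columns=cols), evr
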