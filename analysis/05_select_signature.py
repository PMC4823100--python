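#!/usr/bin/env python
"""Select the luminal signature and evaluate it as a classifier.

Ranks the catalog genes by ten-fold cross-validated chi-squared merit
against the subtype labels of the 55-sample panel, keeps genes with
merit > 15, and evaluates the signature by cross-validated MLP
classification, Ward.D2 clustering purity, and PCA. Writes the merit
table, signature list, confusion matrix and cluster assignment.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from aerlnc import io_formats
from aerlnc.models import ExpressionPanel
from aerlnc.subtype_signature import (
    chi2_merit,
    crossval_classify,
    hierarchical_cluster,
    pca,
    select_signature,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    inputs = args.results / "inputs"

    panel = io_formats.read_expression_panel(inputs / "panel.tsv", inputs / "panel_labels.tsv")
    catalog = pd.read_csv(args.results / "catalog.tsv", sep="\t", comment="#", index_col=0)
    genes = [g for g in catalog.index if g in panel.gene_ids]
    merit_panel = ExpressionPanel(panel.values.loc[genes], dict(panel.subtype))

    merit = chi2_merit(merit_panel, folds=10, seed=args.seed)
    signature = select_signature(merit, threshold=15.0)
    io_formats.write_table(merit.rename_axis("gene_id"), args.results / "merit_table.tsv",
                           seed=args.seed)
    (args.results / "signature.txt").write_text("\n".join(signature) + "\n")
    print(f"{len(signature)} of {len(genes)} catalog genes exceed merit 15")

    truth = json.loads((inputs / "truth.json").read_text())
    planted = {r["gene_id"] for r in truth["signature"]}
    in_top = len(planted & set(merit.sort_values("rank").index[: len(planted)]))
    print(f"{in_top}/{len(planted)} planted signature genes rank in the top {len(planted)} by merit")

    sig_panel = ExpressionPanel(panel.values.loc[signature], dict(panel.subtype))
    accuracy, confusion = crossval_classify(sig_panel, folds=10, seed=args.seed)
    io_formats.write_table(confusion, args.results / "confusion_matrix.tsv", seed=args.seed)
    print(f"10-fold MLP accuracy with the signature: {100 * accuracy:.2f}%")

    _Z, assignment, purity = hierarchical_cluster(panel, signature, k=4)
    io_formats.write_table(assignment.to_frame(), args.results / "cluster_assignment.tsv",
                           seed=args.seed)
    scores, evr = pca(panel, signature)
    io_formats.write_table(scores.iloc[:, :2], args.results / "pca_scores.tsv", seed=args.seed)
    print(f"Ward.D2 purity at k=4: {purity:.3f}; PC1 explains {100 * evr[0]:.1f}% of variance")


if __name__ == "__main__":
    main()
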