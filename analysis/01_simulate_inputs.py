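#!/usr/bin/env python
"""Generate every synthetic input of the study and record ground truth.

Writes the gene annotation (GTF), binding-site peaks (BED), knockdown
count matrix with its design, the 55-sample subtype expression panel,
and the two qRT-PCR runs under results/inputs/, plus truth.json naming
everything that was planted.
"""

import argparse
from pathlib import Path

from aerlnc import io_formats
from aerlnc.synthetic_data import (
    SimulationConfig,
    gen_annotation,
    gen_binding_sites,
    gen_counts,
    gen_ct,
    gen_panel,
    write_truth,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    out = args.results / "inputs"
    out.mkdir(parents=True, exist_ok=True)

    annotation = gen_annotation(cfg)
    counts, de_truth = gen_counts(annotation, cfg)
    sites, site_truth = gen_binding_sites(annotation, de_truth["gene_id"], cfg)
    panel, sig_truth = gen_panel(annotation, cfg, signature_genes=de_truth["gene_id"])
    ct1, ct2, ct_truth = gen_ct(cfg)

    io_formats.write_gtf(annotation, out / "annotation.gtf", seed=args.seed)
    io_formats.write_bed(sites, out / "binding_sites.bed", seed=args.seed)
    io_formats.write_count_table(counts, out / "counts.tsv", seed=args.seed)
    io_formats.write_design(counts, out / "design.tsv")
    io_formats.write_expression_panel(panel, out / "panel.tsv", out / "panel_labels.tsv",
                                      seed=args.seed)
    io_formats.write_ct_table(ct1, out / "ct_run1.tsv", seed=args.seed)
    io_formats.write_ct_table(ct2, out / "ct_run2.tsv", seed=args.seed)
    write_truth({"de": de_truth, "sites": site_truth, "signature": sig_truth,
                 "ct": ct_truth, "seed": args.seed}, out / "truth.json")

    n_lnc = sum(g.is_lncrna for g in annotation.values())
    print(f"simulated {len(annotation)} genes ({n_lnc} lncRNAs) on {cfg.n_chromosomes} chromosomes")
    print(f"planted {len(de_truth)} regulated lncRNAs "
          f"({(de_truth['direction'] == 'down').sum()} down / "
          f"{(de_truth['direction'] == 'up').sum()} up), "
          f"{len(sites)} binding sites, {cfg.signature_size}-gene luminal signature")
    print(f"qRT-PCR runs of {cfg.run_sizes[0]} and {cfg.run_sizes[1]} samples "
          f"with batch effect (a, b) = {cfg.ct_shift}")
    print(f"inputs written to {out}")


if __name__ == "__main__":
    main()
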