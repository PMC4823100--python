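"""End-to-end orchestration of the analysis stages on synthetic data.

`run_demo` wires every stage together: simulate inputs, build the DE
catalog, test TSS-to-binding-site distance enrichment, profile ChIP
signal at catalog TSSs, select and evaluate the luminal signature,
screen co-expression, and harmonize the two qRT-PCR runs. Every output
is a provenance-headed TSV (or JSON) and the run closes with a manifest
of output checksums, so that identical config + seed reproduces
identical bytes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from aerlnc import __version__, io_formats
from aerlnc.cis_regulation import (
    DISTANCE_CAP,
    distance_enrichment_test,
    matched_random_sets,
    nearest_site_distance,
    bin_signal,
    promoter_enhancer_call,
)
from aerlnc.coexpression import P_MAX, R_MIN, pearson_screen
from aerlnc.de_catalog import (
    compute_rpkm,
    consensus_de,
    de_test,
    filter_lncrnas,
    size_factors,
)
from aerlnc.models import BindingSiteSet, CountMatrix, ExpressionPanel, GeneModel, GenomicInterval
from aerlnc.qpcr_harmonization import N_BOOT, delta_ct, group_difference, harmonize_runs
from aerlnc.subtype_signature import (
    MERIT_THRESHOLD,
    chi2_merit,
    crossval_classify,
    hierarchical_cluster,
    pca,
    select_signature,
)
from aerlnc.synthetic_data import (
    SimulationConfig,
    gen_annotation,
    gen_binding_sites,
    gen_chip_tags,
    gen_coexpression_panel,
    gen_counts,
    gen_ct,
    gen_panel,
    write_truth,
)


@dataclass
class RunConfig:
    """Stage parameters for a pipeline run (defaults = study settings)."""

    seed: int = 1
    alpha: float = 0.05
    min_methods: Optional[int] = None
    cap: int = DISTANCE_CAP
    domain_window: int = 100_000
    n_sets: int = 1000
    half_window: int = 1000
    bin_size: int = 50
    extension: int = 200
    tags_per_region: int = 500
    folds: int = 10
    merit_threshold: float = MERIT_THRESHOLD
    k_clusters: int = 4
    r_min: float = R_MIN
    p_max: float = P_MAX
    n_boot: int = N_BOOT
    ct_convention: str = "ratio"

    def __post_init__(self) -> None:
        if self.n_sets <= 0:
            raise ValueError("n_sets must be > 0")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.cap <= 0 or self.half_window <= 0 or self.bin_size <= 0:
            raise ValueError("cap, half_window and bin_size must be > 0")
        if self.extension < 0 or self.n_boot < 1:
            raise ValueError("extension must be >= 0 and n_boot >= 1")
        if not (0 < self.r_min <= 1) or not (0 < self.p_max < 1):
            raise ValueError("r_min must be in (0, 1] and p_max in (0, 1)")
        if self.ct_convention not in ("ratio", "power"):
            raise ValueError("ct_convention must be 'ratio' or 'power'")


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a flat key = value config file into a RunConfig."""
    kwargs: dict = {}
    fields = {f: t for f, t in RunConfig.__annotations__.items()}
    with open(path, "rt", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line without '=': {raw.strip()!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"unknown config key: {key!r}")
            default = getattr(RunConfig, key, None)
            if isinstance(default, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int) or key in ("min_methods",):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
    return RunConfig(**kwargs)


def catalog_from_counts(
    counts: CountMatrix,
    annotation: Mapping[str, GeneModel],
    alpha: float = 0.05,
    min_methods: Optional[int] = None,
    blacklist=(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DE test -> consensus -> lncRNA filters -> RPKM.

    Returns (catalog, full DE table). The catalog holds the surviving
    genes with direction, filter flags and per-condition RPKM.
    """
    de = de_test(counts, alpha=alpha)
    consensus = consensus_de([de], alpha=alpha, min_methods=min_methods)
    flags = filter_lncrnas(consensus.index, annotation, blacklist=blacklist)
    kept = flags[flags["keep"]].index

    sf = size_factors(counts.counts)
    norm = counts.counts / sf
    million = counts.million_reads
    conds = counts.conditions
    catalog = consensus.loc[kept].join(flags.loc[kept, ["biotype", "filter_flags"]])
    for cond in conds:
        samples = counts.samples_of(cond)
        mean_norm = norm.loc[kept, samples].mean(axis=1)
        kb = pd.Series({g: annotation[g].longest_isoform_kb for g in kept})
        catalog[f"rpkm_{cond}"] = compute_rpkm(
            mean_norm.to_numpy(), kb.to_numpy(), float(million[samples].mean())
        )
    catalog = catalog.join(de.loc[kept, ["log2_fc", "p_value", "adj_p"]])
    return catalog, de


def distance_stage(
    annotation: Mapping[str, GeneModel],
    sites: BindingSiteSet,
    observed_genes,
    n_sets: int = 1000,
    seed: int = 0,
    cap: int = DISTANCE_CAP,
) -> dict:
    """Observed nearest distances vs biotype-matched resampling null."""
    observed_genes = list(observed_genes)
    pool = {g: m for g, m in annotation.items() if m.is_lncrna}
    all_dist = nearest_site_distance(pool, sites, cap=cap)
    composition: dict[str, int] = {}
    for g in observed_genes:
        composition[annotation[g].biotype] = composition.get(annotation[g].biotype, 0) + 1
    sets = matched_random_sets(pool, composition, n_sets=n_sets, seed=seed, exclude=observed_genes)
    observed = all_dist.loc[observed_genes].to_numpy()
    nulls = [all_dist.loc[s].to_numpy() for s in sets]
    wilcoxon_p, empirical_p = distance_enrichment_test(observed, nulls)
    return {
        "observed": pd.Series(observed, index=observed_genes, name="distance_bp"),
        "wilcoxon_p": wilcoxon_p,
        "empirical_p": empirical_p,
        "n_sets": n_sets,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_demo(
    seed: int = 1,
    outdir: str | Path = "demo_out",
    run_cfg: Optional[RunConfig] = None,
    sim_cfg: Optional[SimulationConfig] = None,
) -> dict:
    """Full synthetic end-to-end run; returns the summary dict.

    Writes every stage output plus ``manifest.json`` (paths, sha256
    checksums, parameters) under ``outdir``.
    """
    run_cfg = run_cfg or RunConfig(seed=seed)
    sim_cfg = sim_cfg or SimulationConfig(seed=seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": seed, "version": __version__}

    # --- simulate inputs -------------------------------------------------
    annotation = gen_annotation(sim_cfg)
    counts, de_truth = gen_counts(annotation, sim_cfg)
    sites, site_truth = gen_binding_sites(annotation, de_truth["gene_id"], sim_cfg)
    # the luminal signature lives within the regulated genes, mirroring
    # the luminal specificity of the knockdown-responsive lncRNAs
    panel, sig_truth = gen_panel(annotation, sim_cfg, signature_genes=de_truth["gene_id"])
    ct1, ct2, ct_truth = gen_ct(sim_cfg)

    io_formats.write_gtf(annotation, out / "annotation.gtf", seed=seed)
    io_formats.write_bed(sites, out / "binding_sites.bed", seed=seed)
    io_formats.write_count_table(counts, out / "counts.tsv", seed=seed)
    io_formats.write_design(counts, out / "design.tsv")
    io_formats.write_expression_panel(panel, out / "panel.tsv", out / "panel_labels.tsv", seed=seed)
    io_formats.write_ct_table(ct1, out / "ct_run1.tsv", seed=seed)
    io_formats.write_ct_table(ct2, out / "ct_run2.tsv", seed=seed)
    write_truth(
        {"de": de_truth, "sites": site_truth, "signature": sig_truth, "ct": ct_truth, "seed": seed},
        out / "truth.json",
    )

    # --- catalog ---------------------------------------------------------
    catalog, de_table = catalog_from_counts(
        counts, annotation, alpha=run_cfg.alpha, min_methods=run_cfg.min_methods
    )
    io_formats.write_table(de_table, out / "de_table.tsv", seed=seed)
    io_formats.write_table(catalog, out / "catalog.tsv", seed=seed)
    summary["n_catalog"] = int(len(catalog))
    summary["n_down"] = int((catalog["direction"] == "down").sum())
    summary["n_up"] = int((catalog["direction"] == "up").sum())
    planted = set(de_truth["gene_id"])
    summary["catalog_recall"] = (
        float(len(planted & set(catalog.index)) / len(planted)) if planted else float("nan")
    )

    # --- distance enrichment (down- and up-regulated separately) ---------
    report_rows = []
    for direction in ("down", "up"):
        genes = catalog.index[catalog["direction"] == direction]
        if len(genes) == 0:
            continue
        res = distance_stage(
            annotation, sites, genes, n_sets=run_cfg.n_sets, seed=seed, cap=run_cfg.cap
        )
        summary[f"distance_wilcoxon_p_{direction}"] = res["wilcoxon_p"]
        summary[f"distance_empirical_p_{direction}"] = res["empirical_p"]
        report_rows.append(
            {
                "direction": direction,
                "n_genes": len(genes),
                "median_distance_bp": float(np.median(res["observed"].replace(np.inf, np.nan).dropna())),
                "wilcoxon_p": res["wilcoxon_p"],
                "empirical_p": res["empirical_p"],
            }
        )
    io_formats.write_table(
        pd.DataFrame(report_rows), out / "distance_report.tsv", seed=seed, index=False
    )

    # --- ChIP signal at catalog TSSs ------------------------------------
    regions = [
        GenomicInterval(annotation[g].chrom, annotation[g].tss - 1, annotation[g].tss, annotation[g].strand)
        for g in catalog.index
    ]
    anchors = [
        (g, annotation[g].chrom, annotation[g].tss - 1, annotation[g].strand) for g in catalog.index
    ]
    if regions:
        tags_a, tags_b = gen_chip_tags(regions, "promoter", run_cfg.tags_per_region, seed=seed)
        sig_a = bin_signal(tags_a, anchors, run_cfg.half_window, run_cfg.bin_size, run_cfg.extension, mark="H3K4me3")
        sig_b = bin_signal(tags_b, anchors, run_cfg.half_window, run_cfg.bin_size, run_cfg.extension, mark="H3K4me1")
        calls = promoter_enhancer_call(sig_a, sig_b)
        io_formats.write_table(sig_a, out / "signal_H3K4me3.tsv", seed=seed)
        io_formats.write_table(sig_b, out / "signal_H3K4me1.tsv", seed=seed)
        io_formats.write_table(calls, out / "promoter_calls.tsv", seed=seed)
        summary["promoter_fraction"] = float((calls["label"] == "promoter_like").mean())

    # --- signature selection and evaluation ------------------------------
    # merit is evaluated over the catalog genes (the regulated lncRNAs),
    # as the study does, not over the whole lncRNA universe
    catalog_in_panel = [g for g in catalog.index if g in panel.gene_ids]
    merit_panel = ExpressionPanel(
        panel.values.loc[catalog_in_panel],
        dict(panel.subtype),
        None if panel.receptor_status is None else dict(panel.receptor_status),
    )
    merit = chi2_merit(merit_panel, folds=run_cfg.folds, seed=seed)
    io_formats.write_table(merit, out / "merit_table.tsv", seed=seed)
    signature = select_signature(merit, threshold=run_cfg.merit_threshold)
    (out / "signature.txt").write_text("\n".join(signature) + "\n")
    summary["n_signature"] = len(signature)
    planted_sig = set(sig_truth["gene_id"])
    top = merit.sort_values("rank").index[: len(planted_sig)]
    summary["signature_recall_topk"] = float(len(planted_sig & set(top)) / len(planted_sig))

    sig_panel = ExpressionPanel(
        panel.values.loc[signature],
        dict(panel.subtype),
        None if panel.receptor_status is None else dict(panel.receptor_status),
    )
    accuracy, confusion = crossval_classify(sig_panel, folds=run_cfg.folds, seed=seed)
    io_formats.write_table(confusion, out / "confusion_matrix.tsv", seed=seed)
    summary["classification_accuracy_pct"] = 100.0 * accuracy

    _Z, assignment, purity = hierarchical_cluster(panel, signature, k=run_cfg.k_clusters)
    io_formats.write_table(assignment.to_frame(), out / "cluster_assignment.tsv", seed=seed)
    summary["clustering_purity"] = purity
    scores, evr = pca(panel, signature)
    io_formats.write_table(scores.iloc[:, :2], out / "pca_scores.tsv", seed=seed)
    summary["pc1_variance_ratio"] = float(evr[0])

    # --- co-expression screen -------------------------------------------
    # guilt-by-association around a focal gene with planted co-regulated
    # partners (the DSCAM-AS1-style screen)
    co_panel, co_truth = gen_coexpression_panel(seed=seed)
    hits = pearson_screen(co_panel, co_truth["focal"], r_min=run_cfg.r_min, p_max=run_cfg.p_max)
    io_formats.write_table(hits, out / "coexpression_hits.tsv", seed=seed)
    summary["focal_gene"] = co_truth["focal"]
    summary["n_coexpressed"] = int(len(hits))
    summary["coexpression_recall"] = float(
        len(set(hits.index) & set(co_truth["correlated"])) / len(co_truth["correlated"])
    )
    summary["coexpression_false_hits"] = int(len(set(hits.index) - set(co_truth["correlated"])))

    # --- qRT-PCR harmonization ------------------------------------------
    v1 = delta_ct(ct1, convention=run_cfg.ct_convention)
    v2 = delta_ct(ct2, convention=run_cfg.ct_convention)
    model, adjusted = harmonize_runs(v1.to_numpy(), v2.to_numpy(), n_boot=run_cfg.n_boot, seed=seed)
    merged = np.concatenate([v1.to_numpy(), adjusted])
    groups = np.concatenate([ct1.groups.to_numpy(), ct2.groups.to_numpy()])
    wil_p, shapiro = group_difference(merged, groups)
    harmonized = pd.DataFrame(
        {
            "value": merged,
            "run_id": [1] * len(v1) + [2] * len(v2),
            "group": groups,
        },
        index=list(v1.index) + list(v2.index),
    )
    io_formats.write_table(harmonized.rename_axis("sample_id"), out / "qpcr_harmonized.tsv", seed=seed)
    summary["harmonization_alpha"] = model.alpha_hat
    summary["harmonization_beta"] = model.beta_hat
    summary["qpcr_group_p"] = wil_p
    summary["shapiro_p"] = shapiro

    # --- manifest --------------------------------------------------------
    with open(out / "summary.json", "wt", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    artifacts = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": seed,
        "parameters": asdict(run_cfg),
        "outputs": {p.name: _sha256(p) for p in artifacts},
    }
    with open(out / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    summary["manifest"] = manifest
    return summary
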