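"""Synthetic input generators for every pipeline stage.

Each generator is a pure function of its configuration and seed
(byte-identical outputs on repeat) and returns the planted ground truth
alongside the data, so downstream recovery tests can score themselves.

The generators emulate, in order: a Gencode-like gene universe with an
lncRNA biotype mixture; ER-alpha binding-site peaks planted near
regulated genes; a two-condition negative-binomial knockdown experiment
(si-ER-alpha vs control); a 55-sample, 4-subtype breast-cancer cell-line
expression panel with a planted luminal signature; promoter-like vs
enhancer-like histone-mark tag pileups (H3K4me3:H3K4me1 ratios 4:1 and
1:4); and two qRT-PCR runs differing by a location/scale batch effect
with an ER-status group effect.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from aerlnc.models import (
    BindingSiteSet,
    CountMatrix,
    CtSeries,
    ExpressionPanel,
    GeneModel,
    GenomicInterval,
    LNCRNA_BIOTYPES,
    TagTrack,
)

# distinct sub-streams so that generators called with the same config
# seed still draw independent randomness
_STREAM = {
    "annotation": 1,
    "sites": 2,
    "counts": 3,
    "panel": 4,
    "tags": 5,
    "ct": 6,
}

#: minimum TSS spacing enforced by the annotation generator (bp)
TSS_SPACING = 1000
#: margin at the chromosome edges so gene bodies stay in bounds (bp)
_EDGE_MARGIN = 10_000


def _default_biotype_fractions() -> dict[str, float]:
    # roughly Gencode-like mixture; lncRNA classes mirror the biotype
    # spectrum seen among regulated genes (antisense and lincRNA dominant,
    # few processed_transcript / sense_intronic / sense_overlapping)
    return {
        "protein_coding": 0.55,
        "lincRNA": 0.18,
        "antisense": 0.17,
        "processed_transcript": 0.04,
        "sense_intronic": 0.01,
        "sense_overlapping": 0.01,
        "pseudogene": 0.04,
    }


def _default_subtype_design() -> dict[str, int]:
    # 55 cell lines split across the four subtypes
    return {"luminal": 14, "basal": 14, "claudin_low": 14, "normal_like": 13}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults set to the
    conditions the pipeline is characterized under."""

    seed: int = 0
    n_genes: int = 2000
    biotype_fractions: dict[str, float] = field(default_factory=_default_biotype_fractions)
    n_chromosomes: int = 5
    chrom_length: int = 50_000_000
    # differential expression (knockdown contrast)
    de_fraction: float = 0.10
    lfc: float = 2.0
    dispersion: float = 0.05
    lib_size: int = 20_000_000
    n_reps: int = 3
    down_fraction: float = 0.65  # echoes the 86/133 down vs 47/133 up split
    # binding sites
    proximity_scale: float = 10_000.0
    n_background_sites: int = 1000
    site_width: int = 200
    # subtype panel
    subtype_design: dict[str, int] = field(default_factory=_default_subtype_design)
    signature_size: int = 29
    signature_effect: float = 3.0  # luminal mean shift, in within-group sd units
    signature_down_fraction: float = 0.25  # mirrors 7/9 down among 22/28 up
    subtype_separation: float = 1.0  # sd of per-subtype centroid offsets on signature genes
    panel_sigma: float = 0.4  # within-group sd of log10 abundance
    # qRT-PCR
    run_sizes: tuple[int, int] = (22, 20)
    ct_shift: tuple[float, float] = (0.5, 1.2)  # run-2 (location a, scale b) on log scale
    group_delta: float = 0.7  # ER+ minus ER- mean log Delta-Ct
    ct_sigma: float = 0.35
    er_pos_fraction: float = 26 / 42  # 26 ER+ of 42 biopsies

    def __post_init__(self) -> None:
        total = sum(self.biotype_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"biotype fractions must sum to 1, got {total}")
        for name in ("n_genes", "n_chromosomes", "chrom_length", "lib_size", "n_reps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM[stream]])


def gen_annotation(cfg: SimulationConfig) -> dict[str, GeneModel]:
    """Generate a gene annotation with non-overlapping TSSs.

    Genes are placed on a 1 kb grid per chromosome (uniform slot draw
    without replacement), biotype counts match the configured fractions
    to rounding (largest remainder), and each gene carries 1-4
    transcripts of >= 100 bp.
    """
    rng = cfg.rng("annotation")
    slots_per_chrom = (cfg.chrom_length - 2 * _EDGE_MARGIN) // TSS_SPACING
    capacity = slots_per_chrom * cfg.n_chromosomes
    if cfg.n_genes > capacity:
        raise ValueError(
            f"cannot place {cfg.n_genes} genes at >= {TSS_SPACING} bp spacing: "
            f"capacity is {capacity}"
        )

    # biotype counts by largest remainder
    names = sorted(cfg.biotype_fractions)
    quotas = {b: cfg.biotype_fractions[b] * cfg.n_genes for b in names}
    counts = {b: int(math.floor(q)) for b, q in quotas.items()}
    short = cfg.n_genes - sum(counts.values())
    for b in sorted(names, key=lambda b: quotas[b] - counts[b], reverse=True)[:short]:
        counts[b] += 1
    biotypes = np.array([b for b in names for _ in range(counts[b])], dtype=object)
    rng.shuffle(biotypes)

    # round-robin gene allocation across chromosomes
    per_chrom = [cfg.n_genes // cfg.n_chromosomes] * cfg.n_chromosomes
    for i in range(cfg.n_genes % cfg.n_chromosomes):
        per_chrom[i] += 1

    genes: dict[str, GeneModel] = {}
    gi = 0
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        slots = np.sort(rng.choice(slots_per_chrom, size=per_chrom[ci], replace=False))
        for slot in slots:
            tss = int(slot) * TSS_SPACING + _EDGE_MARGIN + 1  # 1-based
            n_tx = int(rng.integers(1, 5))
            lengths = tuple(int(x) for x in rng.integers(100, 5001, size=n_tx))
            strand = "+" if rng.random() < 0.5 else "-"
            span = max(lengths)
            if strand == "+":
                start, end = tss, tss + span - 1
            else:
                start, end = tss - span + 1, tss
            gid = f"GENE{gi:05d}"
            genes[gid] = GeneModel(
                gene_id=gid,
                symbol=f"SYN{gi:05d}",
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                biotype=str(biotypes[gi]),
                transcript_lengths=lengths,
            )
            gi += 1
    return genes


def gen_binding_sites(
    annotation: Mapping[str, GeneModel],
    target_genes: Iterable[str],
    cfg: SimulationConfig,
    n_background: Optional[int] = None,
) -> tuple[BindingSiteSet, pd.DataFrame]:
    """Plant one binding site per target gene near its TSS, plus uniform
    background sites.

    The signed TSS offset has |offset| ~ Exponential(proximity_scale);
    sites are ``site_width`` bp wide, centered on the planted summit.
    Returns the site set and the planted ground truth (gene_id, summit,
    signed offset from the TSS).
    """
    rng = cfg.rng("sites")
    targets = list(target_genes)
    missing = [t for t in targets if t not in annotation]
    if missing:
        raise ValueError(f"target genes absent from annotation: {missing[:5]}")
    if n_background is None:
        n_background = cfg.n_background_sites

    half = cfg.site_width // 2
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    summits: list[int] = []
    truth_rows = []
    for t in targets:
        g = annotation[t]
        mag = rng.exponential(cfg.proximity_scale)  # exponential(0) == 0
        sign = 1 if rng.random() < 0.5 else -1
        summit = int(round(g.tss + sign * mag))
        summit = max(half, summit)
        chroms.append(g.chrom)
        summits.append(summit)
        starts.append(summit - half)
        ends.append(summit + (cfg.site_width - half))
        truth_rows.append({"gene_id": t, "summit": summit, "offset": summit - g.tss})
    for _ in range(n_background):
        chrom = f"chr{int(rng.integers(cfg.n_chromosomes)) + 1}"
        summit = int(rng.integers(_EDGE_MARGIN, cfg.chrom_length - _EDGE_MARGIN))
        chroms.append(chrom)
        summits.append(summit)
        starts.append(summit - half)
        ends.append(summit + (cfg.site_width - half))
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "summit", "offset"])
    return BindingSiteSet(chroms, starts, ends, summits), truth


def gen_counts(
    annotation: Mapping[str, GeneModel], cfg: SimulationConfig
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate the two-condition knockdown count experiment.

    Counts are NB(mean_i * s_j * 2^(+/- lfc * de_i), dispersion) with
    Var = mu + phi * mu^2. A ``de_fraction`` of lncRNA genes is planted
    differentially expressed; ``down_fraction`` of those go down in the
    knockdown condition. Returns the count matrix and the truth table of
    planted genes (gene_id, direction, lfc).
    """
    if cfg.n_reps < 2:
        raise ValueError("DE testing requires >= 2 replicates per condition")
    rng = cfg.rng("counts")
    gene_ids = list(annotation)
    n = len(gene_ids)

    base = np.exp(rng.normal(np.log(100.0), 1.0, size=n))
    base = np.clip(base, 5.0, None)
    base *= cfg.lib_size / base.sum()

    lnc_idx = [i for i, gid in enumerate(gene_ids) if annotation[gid].is_lncrna]
    truth_rows: list[dict] = []
    fold = np.ones(n)
    if cfg.lfc != 0 and cfg.de_fraction > 0:
        n_de = int(round(cfg.de_fraction * len(lnc_idx)))
        planted = rng.choice(lnc_idx, size=n_de, replace=False)
        n_down = int(round(cfg.down_fraction * n_de))
        for k, i in enumerate(planted):
            direction = "down" if k < n_down else "up"
            signed = -cfg.lfc if direction == "down" else cfg.lfc
            fold[i] = 2.0**signed
            truth_rows.append({"gene_id": gene_ids[i], "direction": direction, "lfc": signed})
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "direction", "lfc"])

    samples: dict[str, np.ndarray] = {}
    condition: dict[str, str] = {}
    phi = cfg.dispersion
    r = 1.0 / phi
    for cond, mult in (("ctrl", np.ones(n)), ("ko", fold)):
        for rep in range(1, cfg.n_reps + 1):
            s_j = float(np.exp(rng.normal(0.0, 0.1)))
            mu = base * mult * s_j
            p = r / (r + mu)
            name = f"{cond}_{rep}"
            samples[name] = rng.negative_binomial(r, p)
            condition[name] = cond
    counts = pd.DataFrame(samples, index=pd.Index(gene_ids, name="gene_id"))
    return CountMatrix(counts, condition), truth


def gen_panel(
    annotation: Mapping[str, GeneModel],
    cfg: SimulationConfig,
    signature_genes: Optional[Iterable[str]] = None,
) -> tuple[ExpressionPanel, pd.DataFrame]:
    """Simulate the multi-subtype expression panel with a planted luminal
    signature.

    Abundances are log-normal (log10 scale, sd ``panel_sigma``); the
    ``signature_size`` planted genes are shifted by
    ``signature_effect * panel_sigma`` in the luminal samples, a
    ``signature_down_fraction`` of them negatively. Every subtype also
    receives its own centroid offset on the signature genes (sd
    ``subtype_separation * panel_sigma``), so non-luminal subtypes are
    mutually distinguishable, as real expression subtypes are. When
    ``signature_genes`` is given, the planted genes are drawn from that
    subset (e.g. the regulated genes of the knockdown experiment, which
    is the luminal-specificity structure the study observes). Returns
    the panel and the truth table (gene_id, sign).
    """
    rng = cfg.rng("panel")
    lnc_ids = [gid for gid, g in annotation.items() if g.is_lncrna]
    if cfg.signature_size > len(lnc_ids):
        raise ValueError(
            f"signature_size {cfg.signature_size} exceeds the {len(lnc_ids)} lncRNA genes"
        )
    candidate_idx = None
    if signature_genes is not None:
        wanted = set(signature_genes)
        candidate_idx = [i for i, gid in enumerate(lnc_ids) if gid in wanted]
        if cfg.signature_size > len(candidate_idx):
            raise ValueError(
                f"signature_size {cfg.signature_size} exceeds the "
                f"{len(candidate_idx)} candidate lncRNA genes"
            )
    n_genes = len(lnc_ids)
    n_samples = sum(cfg.subtype_design.values())

    subtypes: list[str] = []
    for name, count in cfg.subtype_design.items():
        subtypes.extend([name] * count)
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    is_luminal = np.array([s == "luminal" for s in subtypes])

    mu = rng.normal(1.0, 0.5, size=n_genes)  # per-gene log10 baseline
    log_vals = rng.normal(mu[:, None], cfg.panel_sigma, size=(n_genes, n_samples))

    pool = np.arange(n_genes) if candidate_idx is None else np.array(candidate_idx)
    planted = rng.choice(pool, size=cfg.signature_size, replace=False)
    n_down = int(round(cfg.signature_down_fraction * cfg.signature_size))
    signs = np.ones(cfg.signature_size)
    signs[:n_down] = -1.0
    rng.shuffle(signs)
    shift = cfg.signature_effect * cfg.panel_sigma
    subtype_names = sorted(set(subtypes) - {"luminal"})
    centroid = {
        name: rng.normal(0.0, cfg.subtype_separation * cfg.panel_sigma, size=cfg.signature_size)
        for name in subtype_names
    }
    subtype_arr = np.array(subtypes, dtype=object)
    for jj, (j, sgn) in enumerate(zip(planted, signs)):
        log_vals[j, is_luminal] += sgn * shift
        for name in subtype_names:
            log_vals[j, subtype_arr == name] += centroid[name][jj]

    values = pd.DataFrame(
        10.0**log_vals, index=pd.Index(lnc_ids, name="gene_id"), columns=sample_ids
    )
    subtype = dict(zip(sample_ids, subtypes))
    receptor = {s: ("ER+" if subtype[s] == "luminal" else "ER-") for s in sample_ids}
    truth = pd.DataFrame(
        {"gene_id": [lnc_ids[j] for j in planted], "sign": signs}
    ).sort_values("gene_id", ignore_index=True)
    return ExpressionPanel(values, subtype, receptor), truth


def gen_chip_tags(
    regions: Sequence[GenomicInterval],
    profile: str,
    n_tags: int,
    seed: int,
    sd: float = 300.0,
) -> tuple[TagTrack, TagTrack]:
    """Simulate two histone-mark tag tracks around region anchors.

    ``profile='promoter'`` draws mark A (H3K4me3-like) and mark B
    (H3K4me1-like) tags at a 4:1 ratio per region; ``'enhancer'``
    inverts the ratio. Tag positions are Gaussian (sd 300 bp) around the
    region midpoint; ``n_tags`` is the per-region total across both
    marks. Both tracks are padded with uniformly placed background tags
    so they carry the same library size (as two equally sequenced ChIP
    experiments would), which is what makes the focal-region CPM ratio
    reflect the 4:1 generation. Returns (track_A, track_B).
    """
    if profile not in ("promoter", "enhancer"):
        raise ValueError("profile must be 'promoter' or 'enhancer'")
    rng = np.random.default_rng([seed, _STREAM["tags"]])
    frac_a = 0.8 if profile == "promoter" else 0.2
    tracks: dict[str, dict[str, list]] = {
        "A": {"chrom": [], "pos": [], "strand": []},
        "B": {"chrom": [], "pos": [], "strand": []},
    }
    for region in regions:
        n_a = int(round(frac_a * n_tags))
        for mark, count in (("A", n_a), ("B", n_tags - n_a)):
            if count == 0:
                continue
            offsets = rng.normal(0.0, sd, size=count)
            positions = np.maximum(0, np.round(region.midpoint + offsets).astype(np.int64))
            strands = np.where(rng.random(count) < 0.5, "+", "-")
            tracks[mark]["chrom"].extend([region.chrom] * count)
            tracks[mark]["pos"].extend(positions.tolist())
            tracks[mark]["strand"].extend(strands.tolist())
    # equalize library sizes with dispersed background tags
    if regions and n_tags > 0:
        chrom_list = sorted({r.chrom for r in regions})
        span = max(r.end for r in regions) + 1_000_000
        budget = len(regions) * n_tags
        for mark in ("A", "B"):
            deficit = budget - len(tracks[mark]["pos"])
            if deficit <= 0:
                continue
            positions = rng.integers(0, span, size=deficit)
            chroms_bg = rng.choice(np.array(chrom_list, dtype=object), size=deficit)
            strands = np.where(rng.random(deficit) < 0.5, "+", "-")
            tracks[mark]["chrom"].extend(chroms_bg.tolist())
            tracks[mark]["pos"].extend(positions.tolist())
            tracks[mark]["strand"].extend(strands.tolist())
    out = []
    for mark in ("A", "B"):
        t = tracks[mark]
        out.append(
            TagTrack(
                np.array(t["chrom"], dtype=object),
                np.array(t["pos"], dtype=np.int64),
                np.array(t["strand"], dtype=object),
            )
        )
    return out[0], out[1]


def gen_coexpression_panel(
    n_samples: int = 20,
    n_correlated: int = 10,
    n_background: int = 100,
    r: float = 0.9,
    seed: int = 0,
) -> tuple[ExpressionPanel, dict]:
    """Panel with genes planted at a known Pearson correlation to a
    focal gene.

    On the log10 scale the focal gene is standard normal; each planted
    gene is r * focal + sqrt(1 - r^2) * noise; background genes are
    independent. Returns the panel (abundances = 10^log-values around a
    baseline of 10) and the truth dict naming the focal and planted
    genes.
    """
    if not (-1.0 < r < 1.0):
        raise ValueError("r must be in (-1, 1)")
    rng = np.random.default_rng([seed, _STREAM["panel"]])
    focal = rng.normal(0.0, 1.0, n_samples)
    rows = {"FOCAL": focal}
    for i in range(n_correlated):
        noise = rng.normal(0.0, 1.0, n_samples)
        rows[f"CORR{i + 1:03d}"] = r * focal + math.sqrt(1.0 - r * r) * noise
    for i in range(n_background):
        rows[f"BG{i + 1:03d}"] = rng.normal(0.0, 1.0, n_samples)
    log_vals = pd.DataFrame(rows).T
    log_vals.index.name = "gene_id"
    log_vals.columns = [f"S{j + 1:02d}" for j in range(n_samples)]
    values = 10.0 ** (log_vals + 1.0)  # baseline 10, keeps log10(x+0.01) ~ linear
    subtype = {s: "cell_line" for s in values.columns}
    truth = {
        "focal": "FOCAL",
        "correlated": [f"CORR{i + 1:03d}" for i in range(n_correlated)],
        "r": r,
    }
    return ExpressionPanel(values, subtype), truth


def gen_ct(cfg: SimulationConfig) -> tuple[CtSeries, CtSeries, dict]:
    """Simulate two qRT-PCR runs with a location/scale batch effect.

    Run 1 draws log Delta-Ct ~ N(mu_group, ct_sigma^2) with an ER+ vs
    ER- difference of ``group_delta``; run 2 draws from the same model
    and is then transformed x -> a + b*x on the log scale with
    (a, b) = ``ct_shift``. Delta-Ct is encoded back into
    (reference_ct, target_ct) pairs under the ratio convention
    reference/target with reference fixed at 10 cycles.
    """
    rng = cfg.rng("ct")
    a, b = cfg.ct_shift
    reference = 10.0
    tables = []
    for run_id, n in zip((1, 2), cfg.run_sizes):
        n_pos = int(round(cfg.er_pos_fraction * n))
        groups = np.array(["ER_pos"] * n_pos + ["ER_neg"] * (n - n_pos), dtype=object)
        mu = np.where(groups == "ER_pos", cfg.group_delta, 0.0)
        log_v = rng.normal(mu, cfg.ct_sigma)
        if run_id == 2:
            log_v = a + b * log_v
        value = np.exp(log_v)
        target = np.clip(reference / value, 0.5, 45.0)
        table = pd.DataFrame(
            {
                "target_ct": target,
                "reference_ct": reference,
                "run_id": run_id,
                "group": groups,
            },
            index=pd.Index([f"run{run_id}_s{i + 1:02d}" for i in range(n)], name="sample_id"),
        )
        tables.append(CtSeries(table))
    truth = {
        "a": a,
        "b": b,
        "group_delta": cfg.group_delta,
        "sigma": cfg.ct_sigma,
        "run_sizes": list(cfg.run_sizes),
    }
    return tables[0], tables[1], truth


def write_truth(truth: dict, path: str | Path) -> None:
    """Record planted ground truth as a JSON sidecar."""

    def _clean(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, pd.DataFrame):
            return obj.to_dict(orient="records")
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        return obj

    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(_clean(truth), fh, indent=1, sort_keys=True)
        fh.write("\n")
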