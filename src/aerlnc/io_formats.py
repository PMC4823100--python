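"""Readers and writers for the external formats the pipeline touches.

This is the single place where coordinates change basis: BED files are
0-based half-open, GTF files 1-based inclusive. All writers emit
tab-separated UTF-8 with a commented header line recording the tool
version and, when given, the seed that produced the data.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from aerlnc.models import BindingSiteSet, CountMatrix, CtSeries, ExpressionPanel, GeneModel, KNOWN_BIOTYPES, TagTrack

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _header(seed: Optional[int]) -> str:
    from aerlnc import __version__

    line = f"#aerlnc v{__version__}"
    if seed is not None:
        line += f" seed={seed}"
    return line


def _parse_attributes(attr_field: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(attr_field))
    if not attrs:
        raise ValueError(f"malformed GTF attribute field at line {lineno}: {attr_field!r}")
    return attrs


def read_gtf(path: str | Path) -> dict[str, GeneModel]:
    """Read a Gencode-dialect GTF into gene models keyed by gene_id.

    The gene TSS is the gene-record boundary on the strand (start on '+',
    end on '-'), 1-based. Transcript lengths are exon-length sums per
    transcript; a gene with no transcript records falls back to its own
    span as sole isoform, with a warning. A missing biotype attribute is
    recorded as ``"unknown"`` with a warning.
    """
    genes: dict[str, dict] = {}
    tx_gene: dict[str, str] = {}
    tx_len: dict[str, int] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"expected 9 GTF fields at line {lineno}, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attr_field = fields
            if feature not in ("gene", "transcript", "exon"):
                continue
            attrs = _parse_attributes(attr_field, lineno)
            if "gene_id" not in attrs:
                raise ValueError(f"GTF line {lineno} lacks gene_id attribute")
            gid = attrs["gene_id"]
            if feature == "gene":
                biotype = attrs.get("gene_type", attrs.get("gene_biotype"))
                if biotype is None:
                    warnings.warn(f"gene {gid} lacks a biotype attribute; set to 'unknown'")
                    biotype = "unknown"
                biotype = biotype.replace(" ", "_").replace("-", "_")
                if biotype not in KNOWN_BIOTYPES:
                    biotype = "unknown"
                genes[gid] = {
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "strand": strand,
                    "biotype": biotype,
                    "symbol": attrs.get("gene_name", gid),
                }
            elif feature == "transcript":
                tid = attrs.get("transcript_id")
                if tid is None:
                    raise ValueError(f"transcript at line {lineno} lacks transcript_id")
                tx_gene[tid] = gid
                tx_len.setdefault(tid, 0)
            else:  # exon
                tid = attrs.get("transcript_id")
                if tid is None:
                    raise ValueError(f"exon at line {lineno} lacks transcript_id")
                tx_gene.setdefault(tid, gid)
                tx_len[tid] = tx_len.get(tid, 0) + int(end) - int(start) + 1

    by_gene: dict[str, list[int]] = {gid: [] for gid in genes}
    for tid, gid in tx_gene.items():
        if gid in by_gene and tx_len.get(tid, 0) > 0:
            by_gene[gid].append(tx_len[tid])

    out: dict[str, GeneModel] = {}
    for gid, rec in genes.items():
        lengths = by_gene[gid]
        if not lengths:
            warnings.warn(f"gene {gid} has no transcript records; using gene span as sole isoform")
            lengths = [rec["end"] - rec["start"] + 1]
        out[gid] = GeneModel(
            gene_id=gid,
            symbol=rec["symbol"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            start=rec["start"],
            end=rec["end"],
            biotype=rec["biotype"],
            transcript_lengths=tuple(lengths),
        )
    return out


def write_gtf(genes: Mapping[str, GeneModel] | Iterable[GeneModel], path: str | Path, seed: Optional[int] = None) -> None:
    """Write gene models as Gencode-dialect GTF (one exon per transcript).

    ``read_gtf(write_gtf(x)) == x``: each transcript is emitted as a
    single exon of the recorded length anchored at the gene start.
    """
    if isinstance(genes, Mapping):
        genes = genes.values()
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(_header(seed) + "\n")
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_type "{g.biotype}"; gene_name "{g.symbol}";'
            fh.write(
                "\t".join(
                    [g.chrom, "aerlnc", "gene", str(g.start), str(g.end), ".", g.strand, ".", attrs]
                )
                + "\n"
            )
            for i, length in enumerate(g.transcript_lengths, 1):
                tid = f"{g.gene_id}.t{i}"
                tattrs = attrs + f' transcript_id "{tid}";'
                t_end = g.start + length - 1
                for feat in ("transcript", "exon"):
                    fh.write(
                        "\t".join(
                            [g.chrom, "aerlnc", feat, str(g.start), str(t_end), ".", g.strand, ".", tattrs]
                        )
                        + "\n"
                    )


def read_bed(path: str | Path) -> BindingSiteSet:
    """Read a BED3+ peak file into a :class:`BindingSiteSet`.

    Coordinates are 0-based half-open. The summit defaults to the
    interval midpoint (floor on ties); if a 7th column is present it is
    taken as an absolute summit position. Records with end <= start are
    rejected with a warning.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    summits: list[int] = []
    any_summit = False
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED line {lineno} has fewer than 3 fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                warnings.warn(f"BED line {lineno}: end <= start, record rejected")
                continue
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
            if len(fields) >= 7:
                summits.append(int(fields[6]))
                any_summit = True
            else:
                summits.append((start + end) // 2)
    return BindingSiteSet(chroms, starts, ends, summits if any_summit or summits else None)


def write_bed(sites: BindingSiteSet, path: str | Path, seed: Optional[int] = None) -> None:
    """Write a site set as BED6+summit (7th column = absolute summit)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(_header(seed) + "\n")
        for i in range(len(sites)):
            fh.write(
                "\t".join(
                    [
                        str(sites.chroms[i]),
                        str(sites.starts[i]),
                        str(sites.ends[i]),
                        f"site_{i}",
                        "0",
                        ".",
                        str(sites.summits[i]),
                    ]
                )
                + "\n"
            )


def read_tag_bed(path: str | Path) -> TagTrack:
    """Read ChIP tag 5' positions from a BED6 file (strand in column 6)."""
    chroms: list[str] = []
    pos: list[int] = []
    strands: list[str] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"tag BED line {lineno} has fewer than 3 fields")
            strand = fields[5] if len(fields) >= 6 else "+"
            start, end = int(fields[1]), int(fields[2])
            chroms.append(fields[0])
            # the 5' base: interval start on '+', end-1 on '-'
            pos.append(start if strand != "-" else end - 1)
            strands.append(strand if strand in ("+", "-") else "+")
    return TagTrack(np.array(chroms, dtype=object), np.array(pos), np.array(strands, dtype=object))


def write_tag_bed(track: TagTrack, path: str | Path, seed: Optional[int] = None) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(_header(seed) + "\n")
        for i in range(len(track)):
            p, s = int(track.pos[i]), str(track.strands[i])
            fh.write(
                "\t".join([str(track.chroms[i]), str(p), str(p + 1), f"tag_{i}", "0", s]) + "\n"
            )


def read_count_table(path: str | Path, design: Mapping[str, str]) -> CountMatrix:
    """Read a genes-x-samples TSV of integer counts.

    First column holds gene ids; every sample column must appear in
    ``design`` (sample -> condition map). Non-integer, negative or
    duplicated entries raise with the offending cell or id named.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.empty:
        raise ValueError("no data rows in count table")
    return CountMatrix(df, design)


def write_count_table(cm: CountMatrix, path: str | Path, seed: Optional[int] = None) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(_header(seed) + "\n")
        cm.counts.rename_axis("gene_id").to_csv(fh, sep="\t")


def write_design(cm: CountMatrix, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("sample_id\tcondition\n")
        for s, c in cm.condition.items():
            fh.write(f"{s}\t{c}\n")


def read_design(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["sample_id"], df["condition"]))


def read_expression_panel(values_path: str | Path, labels_path: str | Path) -> ExpressionPanel:
    """Read an abundance panel plus its per-sample label table.

    The label table needs ``sample_id`` and ``subtype`` columns; a
    ``receptor_status`` column is optional.
    """
    values = pd.read_csv(values_path, sep="\t", comment="#", index_col=0)
    labels = pd.read_csv(labels_path, sep="\t", comment="#")
    subtype = dict(zip(labels["sample_id"], labels["subtype"]))
    receptor = (
        dict(zip(labels["sample_id"], labels["receptor_status"]))
        if "receptor_status" in labels.columns
        else None
    )
    return ExpressionPanel(values, subtype, receptor)


def write_expression_panel(
    panel: ExpressionPanel, values_path: str | Path, labels_path: str | Path, seed: Optional[int] = None
) -> None:
    with open(values_path, "wt", encoding="utf-8") as fh:
        fh.write(_header(seed) + "\n")
        panel.values.rename_axis("gene_id").to_csv(fh, sep="\t")
    with open(labels_path, "wt", encoding="utf-8") as fh:
        cols = "sample_id\tsubtype"
        if panel.receptor_status is not None:
            cols += "\treceptor_status"
        fh.write(cols + "\n")
        for s in panel.sample_ids:
            row = f"{s}\t{panel.subtype[s]}"
            if panel.receptor_status is not None:
                row += f"\t{panel.receptor_status[s]}"
            fh.write(row + "\n")


def read_ct_table(path: str | Path) -> CtSeries:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return CtSeries(df)


def write_ct_table(series: CtSeries, path: str | Path, seed: Optional[int] = None) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(_header(seed) + "\n")
        series.table.rename_axis("sample_id").to_csv(fh, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path, seed: Optional[int] = None, index: bool = True) -> None:
    """Generic TSV writer with the provenance header."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(_header(seed) + "\n")
        df.to_csv(fh, sep="\t", index=index)
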