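"""Core domain containers shared across pipeline stages.

Coordinate conventions: genomic intervals are 0-based half-open (BED
convention); gene coordinates and TSS are 1-based inclusive (GTF
convention). Conversion between the two happens only inside
:mod:`aerlnc.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: biotypes counted as lncRNA by the catalog filters
LNCRNA_BIOTYPES = frozenset(
    {"antisense", "lincRNA", "processed_transcript", "sense_intronic", "sense_overlapping"}
)

#: closed vocabulary for gene biotypes
KNOWN_BIOTYPES = LNCRNA_BIOTYPES | {"protein_coding", "pseudogene", "unknown"}

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start, got [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Midpoint base, floor on ties."""
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene with its transcript structure.

    ``start``/``end``/``tss`` are 1-based inclusive. The TSS is the gene
    boundary on the strand: gene start on '+', gene end on '-'.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str
    transcript_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be '+' or '-', got {self.strand!r}")
        if self.biotype not in KNOWN_BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r} for {self.gene_id}")
        if not self.transcript_lengths:
            raise ValueError(f"gene {self.gene_id} has no transcript lengths")
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end < start")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def longest_isoform_kb(self) -> float:
        return max(self.transcript_lengths) / 1000.0

    @property
    def is_lncrna(self) -> bool:
        return self.biotype in LNCRNA_BIOTYPES


class BindingSiteSet:
    """A set of genomic intervals with summits (e.g. ChIP peaks).

    Sites are stored sorted by (chrom, summit); per-chromosome summit
    arrays back the fast nearest-site queries in
    :mod:`aerlnc.cis_regulation`.
    """

    def __init__(
        self,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        summits: Optional[Sequence[int]] = None,
    ) -> None:
        chroms = np.asarray(chroms, dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if not (len(chroms) == len(starts) == len(ends)):
            raise ValueError("chroms/starts/ends must have equal length")
        if np.any(ends <= starts):
            raise ValueError("every site must satisfy end > start")
        if summits is None:
            summits = (starts + ends) // 2  # midpoint, floor on ties
        else:
            summits = np.asarray(summits, dtype=np.int64)
            if len(summits) != len(starts):
                raise ValueError("summits length mismatch")
        order = np.lexsort((summits, chroms.astype(str)))
        self.chroms = chroms[order]
        self.starts = starts[order]
        self.ends = ends[order]
        self.summits = summits[order]
        self._by_chrom: dict[str, np.ndarray] = {}
        for c in np.unique(self.chroms.astype(str)):
            self._by_chrom[c] = self.summits[self.chroms == c]

    def __len__(self) -> int:
        return len(self.summits)

    def summits_on(self, chrom: str) -> np.ndarray:
        """Sorted summit positions on one chromosome (empty if absent)."""
        return self._by_chrom.get(chrom, np.empty(0, dtype=np.int64))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BindingSiteSet):
            return NotImplemented
        return (
            len(self) == len(other)
            and bool(np.all(self.chroms == other.chroms))
            and bool(np.all(self.starts == other.starts))
            and bool(np.all(self.ends == other.ends))
            and bool(np.all(self.summits == other.summits))
        )


@dataclass
class TagTrack:
    """Sequencing tag (read) 5' positions for one ChIP mark.

    ``pos`` holds the 5'-most base of each tag (0-based); tags on '-'
    strand extend leftwards when the signal binner applies read extension.
    """

    chroms: np.ndarray
    pos: np.ndarray
    strands: np.ndarray

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.strands = np.asarray(self.strands, dtype=object)
        if not (len(self.chroms) == len(self.pos) == len(self.strands)):
            raise ValueError("tag arrays must have equal length")

    def __len__(self) -> int:
        return len(self.pos)


class CountMatrix:
    """Genes x samples integer counts with a condition label per sample."""

    def __init__(self, counts: pd.DataFrame, condition: Mapping[str, str]) -> None:
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise ValueError(f"duplicated gene id: {dup}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                bad = np.argwhere(np.mod(arr, 1) != 0)[0]
                raise ValueError(
                    f"non-integer count at gene {counts.index[bad[0]]!r}, "
                    f"sample {counts.columns[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
            arr = counts.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at gene {counts.index[bad[0]]!r}, "
                f"sample {counts.columns[bad[1]]!r}"
            )
        missing = [s for s in counts.columns if s not in condition]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        self.counts = counts
        self.condition = {s: condition[s] for s in counts.columns}

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def lib_sizes(self) -> pd.Series:
        """Reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def million_reads(self) -> pd.Series:
        return self.lib_sizes / 1e6

    def samples_of(self, cond: str) -> list[str]:
        return [s for s, c in self.condition.items() if c == cond]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.condition.values():
            if c not in seen:
                seen.append(c)
        return seen


class ExpressionPanel:
    """Genes x samples abundance panel with subtype labels per sample."""

    def __init__(
        self,
        values: pd.DataFrame,
        subtype: Mapping[str, str],
        receptor_status: Optional[Mapping[str, str]] = None,
    ) -> None:
        if values.isna().any().any():
            raise ValueError("panel contains missing values")
        missing = [s for s in values.columns if s not in subtype]
        if missing:
            raise ValueError(f"samples without subtype label: {missing}")
        self.values = values
        self.subtype = pd.Series({s: subtype[s] for s in values.columns})
        if receptor_status is not None:
            receptor_status = pd.Series(
                {s: receptor_status[s] for s in values.columns}
            )
        self.receptor_status = receptor_status

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


class CtSeries:
    """Per-sample qRT-PCR cycle thresholds for one run.

    Columns: sample_id (index), target_ct, reference_ct, run_id, group.
    """

    REQUIRED = ("target_ct", "reference_ct", "run_id", "group")

    def __init__(self, table: pd.DataFrame) -> None:
        for col in self.REQUIRED:
            if col not in table.columns:
                raise ValueError(f"CtSeries missing column {col!r}")
        for col in ("target_ct", "reference_ct"):
            vals = table[col].to_numpy(dtype=float)
            if np.any(~np.isfinite(vals)) or np.any(vals <= 0) or np.any(vals > 45):
                raise ValueError(f"{col} values must lie in (0, 45]")
        if table["run_id"].isna().any() or table["group"].isna().any():
            raise ValueError("run_id and group must be non-missing")
        self.table = table.copy()

    def __len__(self) -> int:
        return len(self.table)

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]
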