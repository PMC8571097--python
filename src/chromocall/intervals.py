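"""Genomic intervals, fragments, gene models and count matrices.

All coordinates are 0-based half-open (BED convention). The TSS of a
minus-strand gene is ``end - 1``. These primitives are the substrate of
every quantification step in the pipeline: peak counting, TSS-window
quantification and genome binning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "FragmentRecord",
    "CountMatrix",
    "ParseError",
    "read_intervals",
    "write_intervals",
    "read_fragments",
    "write_fragments",
    "read_gene_models",
    "write_gene_models",
    "fragments_to_frame",
    "frame_to_fragments",
    "overlap_join",
    "count_fragments_in_intervals",
]


class ParseError(ValueError):
    """Raised for malformed interval/fragment files; carries the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        return self.name if self.name else f"{self.chrom}:{self.start}-{self.end}"

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with an oriented interval; the TSS depends on strand."""

    gene_id: str
    interval: GenomicInterval

    @property
    def tss(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    def tss_window(self, half_width: int) -> GenomicInterval:
        """Symmetric half-open window around the TSS, clipped at 0."""
        if half_width <= 0:
            raise ValueError("half_width must be positive")
        start = max(0, self.tss - half_width)
        return GenomicInterval(
            self.interval.chrom, start, self.tss + half_width, name=self.gene_id
        )


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced fragment (or a stack of identical fragments, via count).

    ``barcode`` identifies a sample in bulk mode or a cell in single-cell
    mode; one reader serves both stages.
    """

    chrom: str
    start: int
    end: int
    barcode: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"fragment {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.count < 1:
            raise ValueError(f"fragment count must be >= 1, got {self.count}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class CountMatrix:
    """Rows are intervals/genes, columns are samples/cells; values are counts."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate row identifiers in count matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate column identifiers in count matrix")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

IntervalFormat = Literal["BED3", "BED6", "bedGraph"]


def read_intervals(path: str | Path, format: IntervalFormat = "BED6") -> list[GenomicInterval]:
    """Read tab-separated intervals; half-open coordinates, errors name lines."""
    if format not in ("BED3", "BED6", "bedGraph"):
        raise ValueError(f"unknown interval format {format!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = score = None
                strand = "."
                if format == "bedGraph":
                    score = float(fields[3])
                elif format == "BED6":
                    if len(fields) > 3 and fields[3] != ".":
                        name = fields[3]
                    if len(fields) > 4 and fields[4] != ".":
                        score = float(fields[4])
                    if len(fields) > 5:
                        strand = fields[5]
                out.append(GenomicInterval(chrom, start, end, name, score, strand))
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_intervals(
    path: str | Path, intervals: Iterable[GenomicInterval], format: IntervalFormat = "BED6"
) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if format == "BED3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            elif format == "bedGraph":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.score or 0}\n")
            else:
                name = iv.name if iv.name is not None else "."
                score = repr(iv.score) if iv.score is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_fragments(path: str | Path) -> list[FragmentRecord]:
    """Read a 5-column fragments file; records come back sorted by (chrom, start)."""
    out: list[FragmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                out.append(
                    FragmentRecord(
                        fields[0], int(fields[1]), int(fields[2]), fields[3], int(fields[4])
                    )
                )
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    out.sort(key=lambda f: (f.chrom, f.start, f.end, f.barcode))
    return out


def write_fragments(path: str | Path, fragments: Iterable[FragmentRecord]) -> None:
    with open(path, "w") as fh:
        for fr in fragments:
            fh.write(f"{fr.chrom}\t{fr.start}\t{fr.end}\t{fr.barcode}\t{fr.count}\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Gene models as BED6 (name column = gene id, strand column oriented)."""
    genes = []
    for iv in read_intervals(path, format="BED6"):
        if iv.name is None:
            raise ParseError(f"{path}: gene record without an id: {iv}")
        genes.append(GeneModel(iv.name, iv))
    return genes


def write_gene_models(path: str | Path, genes: Iterable[GeneModel]) -> None:
    write_intervals(path, [g.interval if g.interval.name else
                           GenomicInterval(g.interval.chrom, g.interval.start,
                                           g.interval.end, g.gene_id,
                                           g.interval.score, g.interval.strand)
                           for g in genes], format="BED6")


def fragments_to_frame(fragments: Sequence[FragmentRecord]) -> pd.DataFrame:
    """Columnar view of a fragment list for vectorized quantification."""
    return pd.DataFrame(
        {
            "chrom": [f.chrom for f in fragments],
            "start": np.array([f.start for f in fragments], dtype=np.int64),
            "end": np.array([f.end for f in fragments], dtype=np.int64),
            "barcode": [f.barcode for f in fragments],
            "count": np.array([f.count for f in fragments], dtype=np.int64),
        }
    )


def frame_to_fragments(frame: pd.DataFrame) -> list[FragmentRecord]:
    return [
        FragmentRecord(c, int(s), int(e), b, int(n))
        for c, s, e, b, n in zip(
            frame["chrom"], frame["start"], frame["end"], frame["barcode"], frame["count"]
        )
    ]


# ---------------------------------------------------------------------------
# overlap primitives
# ---------------------------------------------------------------------------


def _trees_by_chrom(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for idx, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)
    return trees


def overlap_join(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """All (query index, subject index) pairs sharing >= 1 bp on the same chrom.

    Half-open semantics: end-abutting intervals do not overlap.
    """
    trees = _trees_by_chrom(subject)
    pairs: list[tuple[int, int]] = []
    for qi, iv in enumerate(query):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            pairs.append((qi, hit.data))
    pairs.sort()
    return pairs


CountMode = Literal["any_overlap", "midpoint"]


def count_fragments_in_intervals(
    fragments: Sequence[FragmentRecord] | pd.DataFrame,
    intervals: Sequence[GenomicInterval],
    mode: CountMode = "any_overlap",
    barcodes: Sequence[str] | None = None,
) -> CountMatrix:
    """Count fragments per (interval, barcode).

    ``any_overlap`` credits a fragment to every interval it overlaps;
    ``midpoint`` credits it to the interval containing floor((start+end)/2)
    (the first such interval in sorted order if intervals overlap each other).
    """
    if mode not in ("any_overlap", "midpoint"):
        raise ValueError(f"unknown counting mode {mode!r}")
    if len(intervals) == 0:
        raise ValueError("intervals must be non-empty")
    frame = fragments if isinstance(fragments, pd.DataFrame) else fragments_to_frame(fragments)

    if barcodes is None:
        barcodes = sorted(frame["barcode"].unique()) if len(frame) else []
    bar_index = {b: j for j, b in enumerate(barcodes)}
    mat = np.zeros((len(intervals), len(barcodes)), dtype=np.int64)

    order = sorted(range(len(intervals)), key=lambda i: (intervals[i].chrom,
                                                         intervals[i].start,
                                                         intervals[i].end))
    trees: dict[str, IntervalTree] = {}
    for rank, idx in enumerate(order):
        iv = intervals[idx]
        # rank encodes sorted order so midpoint ties resolve to the first interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, (rank, idx))

    for chrom, sub in frame.groupby("chrom", sort=False):
        tree = trees.get(chrom)
        if tree is None:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        counts = sub["count"].to_numpy()
        cols = np.array([bar_index[b] for b in sub["barcode"]])
        if mode == "any_overlap":
            for s, e, n, j in zip(starts, ends, counts, cols):
                for hit in tree.overlap(int(s), int(e)):
                    mat[hit.data[1], j] += n
        else:
            mids = (starts + ends) // 2
            for m, n, j in zip(mids, counts, cols):
                hits = tree.at(int(m))
                if hits:
                    idx = min(hits, key=lambda h: h.data[0]).data[1]
                    mat[idx, j] += n

    row_ids = [iv.id for iv in intervals]
    return CountMatrix(pd.DataFrame(mat, index=row_ids, columns=list(barcodes)))
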