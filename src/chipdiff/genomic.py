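"""Domain types and plain-text readers/writers for tags, intervals and genes.

Coordinate conventions used throughout the package:

* all intervals are 0-based half-open ``[start, end)``, the native BED
  convention;
* a *tag* is the 5' end of a single-end sequenced read: for a ``+`` (or
  unstranded) BED record the 5' end is ``start``, for a ``-`` record it is
  ``end - 1``;
* gene TSS coordinates are 0-based offsets of the start-site base itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "GenomicInterval",
    "GenomeLayout",
    "TagCollection",
    "GeneModel",
    "BedParseError",
    "AnnotationError",
    "read_tags_bed",
    "write_tags_bed",
    "read_gene_annotation",
    "write_gene_annotation",
    "write_intervals_bed",
    "read_genome_tsv",
    "write_genome_tsv",
]


class BedParseError(ValueError):
    """A malformed BED line; the message names the offending line number."""


class AnnotationError(ValueError):
    """A malformed or inconsistent gene-annotation record."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class GenomeLayout:
    """Ordered chromosome name -> length (bp) map."""

    def __init__(self, lengths: Mapping[str, int]):
        if not lengths:
            raise ValueError("genome layout must contain at least one chromosome")
        clean: Dict[str, int] = {}
        for name, length in lengths.items():
            if not name:
                raise ValueError("chromosome name must be non-empty")
            if name in clean:
                raise ValueError(f"duplicate chromosome name {name!r}")
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            clean[name] = length
        self._lengths = clean

    @property
    def lengths(self) -> Dict[str, int]:
        return dict(self._lengths)

    @property
    def chromosomes(self) -> List[str]:
        return list(self._lengths)

    @property
    def total_size(self) -> int:
        return sum(self._lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __getitem__(self, chrom: str) -> int:
        return self._lengths[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeLayout) and self._lengths == other._lengths

    def __repr__(self) -> str:
        return f"GenomeLayout({self._lengths!r})"


class TagCollection:
    """Per-chromosome sorted 5'-end tag positions with strands.

    Positions are int64 arrays sorted ascending; strands are int8 arrays
    (+1 forward, -1 reverse) aligned with the positions.
    """

    def __init__(
        self,
        positions: Mapping[str, np.ndarray] | None = None,
        strands: Mapping[str, np.ndarray] | None = None,
    ):
        positions = positions or {}
        strands = strands or {}
        self._pos: Dict[str, np.ndarray] = {}
        self._strand: Dict[str, np.ndarray] = {}
        for chrom in positions:
            pos = np.asarray(positions[chrom], dtype=np.int64)
            if chrom in strands:
                strand = np.asarray(strands[chrom], dtype=np.int8)
            else:
                strand = np.ones(len(pos), dtype=np.int8)
            if len(pos) != len(strand):
                raise ValueError(f"positions/strands length mismatch on {chrom}")
            if len(pos) == 0:
                continue
            order = np.argsort(pos, kind="stable")
            self._pos[chrom] = pos[order]
            self._strand[chrom] = strand[order]

    @classmethod
    def from_records(
        cls, records: Iterable[Tuple[str, int, int]]
    ) -> "TagCollection":
        """Build from ``(chrom, position, strand)`` triples (strand +1/-1)."""
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, pos, strand in records:
            by_chrom.setdefault(chrom, []).append((pos, strand))
        positions = {}
        strands = {}
        for chrom, rows in by_chrom.items():
            positions[chrom] = np.array([r[0] for r in rows], dtype=np.int64)
            strands[chrom] = np.array([r[1] for r in rows], dtype=np.int8)
        return cls(positions, strands)

    @property
    def total_tags(self) -> int:
        return int(sum(len(p) for p in self._pos.values()))

    def chromosomes(self) -> List[str]:
        return sorted(self._pos)

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos.get(chrom, np.empty(0, dtype=np.int64))

    def strands(self, chrom: str) -> np.ndarray:
        return self._strand.get(chrom, np.empty(0, dtype=np.int8))

    def count(self, chrom: str) -> int:
        return len(self._pos.get(chrom, ()))

    def validate_against(self, layout: GenomeLayout) -> None:
        for chrom in self.chromosomes():
            if chrom not in layout:
                raise ValueError(f"tags on unknown chromosome {chrom!r}")
            pos = self._pos[chrom]
            if pos[0] < 0 or pos[-1] >= layout[chrom]:
                raise ValueError(
                    f"tag position outside chromosome {chrom!r} "
                    f"(length {layout[chrom]})"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TagCollection):
            return NotImplemented
        if self.chromosomes() != other.chromosomes():
            return False
        for chrom in self.chromosomes():
            if not np.array_equal(self._pos[chrom], other._pos[chrom]):
                return False
            if not np.array_equal(self._strand[chrom], other._strand[chrom]):
                return False
        return True

    def __repr__(self) -> str:
        return (
            f"TagCollection(total_tags={self.total_tags}, "
            f"chromosomes={self.chromosomes()})"
        )


@dataclass(frozen=True, order=True)
class GeneModel:
    """A gene reduced to its identifier, strand and TSS coordinate."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise AnnotationError("gene_id must be non-empty")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"unknown strand token {self.strand!r}")
        if self.tss < 0:
            raise AnnotationError(f"negative TSS {self.tss} for {self.gene_id}")


# ---------------------------------------------------------------------------
# readers / writers


def _iter_data_lines(path: str | Path) -> Iterator[Tuple[int, List[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split()


def read_tags_bed(path: str | Path) -> TagCollection:
    """Read aligned tags from a BED file (>= 3 columns, optional strand col 6).

    The 5' end is ``start`` for ``+``/unstranded records and ``end - 1`` for
    ``-`` records; unstranded records are treated as forward.
    """
    positions: Dict[str, List[int]] = {}
    strands: Dict[str, List[int]] = {}
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 3:
            raise BedParseError(f"{path}: line {lineno}: fewer than 3 BED columns")
        chrom = fields[0]
        try:
            start = int(fields[1])
            end = int(fields[2])
        except ValueError as exc:
            raise BedParseError(
                f"{path}: line {lineno}: non-integer coordinate"
            ) from exc
        if start < 0 or start >= end:
            raise BedParseError(
                f"{path}: line {lineno}: invalid record [{start},{end})"
            )
        strand_tok = fields[5] if len(fields) >= 6 else "."
        if strand_tok not in ("+", "-", "."):
            raise BedParseError(
                f"{path}: line {lineno}: unknown strand {strand_tok!r}"
            )
        if strand_tok == "-":
            positions.setdefault(chrom, []).append(end - 1)
            strands.setdefault(chrom, []).append(-1)
        else:
            positions.setdefault(chrom, []).append(start)
            strands.setdefault(chrom, []).append(1)
    return TagCollection(
        {c: np.array(v, dtype=np.int64) for c, v in positions.items()},
        {c: np.array(v, dtype=np.int8) for c, v in strands.items()},
    )


def write_tags_bed(tags: TagCollection, path: str | Path) -> None:
    """Write tags as 1 bp BED6 records that round-trip through read_tags_bed."""
    with open(path, "w") as fh:
        for chrom in tags.chromosomes():
            pos = tags.positions(chrom)
            strand = tags.strands(chrom)
            for p, s in zip(pos, strand):
                token = "+" if s > 0 else "-"
                fh.write(f"{chrom}\t{p}\t{p + 1}\t.\t0\t{token}\n")


def read_gene_annotation(path: str | Path) -> List[GeneModel]:
    """Read a minimal gene-annotation table.

    Two dialects are accepted, distinguished by column count:

    * 4 columns: ``gene_id  chrom  strand  tss`` (TSS already resolved);
    * 5+ columns (refFlat-like): ``gene_id  chrom  strand  txStart  txEnd``
      with TSS = ``txStart`` for ``+`` genes and ``txEnd - 1`` for ``-``.

    Duplicate gene ids raise :class:`AnnotationError`.
    """
    genes: List[GeneModel] = []
    seen: set[str] = set()
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 4:
            raise AnnotationError(
                f"{path}: line {lineno}: expected >= 4 tab-separated columns"
            )
        gene_id, chrom, strand = fields[0], fields[1], fields[2]
        if strand not in ("+", "-"):
            raise AnnotationError(
                f"{path}: line {lineno}: unknown strand token {strand!r}"
            )
        try:
            if len(fields) == 4:
                tss = int(fields[3])
            else:
                tx_start, tx_end = int(fields[3]), int(fields[4])
                tss = tx_start if strand == "+" else tx_end - 1
        except ValueError as exc:
            raise AnnotationError(
                f"{path}: line {lineno}: non-numeric coordinate"
            ) from exc
        if gene_id in seen:
            raise AnnotationError(
                f"{path}: line {lineno}: duplicate gene_id {gene_id!r}"
            )
        seen.add(gene_id)
        genes.append(GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, tss=tss))
    return genes


def write_gene_annotation(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\n")


def write_intervals_bed(
    intervals: Sequence[Tuple[GenomicInterval, float]] | Sequence[GenomicInterval],
    path: str | Path,
) -> None:
    """Write intervals as BED6; the score column carries -log10(p), capped at 1000.

    ``intervals`` is either a sequence of ``(interval, pvalue)`` pairs or bare
    intervals (score 0).
    """
    with open(path, "w") as fh:
        for i, item in enumerate(intervals, start=1):
            if isinstance(item, GenomicInterval):
                iv, score = item, 0.0
            else:
                iv, pvalue = item
                if pvalue <= 0:
                    score = 1000.0
                else:
                    score = min(1000.0, -float(np.log10(pvalue)))
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tregion_{i}\t{score:g}\t{iv.strand}\n"
            )


def read_intervals_bed(path: str | Path) -> List[GenomicInterval]:
    """Read BED intervals (coordinates and strand only)."""
    out: List[GenomicInterval] = []
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 3:
            raise BedParseError(f"{path}: line {lineno}: fewer than 3 BED columns")
        strand = fields[5] if len(fields) >= 6 else "."
        try:
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
        except ValueError as exc:
            raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
    return out


def read_genome_tsv(path: str | Path) -> GenomeLayout:
    """Read a two-column ``chrom<TAB>length`` genome layout table."""
    lengths: Dict[str, int] = {}
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 2:
            raise AnnotationError(f"{path}: line {lineno}: expected chrom and length")
        try:
            lengths[fields[0]] = int(fields[1])
        except ValueError as exc:
            raise AnnotationError(f"{path}: line {lineno}: non-numeric length") from exc
    return GenomeLayout(lengths)


def write_genome_tsv(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in layout:
            fh.write(f"{chrom}\t{layout[chrom]}\n")
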