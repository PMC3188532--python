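"""Core domain types shared by every pipeline stage.

All coordinates are 0-based half-open genomic intervals; conversion to and
from 1-based conventions (GTF) happens only at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def distance_to_point(self, pos: int) -> int:
        """Distance from the nearest base of the interval to ``pos`` (0 if inside)."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - (self.end - 1)
        return 0


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals per chromosome; strand is dropped to '.'."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


@dataclass
class GeneModel:
    """An annotated gene: span plus ordered, non-overlapping (flattened) exons.

    Genes with several transcripts are represented by the per-gene union of
    exons, which is also the exonic length used for RPKM.
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    transcript_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons unsorted or overlapping at {ex.start}"
                )
            if not self.interval.contains(ex):
                raise ValueError(
                    f"gene {self.gene_id}: exon {ex.start}-{ex.end} outside span "
                    f"{self.interval.start}-{self.interval.end}"
                )
            prev_end = ex.end

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out


@dataclass
class AlignmentRecord:
    """One aligned read (a single mate) as ordered genomic blocks.

    More than one block encodes a spliced alignment; the gap between
    consecutive blocks is an implied junction.
    """

    read_id: str
    mate: int
    blocks: list[GenomicInterval]
    unique: bool = True
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.mate not in (1, 2):
            raise ValueError(f"mate must be 1 or 2, got {self.mate}")
        if not self.blocks:
            raise ValueError(f"read {self.read_id} has no blocks")
        chrom = self.blocks[0].chrom
        prev_end = -1
        for b in self.blocks:
            if b.chrom != chrom:
                raise ValueError(f"read {self.read_id}: blocks on multiple chromosomes")
            if prev_end >= 0 and b.start < prev_end + 1:
                raise ValueError(
                    f"read {self.read_id}: blocks overlap or lack a >=1 bp gap"
                )
            prev_end = b.end

    @property
    def chrom(self) -> str:
        return self.blocks[0].chrom

    @property
    def start(self) -> int:
        return self.blocks[0].start

    @property
    def end(self) -> int:
        return self.blocks[-1].end

    @property
    def aligned_length(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def gaps(self) -> list[tuple[int, int]]:
        """(end of upstream block, start of downstream block) per junction."""
        return [(a.end, b.start) for a, b in zip(self.blocks, self.blocks[1:])]


@dataclass
class CoverageTrack:
    """Per-base read depth over one chromosome."""

    chrom: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    def __len__(self) -> int:
        return len(self.depth)


@dataclass(frozen=True)
class GwasHit:
    """A genome-wide association hit: SNP with Bonferroni-corrected P and trait."""

    snp_id: str
    chrom: str
    pos: int
    p_corrected: float
    trait: str

    def __post_init__(self) -> None:
        if not (0 < self.p_corrected <= 1):
            raise ValueError(f"p_corrected must be in (0,1], got {self.p_corrected}")


def flatten_gene_spans(genes: Sequence[GeneModel]) -> dict[str, GenomicInterval]:
    """One span per gene_id (union over records sharing an id)."""
    spans: dict[str, GenomicInterval] = {}
    for g in genes:
        iv = g.interval
        if g.gene_id in spans:
            prev = spans[g.gene_id]
            iv = GenomicInterval(
                prev.chrom,
                min(prev.start, iv.start),
                max(prev.end, iv.end),
                prev.strand,
            )
        spans[g.gene_id] = iv
    return spans
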