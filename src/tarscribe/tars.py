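"""Novel-transcript-unit discovery.

Per-base coverage from uniquely mapped reads -> maximal runs with depth >= 2
(transcriptionally active regions, TARs) -> TARs linked by read pairs into
transcript units -> units restricted to intergenic space (annotated gene
spans padded by 200 bp) with a continuous covered run >= 150 bp and average
coverage >= 2 -> adjacent units clustered within +/-3 kb into regions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import AlignmentRecord, CoverageTrack, GeneModel, GenomicInterval

DEFAULT_MIN_DEPTH = 2
DEFAULT_MIN_LEN = 150
DEFAULT_MIN_AVG_COV = 2.0
DEFAULT_MARGIN = 200
DEFAULT_CLUSTER_GAP = 3000


@dataclass
class Tar:
    """Maximal run of bases each covered by >= min_depth unique reads."""

    interval: GenomicInterval
    mean_depth: float


@dataclass
class TranscriptUnit:
    """Chain of TARs connected by paired-end (same-fragment) evidence."""

    tars: list[Tar]
    n_linking_pairs: int = 0

    @property
    def span(self) -> GenomicInterval:
        first, last = self.tars[0].interval, self.tars[-1].interval
        return GenomicInterval(first.chrom, first.start, last.end)

    @property
    def n_exons(self) -> int:
        return len(self.tars)

    @property
    def covered_length(self) -> int:
        return sum(len(t.interval) for t in self.tars)

    @property
    def max_run(self) -> int:
        """Longest contiguous covered run (= longest member TAR)."""
        return max(len(t.interval) for t in self.tars)

    @property
    def avg_coverage(self) -> float:
        """Mean depth over *covered* bases of the unit (gaps excluded)."""
        total = sum(t.mean_depth * len(t.interval) for t in self.tars)
        return total / self.covered_length


@dataclass
class TarRegion:
    """Cluster of transcript units whose spans lie within the cluster gap."""

    units: list[TranscriptUnit] = field(default_factory=list)

    @property
    def span(self) -> GenomicInterval:
        spans = [u.span for u in self.units]
        return GenomicInterval(spans[0].chrom, min(s.start for s in spans),
                               max(s.end for s in spans))


def compute_coverage(
    alignments: Sequence[AlignmentRecord], chrom_sizes: dict[str, int]
) -> dict[str, CoverageTrack]:
    """Per-base depth of unique-read blocks; multi-mapping reads are excluded."""
    diffs = {c: np.zeros(n + 1, dtype=np.int64) for c, n in chrom_sizes.items()}
    for rec in alignments:
        if not rec.unique:
            continue
        for b in rec.blocks:
            if b.chrom not in diffs:
                raise ValueError(f"block on unknown chromosome {b.chrom}")
            if b.end > chrom_sizes[b.chrom]:
                raise ValueError(
                    f"block {b.chrom}:{b.start}-{b.end} beyond chromosome length "
                    f"{chrom_sizes[b.chrom]}"
                )
            diffs[b.chrom][b.start] += 1
            diffs[b.chrom][b.end] -= 1
    return {
        c: CoverageTrack(c, np.cumsum(d[:-1])) for c, d in diffs.items()
    }


def call_tars(coverage: CoverageTrack, min_depth: int = DEFAULT_MIN_DEPTH) -> list[Tar]:
    """Maximal runs of depth >= min_depth, with their mean depth."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    depth = coverage.depth
    mask = depth >= min_depth
    if not mask.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False]))))
    starts, ends = edges[::2], edges[1::2]
    csum = np.concatenate(([0], np.cumsum(depth)))
    return [
        Tar(
            GenomicInterval(coverage.chrom, int(s), int(e)),
            float((csum[e] - csum[s]) / (e - s)),
        )
        for s, e in zip(starts, ends)
    ]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _tar_index(tars: Sequence[Tar]):
    """Per-chromosome sorted arrays for O(log n) block->TAR overlap lookup."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
    order: dict[str, list[int]] = {}
    for i, t in enumerate(tars):
        order.setdefault(t.interval.chrom, []).append(i)
    for chrom, idx in order.items():
        idx.sort(key=lambda i: tars[i].interval.start)
        starts = np.array([tars[i].interval.start for i in idx])
        ends = np.array([tars[i].interval.end for i in idx])
        by_chrom[chrom] = (starts, ends, idx)
    return by_chrom


def _overlapping_tars(index, block: GenomicInterval) -> list[int]:
    entry = index.get(block.chrom)
    if entry is None:
        return []
    starts, ends, idx = entry
    lo = int(np.searchsorted(ends, block.start, side="right"))
    hi = int(np.searchsorted(starts, block.end, side="left"))
    return [idx[k] for k in range(lo, hi)]


def link_tars(
    tars: Sequence[Tar], alignments: Sequence[AlignmentRecord]
) -> list[TranscriptUnit]:
    """Connect TARs into transcript units via read-fragment evidence.

    Two TARs are linked when the two mates of a unique read pair overlap
    them, or when blocks of a single spliced unique read do. Units are the
    connected components; an unlinked TAR becomes a single-exon unit.
    """
    if not tars:
        return []
    index = _tar_index(tars)
    uf = _UnionFind(len(tars))
    by_fragment: dict[str, set[int]] = {}
    for rec in alignments:
        if not rec.unique:
            continue
        touched: set[int] = set()
        for b in rec.blocks:
            touched.update(_overlapping_tars(index, b))
        if touched:
            by_fragment.setdefault(rec.read_id, set()).update(touched)
    n_links: dict[frozenset, int] = {}
    for touched in by_fragment.values():
        ordered = sorted(touched)
        for a, b in zip(ordered, ordered[1:]):
            uf.union(a, b)
        if len(ordered) > 1:
            key = frozenset(ordered)
            n_links[key] = n_links.get(key, 0) + 1
    groups: dict[int, list[int]] = {}
    for i in range(len(tars)):
        groups.setdefault(uf.find(i), []).append(i)
    units = []
    for members in groups.values():
        members.sort(key=lambda i: tars[i].interval.start)
        member_set = set(members)
        pairs = sum(n for key, n in n_links.items() if key <= member_set)
        units.append(TranscriptUnit([tars[i] for i in members], pairs))
    units.sort(key=lambda u: (u.span.chrom, u.span.start))
    return units


def define_intergenic(
    annotation: Sequence[GeneModel],
    chrom_sizes: dict[str, int],
    margin: int = DEFAULT_MARGIN,
) -> list[GenomicInterval]:
    """Complement of gene spans padded by ``margin`` bp on each side."""
    padded: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for g in annotation:
        if g.chrom not in padded:
            raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
        padded[g.chrom].append(
            (max(0, g.interval.start - margin), min(chrom_sizes[g.chrom], g.interval.end + margin))
        )
    out = []
    for chrom in sorted(chrom_sizes):
        length = chrom_sizes[chrom]
        cursor = 0
        for s, e in sorted(padded[chrom]):
            if s > cursor:
                out.append(GenomicInterval(chrom, cursor, s))
            cursor = max(cursor, e)
        if cursor < length:
            out.append(GenomicInterval(chrom, cursor, length))
    return out


def filter_novel_units(
    units: Sequence[TranscriptUnit],
    intergenic: Sequence[GenomicInterval],
    min_len: int = DEFAULT_MIN_LEN,
    min_avg_cov: float = DEFAULT_MIN_AVG_COV,
) -> list[TranscriptUnit]:
    """Units wholly intergenic with a covered run >= min_len and avg cov >= min_avg_cov."""
    kept = []
    for u in units:
        span = u.span
        if not any(iv.contains(span) for iv in intergenic):
            continue
        if u.max_run < min_len:
            continue
        if u.avg_coverage < min_avg_cov:
            continue
        kept.append(u)
    return kept


def cluster_units(
    units: Sequence[TranscriptUnit], gap: int = DEFAULT_CLUSTER_GAP
) -> list[TarRegion]:
    """Single-linkage merge of unit spans separated by <= gap bp (inclusive)."""
    if not units:
        return []
    units = sorted(units, key=lambda u: (u.span.chrom, u.span.start))
    regions: list[TarRegion] = []
    cur = TarRegion([units[0]])
    cur_end = units[0].span.end
    cur_chrom = units[0].span.chrom
    for u in units[1:]:
        s = u.span
        if s.chrom == cur_chrom and s.start - cur_end <= gap:
            cur.units.append(u)
            cur_end = max(cur_end, s.end)
        else:
            regions.append(cur)
            cur = TarRegion([u])
            cur_end = s.end
            cur_chrom = s.chrom
    regions.append(cur)
    return regions


def discover_novel_units(
    alignments: Sequence[AlignmentRecord],
    annotation: Sequence[GeneModel],
    chrom_sizes: dict[str, int],
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_len: int = DEFAULT_MIN_LEN,
    min_avg_cov: float = DEFAULT_MIN_AVG_COV,
    margin: int = DEFAULT_MARGIN,
    cluster_gap: int = DEFAULT_CLUSTER_GAP,
):
    """End-to-end novel-unit discovery; returns (tars, novel units, regions)."""
    coverage = compute_coverage(alignments, chrom_sizes)
    all_tars: list[Tar] = []
    for chrom in sorted(coverage):
        all_tars.extend(call_tars(coverage[chrom], min_depth))
    units = link_tars(all_tars, alignments)
    intergenic = define_intergenic(annotation, chrom_sizes, margin)
    novel = filter_novel_units(units, intergenic, min_len, min_avg_cov)
    regions = cluster_units(novel, cluster_gap)
    return all_tars, novel, regions
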