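"""Splice-junction validation and alternative-splicing classification.

Junctions are taken from the block gaps of spliced alignments, validated by
read support (>= 2 unambiguous reads, >= 5 bp aligned on both sides) and
classified against the annotation into the four analyzed event models:
exon skipping (ES), intron retention (IR), and alternative 5'/3' splice
sites (A5SS/A3SS).  Donor/acceptor orientation follows the gene strand.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .model import AlignmentRecord, CoverageTrack, GeneModel, GenomicInterval

MIN_INTRON_LEN = 20  # separates splice gaps from small deletions
DEFAULT_MIN_JUNC_READS = 2
DEFAULT_MIN_OVERHANG = 5

AS_TYPES = ("A5SS", "A3SS", "ES", "IR")


@dataclass
class Junction:
    """A splice gap: [donor_end, acceptor_start) in genomic orientation.

    ``donor_end`` is the (exclusive) end of the upstream block and
    ``acceptor_start`` the start of the downstream block, irrespective of
    strand; strand enters only at classification time.
    """

    chrom: str
    donor_end: int
    acceptor_start: int
    n_reads: int = 0
    max_overhang_left: int = 0
    max_overhang_right: int = 0

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.donor_end, self.acceptor_start)

    @property
    def intron_length(self) -> int:
        return self.acceptor_start - self.donor_end


@dataclass(frozen=True)
class ASEvent:
    """One classified alternative-splicing event anchored to a gene."""

    gene_id: str
    type: str
    coordinates: tuple
    evidence: tuple = ()
    sample: str = ""

    @property
    def key(self) -> tuple:
        return (self.gene_id, self.type, self.coordinates)


def extract_junctions(
    alignments: Iterable[AlignmentRecord], min_intron: int = MIN_INTRON_LEN
) -> list[Junction]:
    """Tally block gaps of unique reads into junctions with overhang maxima."""
    table: dict[tuple[str, int, int], Junction] = {}
    for rec in alignments:
        if not rec.unique:
            continue
        for i, (gap_start, gap_end) in enumerate(rec.gaps):
            if gap_end - gap_start < min_intron:
                continue
            key = (rec.chrom, gap_start, gap_end)
            j = table.get(key)
            if j is None:
                j = table[key] = Junction(rec.chrom, gap_start, gap_end)
            left = len(rec.blocks[i])
            right = len(rec.blocks[i + 1])
            j.n_reads += 1
            j.max_overhang_left = max(j.max_overhang_left, left)
            j.max_overhang_right = max(j.max_overhang_right, right)
    return sorted(table.values(), key=lambda j: j.key)


def validate_junctions(
    junctions: Iterable[Junction],
    min_reads: int = DEFAULT_MIN_JUNC_READS,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> list[Junction]:
    """Keep junctions with >= min_reads support and >= min_overhang on both sides."""
    return [
        j
        for j in junctions
        if j.n_reads >= min_reads
        and j.max_overhang_left >= min_overhang
        and j.max_overhang_right >= min_overhang
    ]


def assign_junctions(
    junctions: Sequence[Junction], annotation: Sequence[GeneModel]
) -> tuple[dict[str, list[Junction]], list[Junction]]:
    """Assign junctions to genes by span containment of the splice gap."""
    per_gene: dict[str, list[Junction]] = {g.gene_id: [] for g in annotation}
    unassigned: list[Junction] = []
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in annotation:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for j in junctions:
        hits = [
            g
            for g in genes_by_chrom.get(j.chrom, [])
            if g.interval.start <= j.donor_end and j.acceptor_start <= g.interval.end
        ]
        if hits:
            for g in hits:
                per_gene[g.gene_id].append(j)
        else:
            unassigned.append(j)
    return per_gene, unassigned


def classify_events(
    junctions: Sequence[Junction],
    annotation: Sequence[GeneModel],
    coverage: dict[str, CoverageTrack] | None = None,
    min_depth: int = 2,
    sample: str = "",
) -> tuple[list[ASEvent], list[Junction]]:
    """Classify validated junctions (plus coverage, for IR) into AS events.

    Returns (events, junctions overlapping no gene).  IR calls require a
    coverage dict; without one, IR detection is skipped.
    """
    per_gene, unassigned = assign_junctions(junctions, annotation)
    events: list[ASEvent] = []
    for g in sorted(annotation, key=lambda g: g.gene_id):
        jxns = sorted(per_gene[g.gene_id], key=lambda j: (j.donor_end, j.acceptor_start))
        exon_ends = {e.end: i for i, e in enumerate(g.exons)}
        exon_starts = {e.start: i for i, e in enumerate(g.exons)}

        # exon skipping: junction bridges exon i -> exon k with k-i >= 2
        for j in jxns:
            i = exon_ends.get(j.donor_end)
            k = exon_starts.get(j.acceptor_start)
            if i is not None and k is not None and k - i >= 2:
                for skipped in range(i + 1, k):
                    ex = g.exons[skipped]
                    events.append(
                        ASEvent(
                            g.gene_id,
                            "ES",
                            ((ex.start, ex.end),),
                            evidence=(j.key,),
                            sample=sample,
                        )
                    )

        # alternative splice sites: two junctions sharing one side.  Pairs in
        # which both junctions join annotated exon boundaries are annotation-
        # consistent splicing (canonical or exon skipping), not alternative
        # site usage, and are excluded here.
        def _consistent(j: Junction) -> bool:
            return j.donor_end in exon_ends and j.acceptor_start in exon_starts

        by_left: dict[int, list[Junction]] = {}
        by_right: dict[int, list[Junction]] = {}
        for j in jxns:
            by_left.setdefault(j.donor_end, []).append(j)
            by_right.setdefault(j.acceptor_start, []).append(j)
        for shared, group in sorted(by_left.items()):
            if len(group) < 2:
                continue
            # shared genomic-left side: on '+' the donor is shared -> acceptor
            # varies (A3SS); on '-' the mirrored case (A5SS)
            ev_type = "A3SS" if g.strand != "-" else "A5SS"
            group = sorted(group, key=lambda j: j.acceptor_start)
            for a, b in zip(group, group[1:]):
                if _consistent(a) and _consistent(b):
                    continue
                coords = ((a.donor_end, a.acceptor_start), (b.donor_end, b.acceptor_start))
                events.append(
                    ASEvent(g.gene_id, ev_type, coords, evidence=(a.key, b.key), sample=sample)
                )
        for shared, group in sorted(by_right.items()):
            if len(group) < 2:
                continue
            ev_type = "A5SS" if g.strand != "-" else "A3SS"
            group = sorted(group, key=lambda j: j.donor_end)
            for a, b in zip(group, group[1:]):
                if _consistent(a) and _consistent(b):
                    continue
                coords = ((a.donor_end, a.acceptor_start), (b.donor_end, b.acceptor_start))
                events.append(
                    ASEvent(g.gene_id, ev_type, coords, evidence=(a.key, b.key), sample=sample)
                )

        # intron retention: annotated intron fully covered, flanking exons
        # expressed, and no validated junction spanning it
        if coverage is not None and g.chrom in coverage:
            depth = coverage[g.chrom].depth
            for idx, intron in enumerate(g.introns):
                if (depth[intron.start:intron.end] >= min_depth).all():
                    left_ex, right_ex = g.exons[idx], g.exons[idx + 1]
                    left_ok = depth[left_ex.start:left_ex.end].mean() >= min_depth
                    right_ok = depth[right_ex.start:right_ex.end].mean() >= min_depth
                    spanned = any(
                        j.donor_end <= intron.start and j.acceptor_start >= intron.end
                        for j in jxns
                    )
                    if left_ok and right_ok and not spanned:
                        events.append(
                            ASEvent(
                                g.gene_id,
                                "IR",
                                ((intron.start, intron.end),),
                                evidence=(("coverage", intron.start, intron.end),),
                                sample=sample,
                            )
                        )
    return events, unassigned


def pool_events(event_sets: Sequence[Sequence[ASEvent]]):
    """Pool per-sample event lists, removing redundancy.

    Identity key = (gene_id, type, coordinates).  Returns (pooled events,
    per-gene distinct-event counts, distribution of events-per-gene).
    """
    seen: dict[tuple, ASEvent] = {}
    samples: dict[tuple, list[str]] = {}
    for events in event_sets:
        for ev in events:
            if ev.key not in seen:
                seen[ev.key] = ev
            if ev.sample and ev.sample not in samples.setdefault(ev.key, []):
                samples[ev.key].append(ev.sample)
    pooled = sorted(seen.values(), key=lambda e: (e.gene_id, e.type, e.coordinates))
    per_gene: dict[str, int] = {}
    for ev in pooled:
        per_gene[ev.gene_id] = per_gene.get(ev.gene_id, 0) + 1
    multiplicity: dict[int, int] = {}
    for n in per_gene.values():
        multiplicity[n] = multiplicity.get(n, 0) + 1
    return pooled, per_gene, multiplicity
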