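"""Read-supported gene models and 5'/3' boundary extensions.

TARs are attached to an annotated gene when they overlap its span, are
depth-contiguous with it, or are linked to an overlapping TAR by a mate
pair; the union of attached TARs with the annotated span is the potential
gene model, and its overhangs past the annotated ends are the reported
boundary extensions (strand-resolved).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .model import AlignmentRecord, GeneModel, GenomicInterval
from .tars import Tar, _UnionFind, _overlapping_tars, _tar_index

logger = logging.getLogger(__name__)


@dataclass
class ExtendedGeneModel:
    gene_id: str
    annotated: GenomicInterval
    extended: GenomicInterval
    pair_supported: bool = False


@dataclass
class BoundaryExtension:
    """Contiguous read support past an annotated gene end."""

    gene_id: str
    which_end: str  # "5'" or "3'"
    extension_bp: int
    supported_by_pairs: bool = False


def build_gene_models(
    tars: Sequence[Tar],
    alignments: Sequence[AlignmentRecord],
    annotation: Sequence[GeneModel],
) -> list[ExtendedGeneModel]:
    """Attach TARs to genes and return each gene's read-extended span.

    A TAR attachable to two genes goes to the gene with the nearer end; an
    exact tie leaves it unassigned (logged).
    """
    index = _tar_index(tars)
    uf = _UnionFind(len(tars))
    linked: dict[str, set[int]] = {}
    for rec in alignments:
        if not rec.unique:
            continue
        touched: set[int] = set()
        for b in rec.blocks:
            touched.update(_overlapping_tars(index, b))
        if touched:
            linked.setdefault(rec.read_id, set()).update(touched)
    pair_linked_ids: set[int] = set()
    for touched in linked.values():
        if len(touched) < 2:
            continue
        ordered = sorted(touched)
        for a, b in zip(ordered, ordered[1:]):
            uf.union(a, b)
        pair_linked_ids.update(ordered)

    spans = {g.gene_id: g.interval for g in annotation}
    # candidate assignment: TAR -> genes whose component it shares
    overlap_gene: dict[int, list[str]] = {}
    for g in annotation:
        for ti in _overlapping_tars(index, g.interval):
            overlap_gene.setdefault(ti, []).append(g.gene_id)
    comp_genes: dict[int, set[str]] = {}
    for ti, gids in overlap_gene.items():
        comp_genes.setdefault(uf.find(ti), set()).update(gids)

    assigned: dict[int, str] = {}
    for i, t in enumerate(tars):
        direct = overlap_gene.get(i, [])
        if len(direct) == 1:
            assigned[i] = direct[0]
            continue
        if len(direct) > 1:
            # overlaps several genes: ambiguous, leave with all (span union is
            # bounded by the genes themselves, no extension credit)
            continue
        candidates = sorted(comp_genes.get(uf.find(i), ()))
        if not candidates:
            continue
        if len(candidates) == 1:
            assigned[i] = candidates[0]
            continue
        dists = []
        for gid in candidates:
            sp = spans[gid]
            d = min(abs(t.interval.start - sp.end), abs(sp.start - t.interval.end))
            dists.append((d, gid))
        dists.sort()
        if len(dists) > 1 and dists[0][0] == dists[1][0]:
            logger.info(
                "TAR %s:%d-%d equidistant from %s and %s; unassigned",
                t.interval.chrom, t.interval.start, t.interval.end,
                dists[0][1], dists[1][1],
            )
            continue
        assigned[i] = dists[0][1]

    models = []
    for g in sorted(annotation, key=lambda g: (g.chrom, g.interval.start)):
        sp = g.interval
        lo, hi = sp.start, sp.end
        pair_supported = False
        for i, gid in assigned.items():
            if gid != g.gene_id:
                continue
            t = tars[i]
            if t.interval.start < lo or t.interval.end > hi:
                if i in pair_linked_ids and not overlap_gene.get(i):
                    pair_supported = True
            lo = min(lo, t.interval.start)
            hi = max(hi, t.interval.end)
        models.append(
            ExtendedGeneModel(
                g.gene_id, sp, GenomicInterval(sp.chrom, lo, hi, sp.strand), pair_supported
            )
        )
    return models


def detect_extensions(
    models: Sequence[ExtendedGeneModel], min_report: int = 1
) -> list[BoundaryExtension]:
    """Strand-resolved 5'/3' extensions of at least ``min_report`` bp."""
    out = []
    for m in models:
        left = m.annotated.start - m.extended.start
        right = m.extended.end - m.annotated.end
        if m.annotated.strand == "-":
            five, three = right, left
        else:
            five, three = left, right
        if five >= min_report:
            out.append(BoundaryExtension(m.gene_id, "5'", five, m.pair_supported))
        if three >= min_report:
            out.append(BoundaryExtension(m.gene_id, "3'", three, m.pair_supported))
    return out


def summarize_extensions(
    extensions: Sequence[BoundaryExtension], min_bp: int = 50
) -> dict[str, int]:
    """Tally genes extended at the 5' end, 3' end and both (at >= min_bp)."""
    five = {e.gene_id for e in extensions if e.which_end == "5'" and e.extension_bp >= min_bp}
    three = {e.gene_id for e in extensions if e.which_end == "3'" and e.extension_bp >= min_bp}
    return {
        "five_prime": len(five),
        "three_prime": len(three),
        "both_ends": len(five & three),
    }
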