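"""Small-RNA tag processing.

Adapter trimming and 18-30 nt length selection, an annotation filter
cascade (structural RNAs, repeats and exonic tags are excluded before
miRNA analysis), known-miRNA matching with at most two substitutions and a
small terminal-shift tolerance, TPM normalization and abundance summaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

MIN_TAG_LEN = 18
MAX_TAG_LEN = 30
DEFAULT_MAX_MISMATCH = 2
MAX_END_SHIFT = 2

# fixed cascade priority; categories before "intron" are excluded from
# miRNA analysis (structural/annotated RNA first, then repeats and exons)
CASCADE_ORDER = ("rRNA", "tRNA", "scRNA", "snRNA", "snoRNA", "repeat", "exon", "intron")
EXCLUDED_CATEGORIES = frozenset(("rRNA", "tRNA", "scRNA", "snRNA", "snoRNA", "repeat", "exon"))


@dataclass
class SmallRnaTag:
    sequence: str
    count: int
    category: str = "unannotated"


@dataclass
class MirnaQuant:
    mirna_id: str
    count: float
    tpm: float
    ambiguous: bool = False


def _normalize(seq: str) -> str:
    return seq.strip().upper().replace("U", "T")


def clean_tags(
    raw: Sequence[tuple[str, int]],
    adapter: str | None = None,
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
) -> list[SmallRnaTag]:
    """Trim the 3' adapter, keep 18-30 nt inserts, collapse duplicates.

    The insert ends at the earliest position from which the remainder of
    the read is an exact prefix of the adapter.
    """
    adapter = _normalize(adapter) if adapter else None
    collapsed: dict[str, int] = {}
    for seq, count in raw:
        seq = _normalize(seq)
        if adapter:
            cut = len(seq)
            for i in range(len(seq)):
                tail = seq[i:]
                if adapter.startswith(tail) or tail.startswith(adapter):
                    cut = i
                    break
            seq = seq[:cut]
        if not (min_len <= len(seq) <= max_len):
            continue
        collapsed[seq] = collapsed.get(seq, 0) + count
    return [SmallRnaTag(s, c) for s, c in sorted(collapsed.items())]


def length_distribution(tags: Sequence[SmallRnaTag]) -> dict:
    """Read-weighted length histogram with modal length and 20-23 nt mass."""
    hist = {length: 0 for length in range(MIN_TAG_LEN, MAX_TAG_LEN + 1)}
    total = 0
    for t in tags:
        hist[len(t.sequence)] += t.count
        total += t.count
    mode = max(hist, key=lambda length: (hist[length], -length)) if total else None
    mass_20_23 = sum(hist[length] for length in range(20, 24)) / total if total else 0.0
    return {"histogram": hist, "mode": mode, "fraction_20_23": mass_20_23, "total": total}


def annotate_cascade(
    tags: Sequence[SmallRnaTag], category_refs: Mapping[str, Sequence[str]]
) -> list[SmallRnaTag]:
    """Assign each tag the first matching category in the fixed priority order.

    A tag matches a category when its sequence is an exact substring of any
    reference sequence of that category.  Tags matching nothing are
    ``unannotated`` and retained for miRNA analysis.
    """
    refs = {
        cat: [_normalize(s) for s in seqs] for cat, seqs in category_refs.items()
    }
    out = []
    for t in tags:
        category = "unannotated"
        for cat in CASCADE_ORDER:
            if any(t.sequence in ref for ref in refs.get(cat, ())):
                category = cat
                break
        out.append(SmallRnaTag(t.sequence, t.count, category))
    return out


def retained_for_mirna(tags: Sequence[SmallRnaTag]) -> list[SmallRnaTag]:
    """Tags surviving the exclusion cascade (intronic or unannotated)."""
    return [t for t in tags if t.category not in EXCLUDED_CATEGORIES]


def tag_distance(tag: str, mature: str, max_shift: int = MAX_END_SHIFT) -> int | None:
    """Substitution distance between a tag and a mature miRNA.

    Sequences whose lengths differ by more than ``max_shift`` never match.
    The shorter sequence may slide by up to ``max_shift`` positions against
    the longer one (terminal isomiR tolerance); the distance is the minimum
    Hamming distance over the overlap, with unaligned overhang bases free.
    """
    a, b = _normalize(tag), _normalize(mature)
    if abs(len(a) - len(b)) > max_shift:
        return None
    if len(a) > len(b):
        a, b = b, a
    best = None
    for off in range(0, len(b) - len(a) + 1):
        if off > max_shift:
            break
        d = sum(1 for i, ch in enumerate(a) if ch != b[off + i])
        if best is None or d < best:
            best = d
    return best


def match_known(
    tags: Sequence[SmallRnaTag],
    mature_db: Mapping[str, str],
    clean_total: int,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> tuple[list[MirnaQuant], list[SmallRnaTag]]:
    """Assign tags to the nearest mature miRNA within ``max_mismatch``.

    Ties split the tag count evenly across the tied miRNAs (flagged
    ambiguous).  Returns (per-miRNA quantities with TPM on the clean-read
    total, unmatched tags).
    """
    counts: dict[str, float] = {m: 0.0 for m in mature_db}
    ambiguous: set[str] = set()
    unmatched = []
    for t in tags:
        best_d: int | None = None
        best_ids: list[str] = []
        for mid, mseq in mature_db.items():
            d = tag_distance(t.sequence, mseq)
            if d is None or d > max_mismatch:
                continue
            if best_d is None or d < best_d:
                best_d, best_ids = d, [mid]
            elif d == best_d:
                best_ids.append(mid)
        if best_d is None:
            unmatched.append(t)
            continue
        share = t.count / len(best_ids)
        for mid in best_ids:
            counts[mid] += share
            if len(best_ids) > 1:
                ambiguous.add(mid)
    quants = [
        MirnaQuant(mid, c, c * 1e6 / clean_total if clean_total else 0.0, mid in ambiguous)
        for mid, c in counts.items()
        if c > 0
    ]
    quants.sort(key=lambda q: (-q.tpm, q.mirna_id))
    return quants, unmatched


def top_expressed(quants: Sequence[MirnaQuant], clean_total: int, k: int = 20) -> dict:
    """Top-k miRNAs by TPM with their cumulative clean-read fraction."""
    if not quants:
        raise ValueError("no miRNA quantities to rank")
    ranked = sorted(quants, key=lambda q: (-q.tpm, q.mirna_id))[:k]
    cum = sum(q.count for q in ranked)
    return {
        "top": [(q.mirna_id, q.count, q.tpm) for q in ranked],
        "cumulative_fraction": cum / clean_total if clean_total else 0.0,
    }


def mirna_quant_table(quants: Sequence[MirnaQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna_id": [q.mirna_id for q in quants],
            "count": [q.count for q in quants],
            "tpm": [q.tpm for q in quants],
            "ambiguous": [q.ambiguous for q in quants],
        }
    )
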