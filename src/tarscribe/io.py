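"""Readers and writers for the formats the pipeline touches.

GTF (1-based, inclusive) and BED12 (0-based, half-open) annotation, BED12 or
minimal SAM alignments, FASTA via Biopython, and headered TSV tables via
pandas.  Internal coordinates are always 0-based half-open.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import AlignmentRecord, GeneModel, GenomicInterval, GwasHit, merge_intervals

logger = logging.getLogger(__name__)

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

# SAM CIGAR operations that consume the reference
_REF_OPS = {0: "M", 2: "D", 3: "N", 7: "=", 8: "X"}


class ParseError(ValueError):
    """Malformed record in an input file; message names the line number."""


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path, format: str = "gtf") -> list[GeneModel]:
    """Read gene models from GTF or BED12.

    GTF exon records are grouped by ``gene_id`` and flattened to the per-gene
    union of exons; 1-based inclusive coordinates become 0-based half-open.
    """
    if format == "gtf":
        return _read_gtf(Path(path))
    if format == "bed12":
        return _read_bed12_genes(Path(path))
    raise ValueError(f"unknown annotation format {format!r}")


def _read_gtf(path: Path) -> list[GeneModel]:
    exons: dict[str, list[GenomicInterval]] = {}
    tx_ids: dict[str, list[str]] = {}
    n_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            attr = dict(_GTF_ATTR_RE.findall(attrs))
            gid = attr.get("gene_id")
            if gid is None:
                raise ParseError(f"{path}:{lineno}: exon without gene_id attribute")
            n_records += 1
            # GTF is 1-based inclusive
            exons.setdefault(gid, []).append(
                GenomicInterval(chrom, start_i - 1, end_i, strand)
            )
            tid = attr.get("transcript_id")
            if tid and tid not in tx_ids.setdefault(gid, []):
                tx_ids[gid].append(tid)
    if n_records == 0:
        logger.warning("annotation file %s contains no exon records", path)
        return []
    genes = []
    for gid in exons:
        strand = exons[gid][0].strand
        chrom = exons[gid][0].chrom
        flat = merge_intervals(exons[gid])
        flat = [GenomicInterval(e.chrom, e.start, e.end, strand) for e in flat]
        span = GenomicInterval(chrom, flat[0].start, flat[-1].end, strand)
        genes.append(GeneModel(gid, span, flat, tx_ids.get(gid, [])))
    genes.sort(key=lambda g: (g.chrom, g.interval.start, g.gene_id))
    return genes


def _parse_bed12_line(path: Path, lineno: int, line: str):
    fields = line.split("\t")
    if len(fields) < 12:
        raise ParseError(f"{path}:{lineno}: expected >=12 BED12 columns, got {len(fields)}")
    try:
        chrom = fields[0]
        start, end = int(fields[1]), int(fields[2])
        name = fields[3]
        score = fields[4]
        strand = fields[5] if fields[5] in ("+", "-", ".") else "."
        n_blocks = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: malformed BED12 fields") from exc
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise ParseError(f"{path}:{lineno}: blockCount disagrees with block lists")
    blocks = [
        GenomicInterval(chrom, start + off, start + off + size, strand)
        for off, size in zip(offsets, sizes)
    ]
    if blocks[-1].end != end:
        raise ParseError(f"{path}:{lineno}: last block does not reach chromEnd")
    return chrom, start, end, name, score, strand, blocks, fields


def _read_bed12_genes(path: Path) -> list[GeneModel]:
    genes = []
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, _score, strand, blocks, _ = _parse_bed12_line(
                path, lineno, line
            )
            n += 1
            span = GenomicInterval(chrom, start, end, strand)
            genes.append(GeneModel(name, span, blocks, [name]))
    if n == 0:
        logger.warning("annotation file %s is empty", path)
    genes.sort(key=lambda g: (g.chrom, g.interval.start, g.gene_id))
    return genes


def write_annotation(genes: Sequence[GeneModel], path: str | Path, format: str = "gtf") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if format == "gtf":
            for g in genes:
                tid = g.transcript_ids[0] if g.transcript_ids else f"{g.gene_id}.t1"
                for ex in g.exons:
                    attrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}";'
                    fh.write(
                        "\t".join(
                            [
                                g.chrom,
                                "tarscribe",
                                "exon",
                                str(ex.start + 1),
                                str(ex.end),
                                ".",
                                g.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )
        elif format == "bed12":
            for g in genes:
                s = g.interval.start
                sizes = ",".join(str(len(e)) for e in g.exons)
                offs = ",".join(str(e.start - s) for e in g.exons)
                fh.write(
                    "\t".join(
                        [
                            g.chrom,
                            str(s),
                            str(g.interval.end),
                            g.gene_id,
                            "0",
                            g.strand,
                            str(s),
                            str(g.interval.end),
                            "0",
                            str(len(g.exons)),
                            sizes,
                            offs,
                        ]
                    )
                    + "\n"
                )
        else:
            raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def cigar_to_blocks(pos: int, cigartuples: Iterable[tuple[int, int]], chrom: str,
                    strand: str = ".") -> list[GenomicInterval]:
    """Reference blocks of an alignment starting at 0-based ``pos``.

    M/=/X/D extend the current block; N closes it (a splice gap); I/S/H/P do
    not consume reference.
    """
    blocks: list[GenomicInterval] = []
    cur_start = pos
    cur = pos
    for op, length in cigartuples:
        if op in (0, 2, 7, 8):  # M, D, =, X
            cur += length
        elif op == 3:  # N
            if cur > cur_start:
                blocks.append(GenomicInterval(chrom, cur_start, cur, strand))
            cur += length
            cur_start = cur
        elif op in (1, 4, 5, 6):  # I, S, H, P
            continue
        else:
            raise ValueError(f"unsupported CIGAR op code {op}")
    if cur > cur_start:
        blocks.append(GenomicInterval(chrom, cur_start, cur, strand))
    return blocks


def read_alignments(
    path: str | Path,
    format: str = "bed12",
    min_mapq: int = 20,
    chrom_sizes: dict[str, int] | None = None,
) -> list[AlignmentRecord]:
    """Read alignments from BED12 (one read per line) or minimal SAM.

    BED12: the read name carries the mate as a ``/1`` / ``/2`` suffix, the
    score column holds the mismatch count, and an optional 13th column holds
    the uniqueness flag (default unique).

    SAM: secondary/supplementary/unmapped records are dropped; a record is
    *unique* when its MAPQ >= ``min_mapq`` and it carries no XA tag.
    """
    if format == "bed12":
        records = _read_bed12_reads(Path(path))
    elif format == "sam":
        records = _read_sam(Path(path), min_mapq)
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    if chrom_sizes is not None:
        unknown = sorted({r.chrom for r in records} - set(chrom_sizes))
        if unknown:
            raise ValueError(f"alignments on unknown chromosomes: {', '.join(unknown)}")
    return records


def _read_bed12_reads(path: Path) -> list[AlignmentRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, _s, _e, name, score, strand, blocks, fields = _parse_bed12_line(
                path, lineno, line
            )
            if name.endswith(("/1", "/2")):
                read_id, mate = name[:-2], int(name[-1])
            else:
                read_id, mate = name, 1
            unique = True
            if len(fields) > 12:
                unique = fields[12] not in ("0", "false", "False")
            try:
                mismatches = int(score)
            except ValueError:
                mismatches = 0
            records.append(AlignmentRecord(read_id, mate, blocks, unique, mismatches))
    return records


def _read_sam(path: Path, min_mapq: int) -> list[AlignmentRecord]:
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            blocks = cigar_to_blocks(
                aln.reference_start, aln.cigartuples or [], aln.reference_name
            )
            if not blocks:
                continue
            mate = 2 if aln.is_paired and aln.is_read2 else 1
            unique = aln.mapping_quality >= min_mapq and not aln.has_tag("XA")
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            records.append(AlignmentRecord(aln.query_name, mate, blocks, unique, int(nm)))
    return records


def write_alignments_bed12(records: Sequence[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            s = r.blocks[0].start
            sizes = ",".join(str(len(b)) for b in r.blocks)
            offs = ",".join(str(b.start - s) for b in r.blocks)
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(s),
                        str(r.blocks[-1].end),
                        f"{r.read_id}/{r.mate}",
                        str(r.mismatches),
                        r.blocks[0].strand,
                        str(s),
                        str(r.blocks[-1].end),
                        "0",
                        str(len(r.blocks)),
                        sizes,
                        offs,
                        "1" if r.unique else "0",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA / TSV / GWAS
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_counts(path: str | Path) -> pd.Series:
    """Gene-level counts from a headered two-column TSV (gene_id, count)."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="count")


def write_counts(counts: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"gene_id": counts.index, "count": counts.values}).to_csv(
        path, sep="\t", index=False
    )


def read_gwas(path: str | Path) -> list[GwasHit]:
    df = pd.read_csv(path, sep="\t")
    return [
        GwasHit(str(r.snp_id), str(r.chrom), int(r.pos), float(r.p_corrected), str(r.trait))
        for r in df.itertuples()
    ]


def write_gwas(hits: Sequence[GwasHit], path: str | Path) -> None:
    pd.DataFrame(
        {
            "snp_id": [h.snp_id for h in hits],
            "chrom": [h.chrom for h in hits],
            "pos": [h.pos for h in hits],
            "p_corrected": [h.p_corrected for h in hits],
            "trait": [h.trait for h in hits],
        }
    ).to_csv(path, sep="\t", index=False)
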