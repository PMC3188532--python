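"""Seeded synthetic-data generator with machine-readable planted truth.

Emits a toy single-chromosome genome annotation, spliced paired-end
alignments realizing planted novel transcript units, alternative-splicing
events, gene-boundary extensions, two-condition Poisson count tables with
planted fold changes, and 18-30 nt small-RNA tags — everything a downstream
stage needs to demonstrate recovery of known truth.

Reads are emitted directly as alignments (mapping is upstream of this
pipeline); the read-start model is Poisson-uniform within each expressed
isoform, with a handful of deterministic reads added so that every planted
junction has guaranteed support and every planted retained intron has
guaranteed full coverage (Poisson sampling alone cannot promise either at
finite depth).
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import AlignmentRecord, GeneModel, GenomicInterval, GwasHit

BASES = np.array(list("ACGT"))
MIN_TAG, MAX_TAG = 18, 30


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic transcriptome.

    Defaults mirror the sequencing design the pipeline assumes: 90 bp
    paired-end reads with a 200 bp insert, ~10x expressed-base depth on a
    1 Mb genome, two-condition Poisson counts with mean 50 and planted
    |log2 fold change| 1.5 on 10% of genes, and small-RNA tags of 18-30 nt
    with a 22 nt mode.
    """

    seed: int = 0
    genome_length: int = 1_000_000
    n_genes: int = 60
    n_novel_units: int = 50
    read_length: int = 90
    fragment_size: int = 200
    depth_mean: float = 10.0
    as_events_per_type: int = 10
    n_boundary_extensions: int = 12
    de_fraction: float = 0.1
    de_log2fc: float = 1.5
    n_count_genes: int = 2000
    count_mean: float = 50.0
    n_tags: int = 10_000
    n_mature: int = 30
    mature_fraction: float = 0.5
    tag_modal_length: int = 22
    multi_map_fraction: float = 0.01
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        for name in (
            "genome_length", "n_genes", "n_novel_units", "read_length",
            "fragment_size", "as_events_per_type", "n_boundary_extensions",
            "n_count_genes", "n_tags", "n_mature",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {self.chrom: self.genome_length}


@dataclass
class PlantedTruth:
    """Ground truth for every planted feature, keyed to the emitted files."""

    novel_units: list[dict] = field(default_factory=list)
    as_events: list[dict] = field(default_factory=list)
    extensions: list[dict] = field(default_factory=list)
    de_genes: list[dict] = field(default_factory=list)
    smallrna: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            return cls(**json.load(fh))

    def as_event_keys(self) -> set[tuple]:
        return {
            (ev["gene_id"], ev["type"], tuple(tuple(c) for c in ev["coordinates"]))
            for ev in self.as_events
        }


class PlacementError(RuntimeError):
    pass


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), stream])


# ---------------------------------------------------------------------------
# annotation + planted features
# ---------------------------------------------------------------------------

def generate_annotation(config: SimulationConfig) -> tuple[list[GeneModel], PlantedTruth]:
    """Place non-overlapping genes and intergenic novel units, plant AS
    events, boundary extensions and novel-unit truth.

    Features are separated by > 3 kb so that planted units remain distinct
    after clustering and the 200 bp intergenic margins are realizable.
    """
    rng = _rng(config, 1)
    truth = PlantedTruth()
    plan = ["gene"] * config.n_genes + ["unit"] * config.n_novel_units
    rng.shuffle(plan)

    genes: list[GeneModel] = []
    cursor = int(rng.integers(500, 1500))
    gene_i = unit_i = 0
    for kind in plan:
        if kind == "gene":
            n_ex = int(rng.integers(2, 9))
            exon_lens = rng.integers(120, 301, size=n_ex)
            intron_lens = rng.integers(150, 401, size=n_ex - 1)
            strand = "+" if rng.integers(2) else "-"
            exons = []
            pos = cursor
            for i in range(n_ex):
                exons.append(GenomicInterval(config.chrom, pos, pos + int(exon_lens[i]), strand))
                pos += int(exon_lens[i])
                if i < n_ex - 1:
                    pos += int(intron_lens[i])
            gid = f"g{gene_i:04d}"
            gene_i += 1
            span = GenomicInterval(config.chrom, cursor, pos, strand)
            genes.append(GeneModel(gid, span, exons, [f"{gid}.t1"]))
            cursor = pos
        else:
            n_blocks = int(rng.integers(1, 4))
            lens = [int(rng.integers(400, 601))] + [
                int(rng.integers(150, 301)) for _ in range(n_blocks - 1)
            ]
            gaps = [int(rng.integers(80, 151)) for _ in range(n_blocks - 1)]
            blocks = []
            pos = cursor
            for i, L in enumerate(lens):
                blocks.append((pos, pos + L))
                pos += L
                if i < n_blocks - 1:
                    pos += gaps[i]
            truth.novel_units.append(
                {
                    "unit_id": f"nu{unit_i:04d}",
                    "span": [cursor, pos],
                    "blocks": [list(b) for b in blocks],
                }
            )
            unit_i += 1
            cursor = pos
        cursor += int(rng.integers(3200, 4801))
        if cursor > config.genome_length - 600:
            raise PlacementError(
                f"features exceed genome_length={config.genome_length}; "
                "increase genome_length or reduce feature counts"
            )

    _plant_as_events(config, rng, genes, truth)
    _plant_extensions(config, rng, genes, truth)
    return genes, truth


def _plant_as_events(config, rng, genes: list[GeneModel], truth: PlantedTruth) -> None:
    k = config.as_events_per_type
    if k == 0:
        return
    multi_exon = [g for g in genes if len(g.exons) >= 3]
    two_exon_ok = [g for g in genes if len(g.exons) >= 2]
    if len(multi_exon) < k:
        raise PlacementError("not enough >=3-exon genes for exon-skipping events")
    rng.shuffle(multi_exon)
    es_genes = multi_exon[:k]
    used = {g.gene_id for g in es_genes}
    pool = [g for g in two_exon_ok if g.gene_id not in used]
    if len(pool) < 3 * k + config.n_boundary_extensions:
        raise PlacementError("not enough genes to host planted events; raise n_genes")
    rng.shuffle(pool)
    a5_genes, a3_genes, ir_genes = pool[:k], pool[k : 2 * k], pool[2 * k : 3 * k]

    for g in es_genes:
        sk = int(rng.integers(1, len(g.exons) - 1))
        ex = g.exons[sk]
        truth.as_events.append(
            {
                "gene_id": g.gene_id,
                "type": "ES",
                "coordinates": [[ex.start, ex.end]],
                "skip_junction": [g.exons[sk - 1].end, g.exons[sk + 1].start],
                "exon_index": sk,
            }
        )
    for g, ev_type in [(g, "A5SS") for g in a5_genes] + [(g, "A3SS") for g in a3_genes]:
        i = int(rng.integers(0, len(g.exons) - 1))
        delta = int(rng.integers(10, 31))
        canonical = (g.exons[i].end, g.exons[i + 1].start)
        # the *donor* varies for A5SS, the *acceptor* for A3SS; which genomic
        # side that is depends on strand
        vary_left = (ev_type == "A5SS") == (g.strand != "-")
        if vary_left:
            variant = (canonical[0] - delta, canonical[1])
        else:
            variant = (canonical[0], canonical[1] + delta)
        coords = sorted([list(canonical), list(variant)])
        truth.as_events.append(
            {
                "gene_id": g.gene_id,
                "type": ev_type,
                "coordinates": coords,
                "intron_index": i,
                "variant_junction": list(variant),
            }
        )
    for g in ir_genes:
        i = int(rng.integers(0, len(g.exons) - 1))
        intron = g.introns[i]
        truth.as_events.append(
            {
                "gene_id": g.gene_id,
                "type": "IR",
                "coordinates": [[intron.start, intron.end]],
                "intron_index": i,
            }
        )


def _plant_extensions(config, rng, genes: list[GeneModel], truth: PlantedTruth) -> None:
    if config.n_boundary_extensions == 0:
        return
    used = {ev["gene_id"] for ev in truth.as_events}
    pool = [g for g in genes if g.gene_id not in used]
    if len(pool) < config.n_boundary_extensions:
        raise PlacementError("not enough genes left for boundary extensions")
    rng.shuffle(pool)
    chosen = pool[: config.n_boundary_extensions]
    for idx, g in enumerate(chosen):
        if idx % 3 == 0:
            ends = ["5'", "3'"]
        else:
            ends = ["5'" if rng.integers(2) else "3'"]
        for end in ends:
            truth.extensions.append(
                {
                    "gene_id": g.gene_id,
                    "end": end,
                    "length": int(rng.integers(60, 501)),
                }
            )


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass
class _Isoform:
    iso_id: str
    blocks: list[tuple[int, int]]  # genomic, sorted, contiguous-in-transcript
    depth: float
    strand: str = "."
    guarantee_junctions: list[tuple[int, int]] = field(default_factory=list)
    tile_regions: list[tuple[int, int]] = field(default_factory=list)  # padded by 50 bp
    exact_tiles: list[tuple[int, int]] = field(default_factory=list)  # tiled as given

    @property
    def tx_len(self) -> int:
        return sum(e - s for s, e in self.blocks)


def planted_isoforms(
    annotation: Sequence[GeneModel], truth: PlantedTruth, config: SimulationConfig
) -> list[_Isoform]:
    """Expressed isoforms realizing the planted truth (deterministic)."""
    as_by_gene = {ev["gene_id"]: ev for ev in truth.as_events}
    ext_by_gene: dict[str, dict[str, int]] = {}
    for ext in truth.extensions:
        ext_by_gene.setdefault(ext["gene_id"], {})[ext["end"]] = ext["length"]

    isoforms: list[_Isoform] = []
    for g in annotation:
        exons = [(e.start, e.end) for e in g.exons]
        ev = as_by_gene.get(g.gene_id)
        if ev is None:
            exact_tiles: list[tuple[int, int]] = []
            if g.gene_id in ext_by_gene:
                exts = ext_by_gene[g.gene_id]
                left = exts.get("5'" if g.strand != "-" else "3'", 0)
                right = exts.get("3'" if g.strand != "-" else "5'", 0)
                ann_start, ann_end = g.interval.start, g.interval.end
                s0, e0 = exons[0]
                exons[0] = (s0 - left, e0)
                sN, eN = exons[-1]
                exons[-1] = (sN, eN + right)
                if len(exons) == 1:
                    exons[0] = (s0 - left, e0 + right)
                # contiguous-coverage guarantee over the planted extension,
                # anchored 50 bp into the annotated gene body
                if left:
                    exact_tiles.append((ann_start - left, ann_start + 50))
                if right:
                    exact_tiles.append((ann_end - 50, ann_end + right))
            isoforms.append(
                _Isoform(
                    f"{g.gene_id}.c", exons, config.depth_mean, g.strand,
                    exact_tiles=exact_tiles,
                )
            )
        elif ev["type"] == "ES":
            sk = ev["exon_index"]
            skip = exons[:sk] + exons[sk + 1:]
            isoforms.append(
                _Isoform(f"{g.gene_id}.c", exons, config.depth_mean / 2, g.strand)
            )
            isoforms.append(
                _Isoform(
                    f"{g.gene_id}.skip", skip, config.depth_mean / 2, g.strand,
                    guarantee_junctions=[tuple(ev["skip_junction"])],
                )
            )
        elif ev["type"] in ("A5SS", "A3SS"):
            i = ev["intron_index"]
            canonical_j = (exons[i][1], exons[i + 1][0])
            vs, ve = ev["variant_junction"]
            variant = list(exons)
            if vs != canonical_j[0]:
                variant[i] = (variant[i][0], vs)
            else:
                variant[i + 1] = (ve, variant[i + 1][1])
            isoforms.append(
                _Isoform(
                    f"{g.gene_id}.c", exons, config.depth_mean / 2, g.strand,
                    guarantee_junctions=[canonical_j],
                )
            )
            isoforms.append(
                _Isoform(
                    f"{g.gene_id}.alt", variant, config.depth_mean / 2, g.strand,
                    guarantee_junctions=[(vs, ve)],
                )
            )
        else:  # IR
            i = ev["intron_index"]
            retained = (
                exons[:i] + [(exons[i][0], exons[i + 1][1])] + exons[i + 2:]
            )
            isoforms.append(
                _Isoform(
                    f"{g.gene_id}.ir", retained, config.depth_mean, g.strand,
                    tile_regions=[tuple(ev["coordinates"][0])],
                )
            )
    for nu in truth.novel_units:
        isoforms.append(
            _Isoform(
                nu["unit_id"] + ".c",
                [tuple(b) for b in nu["blocks"]],
                config.depth_mean,
            )
        )
    return isoforms


def _project(blocks: Sequence[tuple[int, int]], a: int, b: int, chrom: str,
             strand: str) -> list[GenomicInterval]:
    """Transcript-coordinate interval [a, b) -> genomic blocks."""
    out = []
    off = 0
    for s, e in blocks:
        L = e - s
        lo, hi = max(a, off), min(b, off + L)
        if lo < hi:
            out.append(GenomicInterval(chrom, s + lo - off, s + hi - off, strand))
        off += L
    return out


def _tx_offset(blocks: Sequence[tuple[int, int]], genomic_pos: int) -> int:
    off = 0
    for s, e in blocks:
        if s <= genomic_pos <= e:
            return off + genomic_pos - s
        off += e - s
    raise ValueError(f"position {genomic_pos} not on isoform")


def simulate_alignments(
    annotation: Sequence[GeneModel], truth: PlantedTruth, config: SimulationConfig
) -> list[AlignmentRecord]:
    """Poisson-uniform paired-end fragments over every expressed isoform,
    plus deterministic junction-support and intron-tiling reads, plus a
    small fraction of multi-mapping decoy reads (excluded downstream)."""
    rng = _rng(config, 2)
    rl, frag = config.read_length, config.fragment_size
    records: list[AlignmentRecord] = []
    n_fragments = 0
    for iso in planted_isoforms(annotation, truth, config):
        tx_len = iso.tx_len
        chrom = config.chrom
        if tx_len >= frag and iso.depth > 0:
            n = rng.poisson(iso.depth * tx_len / (2 * rl))
            starts = rng.integers(0, tx_len - frag + 1, size=n)
            for i, s in enumerate(starts):
                rid = f"{iso.iso_id}.f{i}"
                m1 = _project(iso.blocks, int(s), int(s) + rl, chrom, iso.strand)
                m2 = _project(iso.blocks, int(s) + frag - rl, int(s) + frag, chrom, iso.strand)
                records.append(AlignmentRecord(rid, 1, m1))
                records.append(AlignmentRecord(rid, 2, m2))
                n_fragments += 1
        # guaranteed junction support: three single-end reads centered on
        # the junction, each with >= 5 bp on both sides
        for jnum, (gap_s, _gap_e) in enumerate(iso.guarantee_junctions):
            j = _tx_offset(iso.blocks, gap_s)
            lo, hi = max(0, j - rl + 5), min(tx_len - rl, j - 5)
            center = min(hi, max(lo, j - rl // 2))
            for t, s in enumerate((center - 6, center, center + 6)):
                s = min(hi, max(lo, s))
                blocks = _project(iso.blocks, s, s + rl, chrom, iso.strand)
                records.append(AlignmentRecord(f"{iso.iso_id}.j{jnum}.{t}", 1, blocks))
        # guaranteed contiguous coverage: two phase-shifted tilings of
        # unspliced reads give depth >= 2 over retained introns (plus 50 bp
        # flanks) and over planted boundary extensions
        regions = [(s - 50, e + 50) for s, e in iso.tile_regions] + iso.exact_tiles
        for rnum, (a, b) in enumerate(regions):
            idx = 0
            for phase in (0, rl // 2):
                pos = a + phase
                while pos + rl <= b:
                    records.append(
                        AlignmentRecord(
                            f"{iso.iso_id}.t{rnum}.{idx}", 1,
                            [GenomicInterval(chrom, pos, pos + rl, iso.strand)],
                        )
                    )
                    idx += 1
                    pos += rl
                records.append(
                    AlignmentRecord(
                        f"{iso.iso_id}.t{rnum}.{idx}", 1,
                        [GenomicInterval(chrom, b - rl, b, iso.strand)],
                    )
                )
                idx += 1
    n_multi = int(config.multi_map_fraction * n_fragments)
    for i in range(n_multi):
        pos = int(rng.integers(0, config.genome_length - rl))
        records.append(
            AlignmentRecord(
                f"multi{i}", 1,
                [GenomicInterval(config.chrom, pos, pos + rl)],
                unique=False,
            )
        )
    return records


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def simulate_counts(
    config: SimulationConfig,
    gene_ids: Sequence[str] | None = None,
    lib_scale: tuple[float, float] = (1.0, 1.0),
) -> tuple[pd.Series, pd.Series, list[dict]]:
    """Two-condition Poisson count tables with planted fold changes.

    Every gene's baseline rate is ``count_mean``; a ``de_fraction`` subset
    is regulated by a factor 2**de_log2fc applied to one library (direction
    random), so the baseline library always keeps mean ``count_mean``.
    Returns (countsA, countsB, planted DE truth with signed log2fc of A
    relative to B).
    """
    rng = _rng(config, 3)
    if gene_ids is None:
        gene_ids = [f"cg{i:05d}" for i in range(config.n_count_genes)]
    n = len(gene_ids)
    rates_a = np.full(n, config.count_mean, dtype=float)
    rates_b = np.full(n, config.count_mean, dtype=float)
    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    de_truth = []
    for i, s in zip(de_idx, signs):
        if s > 0:
            rates_a[i] *= 2.0 ** config.de_log2fc
        else:
            rates_b[i] *= 2.0 ** config.de_log2fc
        de_truth.append({"gene_id": gene_ids[int(i)], "log2fc": float(s * config.de_log2fc)})
    counts_a = rng.poisson(rates_a * lib_scale[0])
    counts_b = rng.poisson(rates_b * lib_scale[1])
    de_truth.sort(key=lambda d: d["gene_id"])
    return (
        pd.Series(counts_a, index=list(gene_ids), name="count"),
        pd.Series(counts_b, index=list(gene_ids), name="count"),
        de_truth,
    )


# ---------------------------------------------------------------------------
# small RNA
# ---------------------------------------------------------------------------

_CATEGORY_MIX = {
    "rRNA": 0.10, "tRNA": 0.10, "scRNA": 0.02, "snRNA": 0.04, "snoRNA": 0.04,
    "repeat": 0.10, "exon": 0.15, "intron": 0.25, "unannotated": 0.20,
}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _tag_length(rng: np.random.Generator, mode: int) -> int:
    lengths = np.arange(18, 31)
    w = np.exp(-0.5 * ((lengths - mode) / 1.5) ** 2)
    return int(rng.choice(lengths, p=w / w.sum()))


def _mutate(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    s = list(seq)
    for pos in rng.choice(len(s), size=min(n_sub, len(s)), replace=False):
        alternatives = [b for b in "ACGT" if b != s[pos]]
        s[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(s)


def simulate_small_rna(
    config: SimulationConfig, mature_db: dict[str, str] | None = None
) -> tuple[list[tuple[str, int]], dict[str, list[str]], dict[str, str], dict]:
    """Small-RNA tag table: a mature-miRNA fraction (0-2 substitutions,
    skewed abundances) plus tags drawn from annotation-category reference
    pools.  Returns (tags, category reference sequences, mature db, truth).
    """
    rng = _rng(config, 4)
    if mature_db is None:
        # mature miRNAs at the canonical modal length (22 nt by default)
        mature_len = int(np.clip(config.tag_modal_length, MIN_TAG, MAX_TAG))
        mature_db = {
            f"mir-{i + 1:03d}": _random_seq(rng, mature_len)
            for i in range(config.n_mature)
        }
    if not mature_db:
        raise ValueError("mature_db must be non-empty")
    category_refs = {
        cat: [_random_seq(rng, 400) for _ in range(2)]
        for cat in ("rRNA", "tRNA", "scRNA", "snRNA", "snoRNA", "repeat", "exon", "intron")
    }

    mature_ids = sorted(mature_db)
    weights = rng.dirichlet(np.full(len(mature_ids), 0.3))
    n_mature_tags = int(round(config.mature_fraction * config.n_tags))
    per_mirna = rng.multinomial(n_mature_tags, weights)
    tags: dict[str, int] = {}
    truth_counts: dict[str, int] = {}
    for mid, n_reads in zip(mature_ids, per_mirna):
        if n_reads == 0:
            continue
        truth_counts[mid] = int(n_reads)
        n1 = int(round(0.2 * n_reads))
        n2 = int(round(0.1 * n_reads))
        variants = [(mature_db[mid], n_reads - n1 - n2)]
        if n1:
            variants.append((_mutate(rng, mature_db[mid], 1), n1))
        if n2:
            variants.append((_mutate(rng, mature_db[mid], 2), n2))
        for seq, c in variants:
            if c > 0:
                tags[seq] = tags.get(seq, 0) + int(c)

    n_rest = config.n_tags - n_mature_tags
    cats = sorted(_CATEGORY_MIX)
    mix = np.array([_CATEGORY_MIX[c] for c in cats])
    per_cat = rng.multinomial(n_rest, mix / mix.sum())
    cat_truth: dict[str, int] = {}
    for cat, n_reads in zip(cats, per_cat):
        cat_truth[cat] = int(n_reads)
        remaining = int(n_reads)
        while remaining > 0:
            c = int(min(remaining, rng.integers(1, 30)))
            length = _tag_length(rng, config.tag_modal_length)
            if cat == "unannotated":
                seq = _random_seq(rng, length)
            else:
                ref = category_refs[cat][int(rng.integers(0, 2))]
                start = int(rng.integers(0, len(ref) - length + 1))
                seq = ref[start:start + length]
            tags[seq] = tags.get(seq, 0) + c
            remaining -= c
    truth = {
        "modal_length": config.tag_modal_length,
        "mature_read_counts": truth_counts,
        "category_read_counts": cat_truth,
        "n_mature_tags": n_mature_tags,
    }
    tag_list = sorted(tags.items())
    return tag_list, category_refs, mature_db, truth


# ---------------------------------------------------------------------------
# GO / GWAS / KO fixtures for the end-to-end demo
# ---------------------------------------------------------------------------

def generate_gene2go(
    gene_ids: Sequence[str], de_gene_ids: Sequence[str], config: SimulationConfig,
    n_terms: int = 15,
) -> dict[str, list[tuple[str, str]]]:
    """Random GO assignments with one term planted enriched in DE genes."""
    rng = _rng(config, 5)
    categories = ("biological process", "molecular function", "cellular component")
    terms = [(f"GO:{i + 1:07d}", categories[i % 3]) for i in range(n_terms)]
    gene2go: dict[str, list[tuple[str, str]]] = {}
    for gid in gene_ids:
        k = int(rng.integers(1, 4))
        idx = rng.choice(n_terms, size=k, replace=False)
        gene2go[gid] = [terms[int(i)] for i in sorted(idx)]
    enriched = terms[0]
    de_set = set(de_gene_ids)
    for gid in gene_ids:
        if gid in de_set and rng.random() < 0.7 and enriched not in gene2go[gid]:
            gene2go[gid].append(enriched)
    return gene2go


def generate_gwas_hits(
    annotation: Sequence[GeneModel], de_gene_ids: Sequence[str], config: SimulationConfig,
    traits: Sequence[str] = ("backfat", "heart weight", "growth rate"),
) -> list[GwasHit]:
    """Per-trait SNP sets whose most significant SNP sits near a DE gene."""
    rng = _rng(config, 6)
    spans = {g.gene_id: g.interval for g in annotation}
    anchors = [gid for gid in de_gene_ids if gid in spans]
    hits = []
    snp_i = 0
    for t, trait in enumerate(traits):
        if anchors:
            gid = anchors[t % len(anchors)]
            pos = (spans[gid].start + spans[gid].end) // 2 + int(rng.integers(-5000, 5001))
            pos = int(np.clip(pos, 0, config.genome_length - 1))
            hits.append(GwasHit(f"snp{snp_i:04d}", config.chrom, pos, 1e-6 * (t + 1), trait))
            snp_i += 1
        for _ in range(3):
            pos = int(rng.integers(0, config.genome_length))
            p = float(rng.uniform(0.01, 1.0))
            hits.append(GwasHit(f"snp{snp_i:04d}", config.chrom, pos, p, trait))
            snp_i += 1
    return hits


def generate_ko_table(
    de_gene_ids: Sequence[str], traits: Sequence[str] = ("backfat", "heart weight", "growth rate")
) -> dict[str, str]:
    return {
        gid: f"knockout mice show altered {traits[i % len(traits)]}"
        for i, gid in enumerate(sorted(de_gene_ids))
    }
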