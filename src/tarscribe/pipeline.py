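"""Configuration-driven orchestration of all stages.

Stages run in dependency order (coverage -> TARs -> units / junctions /
boundaries -> expression -> integration), communicate via files in the
output directory, and a run manifest records every output with a content
checksum plus a parameter echo, so identical config + inputs yield
byte-identical manifests.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import boundaries as bnd
from . import expression as expr
from . import integrate as integ
from . import io as tio
from . import simulate as sim
from . import smallrna as srna
from . import splicing as spl
from . import tars as tdisc
from .model import GeneModel

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "novel_units", "splicing", "boundaries", "expression", "go", "smallrna", "integration",
)


@dataclass
class PipelineConfig:
    """All stage thresholds (defaults are the pipeline's canonical cutoffs),
    input paths, output directory and seed."""

    outdir: str = "tarscribe_run"
    seed: int = 0
    synthetic: bool = True
    stages: tuple[str, ...] = ALL_STAGES
    # thresholds
    min_depth: int = 2
    min_len: int = 150
    min_avg_cov: float = 2.0
    margin: int = 200
    cluster_gap: int = 3000
    min_junc_reads: int = 2
    min_overhang: int = 5
    fdr_max: float = 0.001
    min_abs_log2: float = 1.0
    mirna_p: float = 0.01
    window: int = 2_500_000
    go_alpha: float = 0.05
    # inputs (ignored in synthetic mode, which generates them)
    inputs: dict = field(default_factory=dict)
    chrom_sizes: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tars_bed(tars: Sequence[tdisc.Tar], path: Path) -> None:
    with open(path, "w") as fh:
        for i, t in enumerate(tars):
            iv = t.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\ttar{i:06d}\t{t.mean_depth:.3f}\n")


def _write_units_bed12(units: Sequence[tdisc.TranscriptUnit], path: Path) -> None:
    with open(path, "w") as fh:
        for i, u in enumerate(units):
            s = u.span
            sizes = ",".join(str(len(t.interval)) for t in u.tars)
            offs = ",".join(str(t.interval.start - s.start) for t in u.tars)
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\tunit{i:06d}\t{u.n_linking_pairs}\t.\t"
                f"{s.start}\t{s.end}\t0\t{u.n_exons}\t{sizes}\t{offs}\n"
            )


def _write_regions_bed(regions: Sequence[tdisc.TarRegion], path: Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            s = r.span
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\tregion{i:06d}\t{len(r.units)}\n")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    manifest: dict = {
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "inputs"
        },
        "stages_run": [],
        "outputs": {},
    }

    if config.synthetic:
        sim_cfg = sim.SimulationConfig(seed=config.seed, **config.simulation)
        inputs = _generate_inputs(sim_cfg, outdir)
        chrom_sizes = sim_cfg.chrom_sizes
        outputs.update(inputs)
    else:
        inputs = {k: Path(v) for k, v in config.inputs.items()}
        missing = [f"{k}={v}" for k, v in inputs.items() if not Path(v).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {', '.join(missing)}")
        chrom_sizes = dict(config.chrom_sizes)
        if not chrom_sizes:
            raise ValueError("chrom_sizes required when synthetic=false")

    annotation = alignments = coverage = all_tars = None
    need_reads = any(s in config.stages for s in ("novel_units", "splicing", "boundaries"))
    if need_reads or "expression" in config.stages:
        annotation = tio.read_annotation(inputs["annotation"], "gtf")
    if need_reads:
        alignments = tio.read_alignments(inputs["reads"], "bed12", chrom_sizes=chrom_sizes)
        coverage = tdisc.compute_coverage(alignments, chrom_sizes)
        all_tars = []
        for chrom in sorted(coverage):
            all_tars.extend(tdisc.call_tars(coverage[chrom], config.min_depth))

    de_df = None
    for stage in config.stages:
        try:
            if stage == "novel_units":
                units = tdisc.link_tars(all_tars, alignments)
                intergenic = tdisc.define_intergenic(annotation, chrom_sizes, config.margin)
                novel = tdisc.filter_novel_units(
                    units, intergenic, config.min_len, config.min_avg_cov
                )
                regions = tdisc.cluster_units(novel, config.cluster_gap)
                _write_tars_bed(all_tars, outdir / "tars.bed")
                _write_units_bed12(novel, outdir / "novel_units.bed12")
                _write_regions_bed(regions, outdir / "tar_regions.bed")
                outputs["tars"] = outdir / "tars.bed"
                outputs["novel_units"] = outdir / "novel_units.bed12"
                outputs["tar_regions"] = outdir / "tar_regions.bed"
            elif stage == "splicing":
                junctions = spl.extract_junctions(alignments)
                valid = spl.validate_junctions(
                    junctions, config.min_junc_reads, config.min_overhang
                )
                events, orphan = spl.classify_events(
                    valid, annotation, coverage, config.min_depth
                )
                with open(outdir / "junctions.bed", "w") as fh:
                    for j in valid:
                        fh.write(
                            f"{j.chrom}\t{j.donor_end}\t{j.acceptor_start}\t"
                            f"junc\t{j.n_reads}\t.\n"
                        )
                pd.DataFrame(
                    {
                        "gene_id": [e.gene_id for e in events],
                        "type": [e.type for e in events],
                        "coordinates": [json.dumps(e.coordinates) for e in events],
                        "evidence": [json.dumps(e.evidence) for e in events],
                    }
                ).to_csv(outdir / "events.tsv", sep="\t", index=False)
                outputs["junctions"] = outdir / "junctions.bed"
                outputs["events"] = outdir / "events.tsv"
                logger.info("%d junctions outside genes (novel-region splicing)", len(orphan))
            elif stage == "boundaries":
                models = bnd.build_gene_models(all_tars, alignments, annotation)
                exts = bnd.detect_extensions(models)
                pd.DataFrame(
                    {
                        "gene_id": [e.gene_id for e in exts],
                        "end": [e.which_end for e in exts],
                        "extension_bp": [e.extension_bp for e in exts],
                        "supported_by_pairs": [e.supported_by_pairs for e in exts],
                    }
                ).to_csv(outdir / "extensions.tsv", sep="\t", index=False)
                outputs["extensions"] = outdir / "extensions.tsv"
            elif stage == "expression":
                counts_a = tio.read_counts(inputs["counts_a"])
                counts_b = tio.read_counts(inputs["counts_b"])
                de_df = expr.call_de(
                    counts_a, counts_b,
                    fdr_max=config.fdr_max, min_abs_log2=config.min_abs_log2,
                )
                de_df.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
                outputs["de_results"] = outdir / "de_results.tsv"
            elif stage == "go":
                if de_df is None:
                    raise RuntimeError("expression stage must run before go")
                gene2go_df = pd.read_csv(inputs["gene2go"], sep="\t")
                gene2go: dict[str, list[tuple[str, str]]] = {}
                for r in gene2go_df.itertuples():
                    gene2go.setdefault(str(r.gene_id), []).append(
                        (str(r.term_id), str(r.category))
                    )
                de_genes = de_df.loc[de_df["significant"], "gene_id"].tolist()
                background = de_df["gene_id"].tolist()
                results = expr.go_enrichment(de_genes, gene2go, background, config.go_alpha)
                pd.DataFrame(
                    {
                        "term_id": [r.term_id for r in results],
                        "category": [r.category for r in results],
                        "k": [r.k for r in results],
                        "K": [r.K for r in results],
                        "n": [r.n for r in results],
                        "N": [r.N for r in results],
                        "p_hyper": [r.p_hyper for r in results],
                        "p_bonferroni": [r.p_bonferroni for r in results],
                        "significant": [r.p_bonferroni <= config.go_alpha for r in results],
                    }
                ).to_csv(outdir / "go_results.tsv", sep="\t", index=False)
                outputs["go_results"] = outdir / "go_results.tsv"
            elif stage == "smallrna":
                tag_df = pd.read_csv(inputs["smallrna"], sep="\t")
                raw = list(zip(tag_df["sequence"], tag_df["count"]))
                tags = srna.clean_tags(raw)
                dist = srna.length_distribution(tags)
                refs_fa = tio.read_fasta(inputs["category_refs"])
                category_refs: dict[str, list[str]] = {}
                for name, seq in refs_fa.items():
                    category_refs.setdefault(name.rsplit(".", 1)[0], []).append(seq)
                annotated = srna.annotate_cascade(tags, category_refs)
                retained = srna.retained_for_mirna(annotated)
                mature = tio.read_fasta(inputs["mature"])
                clean_total = dist["total"]
                quants, _ = srna.match_known(retained, mature, clean_total)
                pd.DataFrame(
                    {
                        "length": list(dist["histogram"].keys()),
                        "reads": list(dist["histogram"].values()),
                    }
                ).to_csv(outdir / "length_hist.tsv", sep="\t", index=False)
                pd.DataFrame(
                    {
                        "sequence": [t.sequence for t in annotated],
                        "count": [t.count for t in annotated],
                        "category": [t.category for t in annotated],
                    }
                ).to_csv(outdir / "categories.tsv", sep="\t", index=False)
                srna.mirna_quant_table(quants).to_csv(
                    outdir / "mirna_quant.tsv", sep="\t", index=False
                )
                outputs["length_hist"] = outdir / "length_hist.tsv"
                outputs["categories"] = outdir / "categories.tsv"
                outputs["mirna_quant"] = outdir / "mirna_quant.tsv"
            elif stage == "integration":
                if de_df is None:
                    raise RuntimeError("expression stage must run before integration")
                ann = annotation or tio.read_annotation(inputs["annotation"], "gtf")
                spans = {g.gene_id: g.interval for g in ann}
                sig = de_df[de_df["significant"]]
                de_genes = {
                    r.gene_id: (spans.get(r.gene_id), r.direction)
                    for r in sig.itertuples()
                }
                gwas_hits = tio.read_gwas(inputs["gwas"])
                cands = integ.proximity_join(de_genes, gwas_hits, config.window)
                ko_df = pd.read_csv(inputs["ko"], sep="\t") if "ko" in inputs else None
                ko = (
                    dict(zip(ko_df["gene_id"].astype(str), ko_df["phenotype"].astype(str)))
                    if ko_df is not None
                    else None
                )
                cands = integ.annotate_candidates(cands, ko)
                pd.DataFrame(
                    {
                        "gene_id": [c.gene_id for c in cands],
                        "snp_id": [c.snp_id for c in cands],
                        "distance_bp": [c.distance_bp for c in cands],
                        "trait": [c.trait for c in cands],
                        "de_direction": [c.de_direction for c in cands],
                        "ko_phenotype": [c.ko_phenotype for c in cands],
                        "trait_match": [c.trait_match for c in cands],
                    }
                ).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
                outputs["candidates"] = outdir / "candidates.tsv"
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:  # noqa: BLE001 - halt with the failing stage named
            raise StageError(stage, exc) from exc
        manifest["stages_run"].append(stage)

    for name in sorted(outputs):
        path = outputs[name]
        manifest["outputs"][name] = {
            "path": path.name,
            "sha256": _sha256(path),
        }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _generate_inputs(sim_cfg: sim.SimulationConfig, outdir: Path) -> dict[str, Path]:
    """Synthetic mode: generate every input file plus the planted truth."""
    annotation, truth = sim.generate_annotation(sim_cfg)
    alignments = sim.simulate_alignments(annotation, truth, sim_cfg)
    gene_ids = [g.gene_id for g in annotation]
    counts_a, counts_b, de_truth = sim.simulate_counts(sim_cfg, gene_ids=gene_ids)
    truth.de_genes = de_truth
    de_ids = [d["gene_id"] for d in de_truth]
    gene2go = sim.generate_gene2go(gene_ids, de_ids, sim_cfg)
    gwas_hits = sim.generate_gwas_hits(annotation, de_ids, sim_cfg)
    ko = sim.generate_ko_table(de_ids)
    tag_list, category_refs, mature_db, sm_truth = sim.simulate_small_rna(sim_cfg)
    truth.smallrna = sm_truth

    paths: dict[str, Path] = {}

    def _p(key: str, name: str) -> Path:
        paths[key] = outdir / name
        return paths[key]

    tio.write_annotation(annotation, _p("annotation", "annotation.gtf"), "gtf")
    tio.write_alignments_bed12(alignments, _p("reads", "reads.bed12"))
    tio.write_counts(counts_a, _p("counts_a", "countsA.tsv"))
    tio.write_counts(counts_b, _p("counts_b", "countsB.tsv"))
    pd.DataFrame(tag_list, columns=["sequence", "count"]).to_csv(
        _p("smallrna", "smallrna.tsv"), sep="\t", index=False
    )
    tio.write_fasta(mature_db, _p("mature", "mature.fa"))
    tio.write_fasta(
        {f"{cat}.{i}": s for cat, seqs in category_refs.items() for i, s in enumerate(seqs)},
        _p("category_refs", "category_refs.fa"),
    )
    rows = [
        (gid, term, category)
        for gid, terms in gene2go.items()
        for term, category in terms
    ]
    pd.DataFrame(rows, columns=["gene_id", "term_id", "category"]).to_csv(
        _p("gene2go", "gene2go.tsv"), sep="\t", index=False
    )
    tio.write_gwas(gwas_hits, _p("gwas", "gwas.tsv"))
    pd.DataFrame(sorted(ko.items()), columns=["gene_id", "phenotype"]).to_csv(
        _p("ko", "ko.tsv"), sep="\t", index=False
    )
    truth.to_json(_p("truth", "truth.json"))
    return paths
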