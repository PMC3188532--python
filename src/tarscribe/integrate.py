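"""GWAS x differential-expression candidate-gene integration.

Significant DE genes lying within a 2.5 Mb window of each trait's most
significant (Bonferroni-corrected) SNP become positional candidate genes;
knockout-phenotype annotations can be attached from an offline table.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model import GenomicInterval, GwasHit

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 2_500_000


@dataclass
class CandidateGene:
    gene_id: str
    snp_id: str
    distance_bp: int
    trait: str
    de_direction: str
    ko_phenotype: str = ""
    trait_match: bool = False


def bonferroni(pvalues: Sequence[float], m: int | None = None) -> np.ndarray:
    """min(1, p*m) elementwise; m defaults to len(pvalues)."""
    p = np.asarray(pvalues, dtype=float)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, p * m)


def top_snps_per_trait(hits: Sequence[GwasHit]) -> list[GwasHit]:
    """Each trait's most significant SNP(s); ties keep all tied SNPs."""
    best: dict[str, float] = {}
    for h in hits:
        if h.trait not in best or h.p_corrected < best[h.trait]:
            best[h.trait] = h.p_corrected
    return [h for h in hits if h.p_corrected == best[h.trait]]


def proximity_join(
    de_genes: Mapping[str, tuple[GenomicInterval, str]],
    gwas_hits: Sequence[GwasHit],
    window: int = DEFAULT_WINDOW,
) -> list[CandidateGene]:
    """Pair significant DE genes with trait-top SNPs within ``window`` bp.

    ``de_genes`` maps gene_id -> (gene span, DE direction).  Distance is
    measured from the nearest base of the gene span to the SNP position
    (0 when the SNP lies inside the gene), inclusive at the window.
    """
    candidates = []
    for snp in top_snps_per_trait(gwas_hits):
        for gene_id in sorted(de_genes):
            span, direction = de_genes[gene_id]
            if span is None:
                logger.warning("gene %s has no genomic placement; skipped", gene_id)
                continue
            if span.chrom != snp.chrom:
                continue
            d = span.distance_to_point(snp.pos)
            if d <= window:
                candidates.append(
                    CandidateGene(gene_id, snp.snp_id, d, snp.trait, direction)
                )
    candidates.sort(key=lambda c: (c.trait, c.snp_id, c.distance_bp, c.gene_id))
    return candidates


def annotate_candidates(
    candidates: Sequence[CandidateGene], ko_table: Mapping[str, str] | None = None
) -> list[CandidateGene]:
    """Attach knockout-mouse phenotype text; flag candidates whose phenotype
    mentions the associated trait."""
    if not ko_table:
        return list(candidates)
    out = []
    for c in candidates:
        pheno = ko_table.get(c.gene_id, "")
        match = bool(pheno) and c.trait.lower() in pheno.lower()
        out.append(
            CandidateGene(
                c.gene_id, c.snp_id, c.distance_bp, c.trait, c.de_direction, pheno, match
            )
        )
    return out
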