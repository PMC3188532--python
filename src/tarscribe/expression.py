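"""Gene-level quantification and two-library differential expression.

Expression is RPKM over per-gene flattened exons.  The two-library test is
the Audic-Claverie exact test in its conditional-binomial form: given the
summed count x+y, the count in library B is Binomial(x+y, n2/(n1+n2)) under
the null of equal relative expression; the two-sided p doubles the smaller
tail (capped at 1).  Multiplicity is handled by Benjamini-Hochberg step-up
FDR for genes and by a raw-p threshold for miRNAs, matching the thresholds
the pipeline defaults to (FDR <= 0.001 & |log2Ratio| >= 1; p < 0.01 &
|log2fc| >= 1).  GO enrichment is an upper-tail hypergeometric test with
Bonferroni correction over tested terms.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import AlignmentRecord, GeneModel

logger = logging.getLogger(__name__)

DEFAULT_FDR_MAX = 0.001
DEFAULT_MIN_ABS_LOG2 = 1.0
DEFAULT_MIRNA_P = 0.01
DEFAULT_GO_ALPHA = 0.05


@dataclass
class ExpressionRecord:
    gene_id: str
    count: int
    exon_len_bp: int
    rpkm: float


@dataclass
class GoTermResult:
    term_id: str
    category: str
    k: int
    K: int
    n: int
    N: int
    p_hyper: float
    p_bonferroni: float


def rpkm(count: int | np.ndarray, exon_len_bp: int | np.ndarray, total_mapped: int):
    """Reads per kilobase of exon per million mapped reads."""
    return count / (exon_len_bp / 1e3) / (total_mapped / 1e6)


def quantify(
    alignments: Sequence[AlignmentRecord],
    annotation: Sequence[GeneModel],
    total_mapped: int | None = None,
) -> list[ExpressionRecord]:
    """Count unique reads on flattened exons and normalize to RPKM.

    A read is assigned to the gene whose exons its blocks overlap most; an
    exact tie leaves it unassigned (logged at debug level).
    """
    exon_index: dict[str, list[tuple[int, int, str]]] = {}
    for g in annotation:
        for e in g.exons:
            exon_index.setdefault(g.chrom, []).append((e.start, e.end, g.gene_id))
    for chrom in exon_index:
        exon_index[chrom].sort()
    starts = {c: np.array([x[0] for x in v]) for c, v in exon_index.items()}
    ends = {c: np.array([x[1] for x in v]) for c, v in exon_index.items()}

    counts = {g.gene_id: 0 for g in annotation}
    n_unique = 0
    for rec in alignments:
        if not rec.unique:
            continue
        n_unique += 1
        overlap: dict[str, int] = {}
        if rec.chrom not in exon_index:
            continue
        st, en, entries = starts[rec.chrom], ends[rec.chrom], exon_index[rec.chrom]
        for b in rec.blocks:
            lo = int(np.searchsorted(en, b.start, side="right"))
            hi = int(np.searchsorted(st, b.end, side="left"))
            for k in range(lo, hi):
                es, ee, gid = entries[k]
                ov = min(ee, b.end) - max(es, b.start)
                if ov > 0:
                    overlap[gid] = overlap.get(gid, 0) + ov
        if not overlap:
            continue
        best = max(overlap.values())
        winners = [gid for gid, ov in overlap.items() if ov == best]
        if len(winners) > 1:
            logger.debug("read %s ties between %s; unassigned", rec.read_id, winners)
            continue
        counts[winners[0]] += 1

    total = total_mapped if total_mapped is not None else n_unique
    out = []
    for g in annotation:
        c = counts[g.gene_id]
        val = rpkm(c, g.exonic_length, total) if total > 0 else 0.0
        out.append(ExpressionRecord(g.gene_id, c, g.exonic_length, float(val)))
    return out


# ---------------------------------------------------------------------------
# Audic-Claverie exact test
# ---------------------------------------------------------------------------

def audic_claverie_p(x, y, n1: float, n2: float):
    """Two-sided Audic-Claverie p for counts x (library A) and y (library B).

    Conditional on x+y, y ~ Binomial(x+y, n2/(n1+n2)); the two-sided p is
    min(1, 2*min(P(Y <= y), P(Y >= y))).  Accepts scalars or arrays.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    x = np.asarray(x)
    y = np.asarray(y)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative")
    n = x + y
    q = n2 / (n1 + n2)
    lower = stats.binom.cdf(y, n, q)
    upper = stats.binom.sf(y - 1, n, q)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    # x = y = 0 carries no evidence
    p = np.where(n == 0, 1.0, p)
    if p.ndim == 0:
        return float(p)
    return p


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_de(
    tableA: pd.Series,
    tableB: pd.Series,
    n1: float | None = None,
    n2: float | None = None,
    fdr_max: float = DEFAULT_FDR_MAX,
    min_abs_log2: float = DEFAULT_MIN_ABS_LOG2,
) -> pd.DataFrame:
    """Audic-Claverie differential expression between two count tables.

    Tables are gene-indexed counts over the same universe.  Genes zero in
    both libraries are excluded before testing; a half-count floor keeps
    the log2 ratio finite when one library is zero (the p-value is exact
    and unaffected).  A gene is significant when q <= fdr_max and
    |log2_ratio| >= min_abs_log2.
    """
    a_idx, b_idx = set(tableA.index), set(tableB.index)
    if a_idx != b_idx:
        diff = sorted(a_idx ^ b_idx)
        raise ValueError(f"count tables disagree on genes: {diff[:10]}")
    tableB = tableB.reindex(tableA.index)
    if n1 is None:
        n1 = float(tableA.sum())
    if n2 is None:
        n2 = float(tableB.sum())
    mask = (tableA > 0) | (tableB > 0)
    x = tableA[mask].to_numpy(dtype=float)
    y = tableB[mask].to_numpy(dtype=float)
    genes = tableA.index[mask]
    xf = np.where(x == 0, 0.5, x)
    yf = np.where(y == 0, 0.5, y)
    log2_ratio = np.log2((xf / n1) / (yf / n2))
    p = audic_claverie_p(x.astype(int), y.astype(int), n1, n2)
    q = bh_fdr(p)
    significant = (q <= fdr_max) & (np.abs(log2_ratio) >= min_abs_log2)
    direction = np.where(log2_ratio > 0, "up", np.where(log2_ratio < 0, "down", "none"))
    return pd.DataFrame(
        {
            "gene_id": genes,
            "x": x.astype(int),
            "y": y.astype(int),
            "n1": n1,
            "n2": n2,
            "log2_ratio": log2_ratio,
            "p": p,
            "q": q,
            "significant": significant,
            "direction": direction,
        }
    ).reset_index(drop=True)


def mirna_de(
    tableA: pd.Series,
    tableB: pd.Series,
    n1: float | None = None,
    n2: float | None = None,
    p_max: float = DEFAULT_MIRNA_P,
    min_abs_log2: float = DEFAULT_MIN_ABS_LOG2,
) -> pd.DataFrame:
    """miRNA differential expression: raw p < p_max and |log2fc| >= threshold."""
    df = call_de(tableA, tableB, n1, n2, fdr_max=np.inf, min_abs_log2=min_abs_log2)
    df["significant"] = (df["p"] < p_max) & (np.abs(df["log2_ratio"]) >= min_abs_log2)
    return df


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------

def go_enrichment(
    de_genes: Sequence[str],
    gene2go: Mapping[str, Sequence[tuple[str, str]]],
    background: Sequence[str],
    alpha: float = DEFAULT_GO_ALPHA,
) -> list[GoTermResult]:
    """Hypergeometric enrichment of GO terms among DE genes, Bonferroni-corrected.

    ``gene2go`` maps gene -> [(term_id, category), ...].  Only terms with at
    least one background gene and one DE gene are tested; the Bonferroni
    factor is the number of tested terms.
    """
    bg = set(background)
    de = set(de_genes)
    if not de <= bg:
        raise ValueError("DE genes must be a subset of the background universe")
    if not de:
        return []
    term_bg: dict[tuple[str, str], int] = {}
    term_de: dict[tuple[str, str], int] = {}
    for gene in bg:
        for term in gene2go.get(gene, ()):  # term = (term_id, category)
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in de:
                term_de[term] = term_de.get(term, 0) + 1
    tested = sorted(t for t in term_de if term_de[t] >= 1)
    m = len(tested)
    out = []
    N, n = len(bg), len(de)
    for term_id, category in tested:
        K = term_bg[(term_id, category)]
        k = term_de[(term_id, category)]
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        out.append(
            GoTermResult(term_id, category, k, K, n, N, p, min(1.0, p * m))
        )
    out.sort(key=lambda r: (r.p_hyper, r.term_id))
    return out
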