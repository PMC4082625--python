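"""Functional-annotation clustering around breakpoints (DAVID-style).

Per-term enrichment of a foreground gene list (genes within +/-200 Kbp of
retained EBRs, or inside an inverted region) against a masked background is
scored with the EASE statistic: a one-sided Fisher exact p-value made
conservative by removing one gene from the overlap cell before computing the
hypergeometric tail.  Terms with EASE p <= 0.05 are agglomerated into
annotation clusters by Cohen's kappa co-membership similarity, and each
cluster is ranked by an Enrichment Score, the negative log10 of the geometric
mean of its members' EASE p-values; ES >= 1.5 flags a significant module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .genome import clipped_overlap
from .rearrange import ClassifiedRearrangement, RegionMask
from .synteny import EBR

EASE_ALPHA = 0.05
ES_SIGNIFICANT = 1.5
DEFAULT_FLANK_BP = 200_000
KAPPA_MIN = 0.35
MIN_CLUSTER_GENES = 10
MAX_CLUSTER_GENES = 3000


@dataclass
class TermStat:
    term_id: str
    k: int     # foreground genes carrying the term
    K: int     # background genes carrying the term
    n: int     # foreground size
    N: int     # background size
    ease_p: float
    members: frozenset = field(default_factory=frozenset)  # foreground member gene ids


@dataclass
class AnnotationCluster:
    member_terms: list[TermStat]
    member_genes: set[str]
    enrichment_score: float

    @property
    def significant(self) -> bool:
        return self.enrichment_score >= ES_SIGNIFICANT


def genes_in_ebr_neighborhoods(genes: pd.DataFrame, ebrs: list[EBR],
                               flank_bp: int = DEFAULT_FLANK_BP) -> list[str]:
    """Genes overlapping any retained EBR extended by ``flank_bp`` on each
    side, deduplicated (a gene near two EBRs counts once)."""
    hits: list[str] = []
    seen: set[str] = set()
    for row in genes.itertuples(index=False):
        for e in ebrs:
            if e.chrom != row.chrom:
                continue
            if clipped_overlap(row.start, row.end,
                               max(0, e.start - flank_bp), e.end + flank_bp):
                if row.gene_id not in seen:
                    seen.add(row.gene_id)
                    hits.append(row.gene_id)
                break
    return hits


def build_background(genes: pd.DataFrame,
                     masks: dict[str, RegionMask] | None = None) -> list[str]:
    """Protein-coding genes outside the telomeric/centromeric masks.

    With a ``biotype`` column only ``protein_coding`` rows are kept;
    otherwise all genes are assumed coding.
    """
    if "biotype" in genes.columns:
        genes = genes[genes["biotype"] == "protein_coding"]
    out: list[str] = []
    for row in genes.itertuples(index=False):
        mask = masks.get(row.chrom) if masks else None
        if mask is not None:
            ivs = list(mask.telomeric) + list(mask.centromeric)
            if any(clipped_overlap(row.start, row.end, s, e) for s, e in ivs):
                continue
        out.append(row.gene_id)
    if not out:
        raise ValueError("background gene list is empty after masking")
    return out


def ease_pvalue(k: int, K: int, n: int, N: int) -> float:
    """EASE-penalized one-sided Fisher exact p-value.

    One gene is removed from the overlap cell: the score is the upper
    hypergeometric tail P[X >= k-1] drawn from a foreground of n-1 genes
    (population N, K term genes).  k = 0 is defined as p = 1.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"invalid 2x2 margins k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    # sf(k-2) = P[X > k-2] = P[X >= k-1]
    return float(hypergeom.sf(k - 2, N, K, n - 1))


def fisher_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Unpenalized one-sided (enrichment) Fisher exact p, for reference."""
    return float(hypergeom.sf(k - 1, N, K, n))


def kappa_similarity(members_i: set[str], members_j: set[str],
                     universe: set[str]) -> float:
    """Cohen's kappa between two terms' gene-membership indicators over the
    foreground universe.  Degenerate tables: identical agreement everywhere
    gives kappa = 1; an empty universe gives kappa = 0.
    """
    if not universe:
        return 0.0
    if not members_i or not members_j:
        raise ValueError("terms must annotate at least one gene")
    n = len(universe)
    a = len(members_i & members_j & universe)           # in both
    b = len((members_i - members_j) & universe)         # i only
    c = len((members_j - members_i) & universe)         # j only
    d = n - a - b - c                                   # in neither
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    if math.isclose(pe, 1.0):
        return 1.0 if math.isclose(po, 1.0) else 0.0
    return (po - pe) / (1 - pe)


def score_terms(foreground: list[str], background: list[str],
                annotations: pd.DataFrame) -> list[TermStat]:
    """EASE statistics for every term annotating >= 1 foreground gene.

    ``annotations`` has columns gene_id, term_id (one row per assignment).
    """
    fg = set(foreground)
    bg = set(background)
    n, N = len(fg), len(bg)
    stats: list[TermStat] = []
    for term_id, sub in annotations.groupby("term_id"):
        term_genes = set(sub["gene_id"])
        members = frozenset(term_genes & fg)
        k = len(members)
        K = len(term_genes & bg)
        if k == 0 or K == 0:
            continue
        stats.append(TermStat(term_id=str(term_id), k=k, K=K, n=n, N=N,
                              ease_p=ease_pvalue(k, min(K, N), n, N),
                              members=members))
    return sorted(stats, key=lambda t: t.ease_p)


def enrichment_score(pvalues: list[float]) -> float:
    """-log10 of the geometric mean of member EASE p-values."""
    if not pvalues:
        raise ValueError("empty p-value list")
    logs = [math.log10(max(p, 1e-300)) for p in pvalues]
    return -sum(logs) / len(logs)


def cluster_terms(term_stats: list[TermStat],
                  kappa_min: float = KAPPA_MIN,
                  min_genes: int = MIN_CLUSTER_GENES,
                  max_genes: int = MAX_CLUSTER_GENES,
                  alpha: float = EASE_ALPHA) -> list[AnnotationCluster]:
    """Greedy agglomeration of significant terms into annotation clusters.

    Terms with EASE p <= ``alpha`` seed clusters in ascending-p order; an
    unassigned term joins a cluster when its kappa similarity reaches
    ``kappa_min`` with at least half of the current member terms.  Clusters
    whose member-gene union falls outside [min_genes, max_genes] are
    discarded.  Output sorted by descending Enrichment Score.
    """
    sig = [t for t in term_stats if t.ease_p <= alpha]
    universe = set().union(*(t.members for t in term_stats)) if term_stats else set()
    unassigned = sorted(sig, key=lambda t: t.ease_p)
    clusters: list[list[TermStat]] = []
    while unassigned:
        seed = unassigned.pop(0)
        cluster = [seed]
        changed = True
        while changed:
            changed = False
            for cand in list(unassigned):
                links = sum(
                    kappa_similarity(set(cand.members), set(m.members), universe) >= kappa_min
                    for m in cluster)
                if links >= max(1, math.ceil(len(cluster) / 2)):
                    cluster.append(cand)
                    unassigned.remove(cand)
                    changed = True
        clusters.append(cluster)

    out: list[AnnotationCluster] = []
    for cluster in clusters:
        genes: set[str] = set().union(*(set(t.members) for t in cluster))
        if not (min_genes <= len(genes) <= max_genes):
            continue
        out.append(AnnotationCluster(
            member_terms=cluster, member_genes=genes,
            enrichment_score=enrichment_score([t.ease_p for t in cluster])))
    return sorted(out, key=lambda c: -c.enrichment_score)


def genes_in_inversion(genes: pd.DataFrame,
                       rearrangement: ClassifiedRearrangement) -> list[str]:
    """Genes overlapping the inverted span (between the inner EBR edges)."""
    if rearrangement.kind != "inversion":
        raise ValueError(f"not an inversion: {rearrangement.kind}")
    sub = genes[(genes["chrom"] == rearrangement.chrom)
                & (genes["start"] < rearrangement.region_end)
                & (genes["end"] > rearrangement.region_start)]
    return sub["gene_id"].tolist()
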