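"""Isoform-level APA quantities.

Relative expression (RE) of the distal vs. proximal pA isoform of a gene
is ``log2(RPM_dis / RPM_prx)``; the relative expression difference (RED)
between two samples is ``RE_B - RE_A`` (later minus earlier), so a
negative RED means a shift toward the proximal isoform, i.e. 3'UTR
shortening.  This module also computes the expression-weighted mean
3'UTR size, gene-level RPM from 3'-most-exon reads, the pooled CDS-pA /
uaRNA aggregate sets, intron position groups, and the fold-change class
of single-UTR (sUTR) genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .models import (
    PA_3UTR,
    PA_INTRON,
    PA_UARNA,
    PA_UPSTREAM_EXON,
    GeneModel,
    PaCluster,
    PaCountMatrix,
)

#: raw-read pseudocount applied (to both terms) only when either raw
#: count is zero; converted to RPM where the ratio is taken on RPM.
PSEUDO_READS = 0.5


@dataclass
class IsoformPair:
    """The top-two 3'UTR pA isoforms of a gene in one comparison."""

    gene_id: str
    prox_pa: PaCluster
    dist_pa: PaCluster
    rpm_prx: np.ndarray  # per sample, comparison order
    rpm_dis: np.ndarray
    re: np.ndarray  # per-sample RE


@dataclass
class GeneUtrSummary:
    gene_id: str
    cutr: Optional[tuple[int, int]]
    autr: Optional[tuple[int, int]]
    sutr: bool
    weighted_utr_size: Optional[float]
    total_pass_reads: int


def relative_expression(rpm_prx: float, rpm_dis: float, pseudo: float = 0.0) -> float:
    """RE = log2((rpm_dis + pseudo) / (rpm_prx + pseudo))."""
    num, den = rpm_dis + pseudo, rpm_prx + pseudo
    if num <= 0 or den <= 0:
        raise ValueError("RE undefined: zero isoform RPM and no pseudocount")
    return math.log2(num / den)


def re_from_counts(prx: float, dis: float, scale: float = 1.0) -> float:
    """RE from raw counts with the package pseudocount policy.

    ``scale`` converts reads to RPM (1e6 / total PASS reads); it cancels
    in RED and Z computations but keeps reported RE on the RPM scale.
    """
    pseudo = PSEUDO_READS if (prx == 0 or dis == 0) else 0.0
    return relative_expression((prx + pseudo) * scale, (dis + pseudo) * scale)


def red(re_sample_a: float, re_sample_b: float) -> float:
    """RED = RE(later sample B) - RE(earlier sample A); negative = shortening."""
    return re_sample_b - re_sample_a


def select_top_isoforms(
    gene: GeneModel,
    matrix: PaCountMatrix,
    samples: Sequence[str],
    min_reads: int = 20,
) -> Optional[IsoformPair]:
    """The two most abundant 3'UTR pA isoforms over the comparing samples.

    Abundance is the read sum across the comparison samples (ties break
    to the larger sum then the 5'-most position); the pair is discarded
    when the combined reads fall below ``min_reads``.
    """
    cands = matrix.gene_clusters(gene.gene_id, PA_3UTR)
    if len(cands) < 2:
        return None

    def sort_key(c: PaCluster):
        total = int(matrix.counts.loc[c.cluster_id, list(samples)].sum())
        oriented = c.summit if gene.strand == "+" else -c.summit
        return (-total, oriented)

    top = sorted(cands, key=sort_key)[:2]
    combined = int(
        sum(matrix.counts.loc[c.cluster_id, list(samples)].sum() for c in top)
    )
    if combined < min_reads:
        return None
    prox, dist = sorted(top, key=lambda c: gene.utr3_size(c.summit))
    rpm = matrix.rpm()
    rpm_prx = rpm.loc[prox.cluster_id, list(samples)].to_numpy(float)
    rpm_dis = rpm.loc[dist.cluster_id, list(samples)].to_numpy(float)
    raw_prx = matrix.counts.loc[prox.cluster_id, list(samples)].to_numpy(float)
    raw_dis = matrix.counts.loc[dist.cluster_id, list(samples)].to_numpy(float)
    res = np.array(
        [
            re_from_counts(p, d, scale=1e6 / t)
            for p, d, t in zip(raw_prx, raw_dis, matrix.totals[list(samples)])
        ]
    )
    return IsoformPair(gene.gene_id, prox, dist, rpm_prx, rpm_dis, res)


def weighted_utr_size(
    gene: GeneModel,
    matrix: PaCountMatrix,
    sample: str,
    min_reads: int = 50,
) -> Optional[float]:
    """Read-weighted mean 3'UTR size in one sample; None below ``min_reads``."""
    clusters = matrix.gene_clusters(gene.gene_id, PA_3UTR)
    if not clusters:
        return None
    reads = np.array([matrix.counts.loc[c.cluster_id, sample] for c in clusters], float)
    if reads.sum() < min_reads:
        return None
    sizes = np.array([gene.utr3_size(c.summit) for c in clusters], float)
    return float((sizes * reads).sum() / reads.sum())


def gene_utr_summary(
    gene: GeneModel, matrix: PaCountMatrix, sample: str, min_reads: int = 50
) -> GeneUtrSummary:
    """cUTR/aUTR partition from the gene's detected 3'UTR pAs.

    The cUTR runs from the stop codon to the first detected pA and the
    aUTR from the first to the last detected pA (pooled over samples).
    """
    clusters = matrix.gene_clusters(gene.gene_id, PA_3UTR)
    total = int(matrix.counts.loc[[c.cluster_id for c in clusters], sample].sum()) if clusters else 0
    if not clusters:
        return GeneUtrSummary(gene.gene_id, None, None, False, None, 0)
    by_size = sorted(clusters, key=lambda c: gene.utr3_size(c.summit))
    first, last = by_size[0].summit, by_size[-1].summit
    cutr = gene.utr3_interval(first)
    if len(clusters) == 1:
        autr = None
    elif gene.strand == "+":
        autr = (first + 1, last + 1)
    else:
        autr = (last, first)
    return GeneUtrSummary(
        gene.gene_id,
        cutr,
        autr,
        sutr=len(clusters) == 1,
        weighted_utr_size=weighted_utr_size(gene, matrix, sample, min_reads),
        total_pass_reads=total,
    )


def gene_expression_rpm(gene: GeneModel, matrix: PaCountMatrix, sample: str) -> float:
    """Gene expression as summed RPM over its 3'-most-exon (3'UTR) pAs."""
    clusters = matrix.gene_clusters(gene.gene_id, PA_3UTR)
    if not clusters:
        return 0.0
    rpm = matrix.rpm()
    return float(sum(rpm.loc[c.cluster_id, sample] for c in clusters))


def aggregate_sets(
    gene: GeneModel,
    matrix: PaCountMatrix,
    mode: str,
    tss_exclusion: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool pA counts into two pseudo-isoform vectors for set-level APA.

    ``cds_apa``: (sum of intron + upstream-exon pA counts, sum of
    3'-most-exon pA counts).  ``uarna``: (sum of antisense uaRNA pA
    counts, sum of sense counts excluding pAs within ``tss_exclusion``
    nt downstream of the TSS).  Vectors are per-sample, matrix order.
    """
    clusters = matrix.gene_clusters(gene.gene_id)
    zero = np.zeros(len(matrix.samples), dtype=int)

    def total(cs: list[PaCluster]) -> np.ndarray:
        if not cs:
            return zero.copy()
        return matrix.counts.loc[[c.cluster_id for c in cs]].sum(axis=0).to_numpy()

    if mode == "cds_apa":
        cds = [c for c in clusters if c.feature_class in (PA_INTRON, PA_UPSTREAM_EXON)]
        utr = [c for c in clusters if c.feature_class == PA_3UTR]
        return total(cds), total(utr)
    if mode == "uarna":
        ua = [c for c in clusters if c.feature_class == PA_UARNA]
        sense = []
        for c in clusters:
            if c.feature_class in (PA_UARNA,):
                continue
            d = c.summit - gene.tss if gene.strand == "+" else gene.tss - c.summit
            if 0 <= d < tss_exclusion:
                continue  # promoter-proximal sense pAs are excluded
            sense.append(c)
        return total(ua), total(sense)
    raise ValueError(f"unknown mode {mode!r}")


def intron_position_group(intron_index: int, n_introns: int) -> str:
    """Label an intron +1/+2 (first two), -1/-2 (last two) or M (middle).

    5' labels take priority when a short gene makes labels conflict
    (e.g. intron 2 of 3 is +2, not -2).  ``intron_index`` is 1-based
    from the 5' end.
    """
    if not 1 <= intron_index <= n_introns:
        raise ValueError(f"intron index {intron_index} out of range 1..{n_introns}")
    if intron_index == 1:
        return "+1"
    if intron_index == 2:
        return "+2"
    if intron_index == n_introns:
        return "-1"
    if intron_index == n_introns - 1:
        return "-2"
    return "M"


def classify_sutr_regulation(
    rpm_a: float, rpm_b: float, fold: float = 1.4
) -> str:
    """up / down / flat by a strict >``fold`` RPM change for sUTR genes."""
    pseudo = PSEUDO_READS if (rpm_a == 0 or rpm_b == 0) else 0.0
    a, b = rpm_a + pseudo, rpm_b + pseudo
    if b / a > fold:
        return "up"
    if a / b > fold:
        return "down"
    return "flat"


def autr_size_bins(sizes: dict[str, int], n_bins: int = 5) -> dict[str, int]:
    """Quantile-bin genes by aUTR size (bin 1 = shortest aUTRs)."""
    gene_ids = list(sizes)
    values = np.array([sizes[g] for g in gene_ids], float)
    ranks = values.argsort().argsort()
    bins = (ranks * n_bins // len(values)) + 1
    return {g: int(b) for g, b in zip(gene_ids, bins)}
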