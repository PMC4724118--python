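"""PASS-read extraction, polyA-site clustering and feature assignment.

3'READS reads begin with the poly(A)-derived T-stretch, so after
alignment they sit antisense to the transcript and the T-run is left
soft-clipped.  A read with >=2 unaligned Ts at its 5' end is a polyA
site-supporting (PASS) read; its cleavage position is the transcript-
strand-oriented last aligned base.  Cleavage positions within 24 nt of
each other are clustered greedily around read-count summits, and each
cluster is assigned a feature class relative to the gene annotation
(3'UTR, intron, upstream exon, antisense uaRNA, or intergenic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .models import (
    PA_3UTR,
    PA_INTERGENIC,
    PA_INTRON,
    PA_UARNA,
    PA_UPSTREAM_EXON,
    GeneModel,
    PaCluster,
    PaCountMatrix,
    revcomp,
)

log = logging.getLogger(__name__)

PosCounts = dict[tuple[str, str, int], int]


@dataclass
class AlignedRead:
    """One 3'-end-seq alignment, reduced to what PASS calling needs.

    ``strand`` is the strand of the transcript the read evidences (the
    alignment strand is the opposite, because the read is the reverse
    complement of the transcript 3' end).  ``leading_softclip_seq`` is
    the soft-clipped sequence at the read's sequenced 5' end, given in
    read orientation, so a genuine poly(A) tail shows up as a T-run.
    """

    chrom: str
    strand: str
    aln_start: int
    aln_end: int
    leading_softclip_seq: str
    mapq: int = 255

    @property
    def cleavage_position(self) -> int:
        """Genomic coordinate of the last transcribed base."""
        return self.aln_end - 1 if self.strand == "+" else self.aln_start


def read_sam(path: str, min_mapq: Optional[int] = None) -> list[AlignedRead]:
    """Load 3'-end-seq alignments from SAM/BAM into AlignedRead records.

    Flag-16 alignments have the read's 5' clip on the right in genome
    coordinates and stored reverse-complemented; it is un-flipped here.
    """
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if min_mapq is not None and rec.mapping_quality <= min_mapq:
                continue
            cig = rec.cigartuples or []
            seq = rec.query_sequence or ""
            if rec.is_reverse:
                clip = seq[len(seq) - cig[-1][1]:] if cig and cig[-1][0] == 4 else ""
                clip = revcomp(clip)
                strand = "+"  # transcript strand opposite the alignment
            else:
                clip = seq[: cig[0][1]] if cig and cig[0][0] == 4 else ""
                strand = "-"
            out.append(
                AlignedRead(
                    chrom=rec.reference_name,
                    strand=strand,
                    aln_start=rec.reference_start,
                    aln_end=rec.reference_end,
                    leading_softclip_seq=clip,
                    mapq=rec.mapping_quality,
                )
            )
    return out


def _clip_t_run(clip: str) -> int:
    """Consecutive Ts at the clip end adjacent to the aligned bases."""
    n = 0
    for base in reversed(clip.upper()):
        if base != "T":
            break
        n += 1
    return n


def extract_pass_reads(
    reads: Iterable[AlignedRead], min_t: int = 2
) -> tuple[PosCounts, int]:
    """Per-position cleavage counts from PASS reads.

    A read is PASS iff its 5' soft clip carries >= ``min_t`` consecutive
    Ts next to the aligned portion; other reads are dropped and counted.
    """
    counts: PosCounts = {}
    dropped = 0
    for r in reads:
        if r.leading_softclip_seq is None:
            log.warning("read without soft-clip info treated as non-PASS")
            dropped += 1
            continue
        if _clip_t_run(r.leading_softclip_seq) >= min_t:
            key = (r.chrom, r.strand, r.cleavage_position)
            counts[key] = counts.get(key, 0) + 1
        else:
            dropped += 1
    return counts, dropped


def _greedy_cluster(
    positions: np.ndarray, counts: np.ndarray, window: int, strand: str
) -> list[tuple[int, list[int]]]:
    """(summit, member positions) by repeated summit-and-absorb.

    The unassigned position with most reads becomes a summit (ties go to
    the 5'-most strand-oriented position); all unassigned positions
    within ``window`` nt of it join its cluster.
    """
    order_pos = positions if strand == "+" else -positions
    # sort by (-count, strand-oriented position) so index 0 is next summit
    order = np.lexsort((order_pos, -counts))
    positions, counts = positions[order], counts[order]
    unassigned = np.ones(len(positions), dtype=bool)
    out = []
    for i in range(len(positions)):
        if not unassigned[i]:
            continue
        summit = positions[i]
        near = unassigned & (np.abs(positions - summit) <= window)
        out.append((int(summit), [int(p) for p in positions[near]]))
        unassigned &= ~near
    return out


def cluster_pa(pos_counts: PosCounts, window: int = 24) -> list[PaCluster]:
    """Cluster per-position cleavage counts into polyA sites.

    Positions within ``window`` nt of a summit merge into it; retained
    summits on one strand are therefore > ``window`` nt apart.
    """
    groups: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for (chrom, strand, pos), n in pos_counts.items():
        groups.setdefault((chrom, strand), []).append((pos, n))
    clusters: list[PaCluster] = []
    for (chrom, strand), items in sorted(groups.items()):
        positions = np.array([p for p, _ in items])
        counts = np.array([n for _, n in items])
        lookup = dict(items)
        for summit, members in _greedy_cluster(positions, counts, window, strand):
            clusters.append(
                PaCluster(
                    chrom=chrom,
                    strand=strand,
                    summit=summit,
                    span=(min(members), max(members) + 1),
                    counts=np.array([sum(lookup[m] for m in members)]),
                    members=sorted(members),
                )
            )
    clusters.sort(key=lambda c: (c.chrom, c.strand, c.summit))
    return clusters


# ---------------------------------------------------------------------------
# feature assignment
# ---------------------------------------------------------------------------

def _within_gene_class(gene: GeneModel, pos: int) -> Optional[str]:
    """3'-most exon > intron > upstream exon precedence inside one gene."""
    s, e = gene.threeprime_exon
    if s <= pos < e:
        downstream_of_stop = (
            pos >= gene.stop_codon if gene.strand == "+" else pos <= gene.stop_codon
        )
        return PA_3UTR if downstream_of_stop else PA_UPSTREAM_EXON
    for is_, ie in gene.introns:
        if is_ <= pos < ie:
            return PA_INTRON
    for es, ee in gene.exons[:-1] if gene.exons else []:
        if es <= pos < ee:
            return PA_UPSTREAM_EXON
    return None


def assign_pa(
    clusters: Sequence[PaCluster],
    genes: Sequence[GeneModel],
    uarna_window: int = 2000,
) -> list[PaCluster]:
    """Assign feature class and gene to each cluster (in place).

    Precedence inside a gene: 3'-most exon > intron > upstream exon.
    Across genes the gene whose 3'-most exon contains the pA wins, then
    the nearest stop codon; ambiguous assignments are flagged.  A pA
    antisense to a gene and within ``uarna_window`` nt upstream of its
    TSS, contained in no same-strand gene, is a uaRNA pA.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    by_strand_chrom: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        s, e = g.span
        trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(s, e, g)
        by_strand_chrom.setdefault((g.chrom, g.strand), []).append(g)

    for clu in clusters:
        tree = trees.get((clu.chrom, clu.strand))
        hits = []
        if tree is not None:
            for iv in tree.at(clu.summit):
                cls = _within_gene_class(iv.data, clu.summit)
                if cls is not None:
                    hits.append((iv.data, cls))
        if hits:
            if len(hits) > 1:
                clu.flags.append("multi_gene")
            in_3p = [(g, c) for g, c in hits if c in (PA_3UTR, PA_UPSTREAM_EXON)
                     and g.threeprime_exon[0] <= clu.summit < g.threeprime_exon[1]]
            pool = in_3p or hits
            gene, cls = min(pool, key=lambda gc: abs(gc[0].stop_codon - clu.summit))
            clu.gene_id = gene.gene_id
            clu.feature_class = cls
            clu.utr3_size = gene.utr3_size(clu.summit) if cls == PA_3UTR else None
            continue
        # antisense upstream-of-TSS (uaRNA) check
        anti = "-" if clu.strand == "+" else "+"
        best: Optional[GeneModel] = None
        best_d = uarna_window + 1
        for g in by_strand_chrom.get((clu.chrom, anti), []):
            d = g.tss - clu.summit if g.strand == "+" else clu.summit - g.tss
            if 0 < d <= uarna_window and d < best_d:
                best, best_d = g, d
        if best is not None:
            clu.gene_id = best.gene_id
            clu.feature_class = PA_UARNA
        else:
            clu.feature_class = PA_INTERGENIC
    return list(clusters)


# ---------------------------------------------------------------------------
# matrix construction
# ---------------------------------------------------------------------------

def build_matrix(
    per_sample_counts: Mapping[str, PosCounts], window: int = 24
) -> PaCountMatrix:
    """Cluster on pooled positions, then split counts per sample.

    All samples share one clustering (so the same pA has the same row in
    every column); per-sample totals are the RPM denominators.
    """
    pooled: PosCounts = {}
    for counts in per_sample_counts.values():
        for key, n in counts.items():
            pooled[key] = pooled.get(key, 0) + n
    clusters = cluster_pa(pooled, window=window)
    samples = list(per_sample_counts)
    table = np.zeros((len(clusters), len(samples)), dtype=int)
    for ci, clu in enumerate(clusters):
        keys = [(clu.chrom, clu.strand, m) for m in clu.members]
        for si, sample in enumerate(samples):
            counts = per_sample_counts[sample]
            table[ci, si] = sum(counts.get(k, 0) for k in keys)
    df = pd.DataFrame(table, index=[c.cluster_id for c in clusters], columns=samples)
    totals = df.sum(axis=0)
    for ci, clu in enumerate(clusters):
        clu.counts = table[ci]
    return PaCountMatrix(clusters=clusters, samples=samples, counts=df, totals=totals)


def call_polya_sites(
    reads_by_sample: Mapping[str, Iterable[AlignedRead]],
    genes: Optional[Sequence[GeneModel]] = None,
    min_t: int = 2,
    window: int = 24,
    uarna_window: int = 2000,
) -> PaCountMatrix:
    """End-to-end: PASS extraction -> clustering -> assignment -> matrix."""
    per_sample = {
        s: extract_pass_reads(reads, min_t=min_t)[0]
        for s, reads in reads_by_sample.items()
    }
    matrix = build_matrix(per_sample, window=window)
    if genes is not None:
        assign_pa(matrix.clusters, genes, uarna_window=uarna_window)
    return matrix


def sam_reads_to_aligned(reads) -> list[AlignedRead]:
    """Convert simulator ``SamRead`` records without a SAM round trip."""
    out = []
    for r in reads:
        clip_len = 0
        cigar = r.cigar
        if r.flag & 16:
            strand = "+"
            if cigar.endswith("S"):
                body = cigar[:-1]
                i = len(body)
                while i > 0 and body[i - 1].isdigit():
                    i -= 1
                clip_len = int(body[i:])
            clip = revcomp(r.seq[len(r.seq) - clip_len:]) if clip_len else ""
        else:
            strand = "-"
            i = 0
            while i < len(cigar) and cigar[i].isdigit():
                i += 1
            if i < len(cigar) and cigar[i] == "S":
                clip_len = int(cigar[:i])
            clip = r.seq[:clip_len] if clip_len else ""
        aligned_len = len(r.seq) - clip_len
        out.append(
            AlignedRead(
                chrom=r.chrom,
                strand=strand,
                aln_start=r.pos,
                aln_end=r.pos + aligned_len,
                leading_softclip_seq=clip,
                mapq=r.mapq,
            )
        )
    return out
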