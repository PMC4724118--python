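"""Shared genomic data model for the APA analysis pipeline.

Coordinate conventions (used consistently across the package):

* all coordinates are 0-based, half-open ``[start, end)`` on the forward
  genome; BED output matches directly;
* a polyA site (pA) is the genomic coordinate of the *last transcribed
  nucleotide* of the isoform that ends there — on the + strand the
  transcript covers ``[..., pa + 1)``, on the − strand ``[pa, ...)``;
* ``stop_codon`` stores the coordinate of the first 3'UTR base (the base
  immediately downstream of the stop codon in transcript orientation), so
  the 3'UTR of a + strand gene is ``[stop_codon, pa + 1)`` and the 3'UTR
  size of an isoform is the strand-oriented distance from ``stop_codon``
  to its pA, inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

Interval = tuple[int, int]

# feature classes a pA can carry
PA_3UTR = "3UTR"
PA_INTRON = "intron"
PA_UPSTREAM_EXON = "upstream_exon"
PA_UARNA = "uaRNA"
PA_INTERGENIC = "intergenic"


def strand_distance(strand: str, upstream: int, downstream: int) -> int:
    """Signed distance from ``upstream`` to ``downstream`` walking 5'->3'."""
    return downstream - upstream if strand == "+" else upstream - downstream


@dataclass
class GeneModel:
    """One gene's structure: TSS, stop codon, exons/introns and its pAs.

    ``exons`` and ``introns`` are listed in transcription (5'->3') order;
    each interval is genomic ``(start, end)`` with ``start < end``.
    ``pa_positions`` is a list of ``(coordinate, feature_class)`` pairs with
    feature_class in {"3UTR", "intron", "upstream_exon"}.  An optional
    antisense pA upstream of the TSS (a uaRNA / PROMPT 3' end) is kept in
    ``uarna_pa``; it lives on the opposite strand.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    stop_codon: int
    exons: list[Interval]
    introns: list[Interval]
    threeprime_exon: Interval
    pa_positions: list[tuple[int, str]] = field(default_factory=list)
    uarna_pa: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for s, e in self.exons:
            if s >= e:
                raise ValueError("empty exon interval")

    # -- genomic extent -------------------------------------------------
    @property
    def span(self) -> Interval:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    # -- 3'UTR geometry -------------------------------------------------
    @property
    def utr3_pas(self) -> list[int]:
        """3'UTR pA coordinates sorted proximal (near stop) to distal."""
        pas = [p for p, c in self.pa_positions if c == PA_3UTR]
        return sorted(pas, key=lambda p: self.utr3_size(p))

    def utr3_size(self, pa: int) -> int:
        """Strand-oriented 3'UTR size (nt) of the isoform ending at ``pa``."""
        return strand_distance(self.strand, self.stop_codon, pa) + 1

    def utr3_interval(self, pa: int) -> Interval:
        """Genomic interval of the 3'UTR of the isoform ending at ``pa``."""
        if self.strand == "+":
            return self.stop_codon, pa + 1
        return pa, self.stop_codon + 1

    def cutr_interval(self) -> Optional[Interval]:
        """Common UTR: stop codon to the first (proximal) pA; None if no pA."""
        pas = self.utr3_pas
        if not pas:
            return None
        return self.utr3_interval(pas[0])

    def autr_interval(self) -> Optional[Interval]:
        """Alternative UTR: first pA to last pA; None for sUTR genes."""
        pas = self.utr3_pas
        if len(pas) < 2:
            return None
        prox, dist = pas[0], pas[-1]
        if self.strand == "+":
            return prox + 1, dist + 1
        return dist, prox

    @property
    def is_sutr(self) -> bool:
        return len(self.utr3_pas) == 1

    def cds_intervals(self) -> list[Interval]:
        """Exonic sequence upstream of the 3'UTR (a coding-region proxy)."""
        out = []
        for s, e in self.exons:
            if self.strand == "+":
                s2, e2 = s, min(e, self.stop_codon)
            else:
                s2, e2 = max(s, self.stop_codon + 1), e
            if s2 < e2:
                out.append((s2, e2))
        return out

    def contains(self, pos: int) -> bool:
        s, e = self.span
        return s <= pos < e


@dataclass
class PaCluster:
    """A clustered polyA site with its per-sample PASS-read counts."""

    chrom: str
    strand: str
    summit: int
    span: Interval
    counts: Optional[np.ndarray] = None  # aligned with matrix sample order
    feature_class: str = PA_INTERGENIC
    gene_id: Optional[str] = None
    utr3_size: Optional[int] = None
    members: list[int] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def cluster_id(self) -> str:
        return f"{self.chrom}:{self.strand}:{self.summit}"


@dataclass
class PaCountMatrix:
    """Genes x pAs x samples PASS-read count table.

    ``counts`` is indexed by cluster id with one column per sample;
    ``totals`` holds the per-sample total PASS reads used as the
    reads-per-million denominator (column sums genome-wide).
    """

    clusters: list[PaCluster]
    samples: list[str]
    counts: pd.DataFrame
    totals: pd.Series

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples):
            raise ValueError("count columns do not match sample list")

    def rpm(self) -> pd.DataFrame:
        """Reads per million PASS reads; errors on a zero-total sample."""
        if (self.totals <= 0).any():
            bad = list(self.totals.index[self.totals <= 0])
            raise ValueError(f"RPM undefined for zero-total sample(s) {bad}")
        return self.counts / self.totals * 1e6

    def cluster_by_id(self, cluster_id: str) -> PaCluster:
        for c in self.clusters:
            if c.cluster_id == cluster_id:
                return c
        raise KeyError(cluster_id)

    def gene_clusters(self, gene_id: str, feature_class: str | None = None) -> list[PaCluster]:
        out = [c for c in self.clusters if c.gene_id == gene_id]
        if feature_class is not None:
            out = [c for c in out if c.feature_class == feature_class]
        return out


COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]
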