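"""RNA-seq and ChIP-seq couplings of APA state.

RNA-seq: the aUTR:cUTR read-density ratio, log2(aUTR/cUTR), reflects
long- vs short-3'UTR isoform expression without 3'-end data; CDS-only
RPKM gives gene expression untouched by 3'UTR changes.  ChIP-seq: after
a MAPQ > 10 filter and duplicate collapse, reads (represented by their
5' ends) are binned in 50-nt steps flanking the TSS and the last pA and
in 100 percentile bins over the gene body; the per-bin enrichment score
is log2(RPM_IP / RPM_input) with a half-read pseudocount on both sides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .models import GeneModel
from .apa_metrics import GeneUtrSummary

log = logging.getLogger(__name__)


@dataclass
class CoverageTrack:
    """Deduplicated, MAPQ-filtered read anchors (5'-end positions)."""

    sample_id: str
    anchors: dict[tuple[str, str], np.ndarray]  # (chrom, strand) -> sorted
    total: int
    mapq_floor: int

    def count(
        self, chrom: str, start: int, end: int, strand: Optional[str] = None
    ) -> int:
        """Anchors within [start, end); both strands unless one is given."""
        strands = [strand] if strand else ["+", "-"]
        n = 0
        for s in strands:
            arr = self.anchors.get((chrom, s))
            if arr is not None:
                n += int(np.searchsorted(arr, end) - np.searchsorted(arr, start))
        return n

    @property
    def rpm_pseudo(self) -> float:
        """RPM equivalent of half a read, the score pseudocount."""
        return 0.5 / max(self.total, 1) * 1e6

    def rpm(self, chrom: str, start: int, end: int, strand: Optional[str] = None) -> float:
        return self.count(chrom, start, end, strand) / max(self.total, 1) * 1e6


def _read_tuples(reads: Iterable) -> Iterable[tuple[str, str, int, int, int]]:
    """(chrom, strand, start, end, mapq) from SamRead-like or tuples."""
    for r in reads:
        if isinstance(r, tuple):
            yield r
            continue
        strand = "-" if r.flag & 16 else "+"
        ref_len = _cigar_ref_len(r.cigar)
        yield (r.chrom, strand, r.pos, r.pos + ref_len, r.mapq)


def _cigar_ref_len(cigar: str) -> int:
    n, total = "", 0
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            if ch in "MDN=X":
                total += int(n)
            n = ""
    return total


def dedupe_filter(
    reads: Iterable, mapq_floor: int = 10, sample_id: str = "track"
) -> CoverageTrack:
    """Drop MAPQ <= floor, collapse duplicate loci, anchor at 5' ends.

    A duplicate is an identical (chrom, strand, start, end); the strict
    ``>`` keeps only confidently unique alignments.
    """
    seen: set[tuple[str, str, int, int]] = set()
    anchors: dict[tuple[str, str], list[int]] = {}
    for chrom, strand, start, end, mapq in _read_tuples(reads):
        if mapq <= mapq_floor:
            continue
        key = (chrom, strand, start, end)
        if key in seen:
            continue
        seen.add(key)
        five_prime = start if strand == "+" else end - 1
        anchors.setdefault((chrom, strand), []).append(five_prime)
    packed = {k: np.sort(np.array(v, dtype=int)) for k, v in anchors.items()}
    total = sum(len(v) for v in packed.values())
    return CoverageTrack(sample_id, packed, total, mapq_floor)


def track_from_sam(path: str, mapq_floor: int = 10, sample_id: str = "track") -> CoverageTrack:
    def gen():
        with pysam.AlignmentFile(path, check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                yield (
                    rec.reference_name,
                    "-" if rec.is_reverse else "+",
                    rec.reference_start,
                    rec.reference_end,
                    rec.mapping_quality,
                )
    return dedupe_filter(gen(), mapq_floor=mapq_floor, sample_id=sample_id)


# ---------------------------------------------------------------------------
# RNA-seq couplings
# ---------------------------------------------------------------------------

def autr_cutr_ratio(
    track: CoverageTrack,
    gene: GeneModel,
    summary: Optional[GeneUtrSummary] = None,
    pseudo: float = 0.0,
) -> Optional[float]:
    """log2 of aUTR read density over cUTR read density (sense reads).

    Uses the gene's annotated cUTR/aUTR unless a detected-pA summary is
    given; returns None when the gene has no aUTR, zero-length regions,
    or zero cUTR reads with no pseudocount configured.
    """
    cutr = summary.cutr if summary else gene.cutr_interval()
    autr = summary.autr if summary else gene.autr_interval()
    if not cutr or not autr or cutr[1] - cutr[0] == 0 or autr[1] - autr[0] == 0:
        return None
    d_c = track.count(gene.chrom, *cutr, strand=gene.strand) / (cutr[1] - cutr[0])
    d_a = track.count(gene.chrom, *autr, strand=gene.strand) / (autr[1] - autr[0])
    if d_c + pseudo == 0 or d_a + pseudo == 0:
        return None
    return float(np.log2((d_a + pseudo) / (d_c + pseudo)))


def cds_expression(track: CoverageTrack, gene: GeneModel) -> Optional[float]:
    """RPKM over the CDS only, immune to 3'UTR length changes."""
    cds = gene.cds_intervals()
    length = sum(e - s for s, e in cds)
    if length == 0 or track.total == 0:
        return None
    reads = sum(track.count(gene.chrom, s, e, strand=gene.strand) for s, e in cds)
    return reads / (length / 1e3) / (track.total / 1e6)


# ---------------------------------------------------------------------------
# ChIP-seq profiles
# ---------------------------------------------------------------------------

@dataclass
class BinProfile:
    gene_id: str
    bins: pd.DataFrame  # columns: label, anchor, score (5'->3' order)


def _gene_last_pa(gene: GeneModel) -> int:
    pas = gene.utr3_pas
    return pas[-1] if pas else (gene.threeprime_exon[1] - 1 if gene.strand == "+" else gene.threeprime_exon[0])


def _gene_bins(
    gene: GeneModel, flank: int, bin_size: int, n_body_bins: int
) -> Optional[list[tuple[str, str, int, int]]]:
    """(label, anchor, start, end) bins 5'->3'; None if body too short."""
    last_pa = _gene_last_pa(gene)
    body_len = abs(last_pa - gene.tss) + 1
    if body_len < n_body_bins:
        return None
    n_flank = flank // bin_size
    bins: list[tuple[str, str, int, int]] = []
    if gene.strand == "+":
        for i in range(n_flank, 0, -1):
            s = gene.tss - i * bin_size
            bins.append((f"up{-i}", "TSS", s, s + bin_size))
        edges = np.linspace(gene.tss, last_pa + 1, n_body_bins + 1).astype(int)
        for j in range(n_body_bins):
            bins.append((f"body{j + 1}", "body", int(edges[j]), int(edges[j + 1])))
        for i in range(1, n_flank + 1):
            s = last_pa + 1 + (i - 1) * bin_size
            bins.append((f"down{i}", "lastPA", s, s + bin_size))
    else:
        for i in range(n_flank, 0, -1):
            e = gene.tss + 1 + i * bin_size
            bins.append((f"up{-i}", "TSS", e - bin_size, e))
        edges = np.linspace(gene.tss + 1, last_pa, n_body_bins + 1).astype(int)
        for j in range(n_body_bins):
            bins.append((f"body{j + 1}", "body", int(edges[j + 1]), int(edges[j])))
        for i in range(1, n_flank + 1):
            e = last_pa - (i - 1) * bin_size
            bins.append((f"down{i}", "lastPA", e - bin_size, e))
    return [(lab, anc, max(0, s), max(0, e)) for lab, anc, s, e in bins]


def _bin_score(
    ip: CoverageTrack, inp: CoverageTrack, chrom: str, start: int, end: int
) -> float:
    return float(
        np.log2(
            (ip.rpm(chrom, start, end) + ip.rpm_pseudo)
            / (inp.rpm(chrom, start, end) + inp.rpm_pseudo)
        )
    )


def chip_profile(
    track_ip: CoverageTrack,
    track_input: CoverageTrack,
    genes: Sequence[GeneModel],
    flank: int = 1000,
    bin_size: int = 50,
    n_body_bins: int = 100,
) -> tuple[dict[str, BinProfile], pd.DataFrame]:
    """Per-gene binned enrichment profiles and their per-bin mean.

    The aggregate takes the mean of per-gene bin scores (not pooled
    reads), so deeply covered genes do not dominate; genes whose body is
    shorter than the percentile-bin count are skipped with a warning.
    """
    profiles: dict[str, BinProfile] = {}
    for gene in genes:
        bins = _gene_bins(gene, flank, bin_size, n_body_bins)
        if bins is None:
            log.warning("gene %s body too short for percentile bins; skipped", gene.gene_id)
            continue
        rows = [
            (lab, anc, _bin_score(track_ip, track_input, gene.chrom, s, e))
            for lab, anc, s, e in bins
        ]
        profiles[gene.gene_id] = BinProfile(
            gene.gene_id, pd.DataFrame(rows, columns=["label", "anchor", "score"])
        )
    if profiles:
        stack = pd.concat(
            [p.bins.assign(gene_id=g) for g, p in profiles.items()], ignore_index=True
        )
        order = next(iter(profiles.values())).bins["label"].tolist()
        agg = (
            stack.groupby("label", sort=False)["score"].mean().reindex(order).to_frame()
        )
    else:
        agg = pd.DataFrame(columns=["score"])
    return profiles, agg


def region_scores(
    track_ip: CoverageTrack,
    track_input: CoverageTrack,
    genes: Sequence[GeneModel],
    flank: int = 1000,
) -> pd.DataFrame:
    """Per-gene summary scores: TSS +/- flank, gene body, last pA +/- flank."""
    rows = []
    for gene in genes:
        last_pa = _gene_last_pa(gene)
        lo, hi = sorted((gene.tss, last_pa))
        rows.append(
            (
                gene.gene_id,
                _bin_score(track_ip, track_input, gene.chrom, gene.tss - flank, gene.tss + flank + 1),
                _bin_score(track_ip, track_input, gene.chrom, lo, hi + 1),
                _bin_score(track_ip, track_input, gene.chrom, last_pa - flank, last_pa + flank + 1),
            )
        )
    return pd.DataFrame(rows, columns=["gene_id", "tss", "body", "last_pa"]).set_index("gene_id")
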