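"""Transposable-element content of 3'UTR segments and the type 1-4 gene
classification, plus the generic two-group distribution comparisons
(Kolmogorov-Smirnov, Wilcoxon rank-sum) used throughout the analysis.

TE coverage is computed on the union of (possibly overlapping) TE
intervals, as a nucleotide fraction of each region class; "contains a
TE" means at least one overlapping nucleotide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import PA_3UTR, GeneModel, PaCountMatrix

TE_CLASSES = ("LINE", "SINE", "LTR", "DNA", "other")


@dataclass
class TeInterval:
    chrom: str
    start: int
    end: int
    te_class: str = "other"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("TE interval must have start < end")


@dataclass
class TeGeneType:
    gene_id: str
    apa_class: str  # shortened / unchanged / lengthened / sutr
    te_in_autr: bool
    te_in_cutr: bool
    te_in_sutr: bool
    type: str  # "1".."4" or "none"


def read_te_bed(path: str) -> list[TeInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            cls = f[3].strip() if len(f) > 3 else "other"
            out.append(TeInterval(f[0], int(f[1]), int(f[2]),
                                  cls if cls in TE_CLASSES else "other"))
    return out


def _merged(tes: Sequence[TeInterval], chrom: str) -> list[tuple[int, int]]:
    ivs = sorted((t.start, t.end) for t in tes if t.chrom == chrom)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _overlap(region: tuple[int, int], merged: Sequence[tuple[int, int]]) -> int:
    s, e = region
    return sum(max(0, min(e, te) - max(s, ts)) for ts, te in merged)


def te_fraction(
    regions: Sequence[tuple[str, int, int]], tes: Sequence[TeInterval]
) -> float:
    """Union-TE nucleotides / region nucleotides, pooled over the regions."""
    total = sum(e - s for _, s, e in regions)
    if total == 0:
        raise ValueError("te_fraction undefined for a zero-length region set")
    merged_by_chrom: dict[str, list[tuple[int, int]]] = {}
    covered = 0
    for chrom, s, e in regions:
        if chrom not in merged_by_chrom:
            merged_by_chrom[chrom] = _merged(tes, chrom)
        covered += _overlap((s, e), merged_by_chrom[chrom])
    return covered / total


def region_contains_te(
    chrom: str, region: tuple[int, int], tes: Sequence[TeInterval]
) -> bool:
    """>=1 overlapping nucleotide counts as containment."""
    return _overlap(region, _merged(tes, chrom)) > 0


def classify_te_types(
    genes: Sequence[GeneModel],
    apa_class: Mapping[str, str],
    tes: Sequence[TeInterval],
) -> list[TeGeneType]:
    """Type 1-4 gene classes from APA regulation x TE location.

    Type 1: shortened, TEs only in aUTR (shortening removes them);
    type 2: shortened, TEs only in cUTR; type 3: unchanged, TEs in aUTR;
    type 4: single 3'UTR containing TEs.  Genes with TEs in both cUTR
    and aUTR are excluded from types 1/2 ("only" read literally).
    The aUTR extent is the annotation's first-to-last pA.
    """
    out = []
    for g in genes:
        cls = apa_class.get(g.gene_id, "sutr" if g.is_sutr else "unchanged")
        cutr, autr = g.cutr_interval(), g.autr_interval()
        in_cutr = bool(cutr and not g.is_sutr and region_contains_te(g.chrom, cutr, tes))
        in_autr = bool(autr and region_contains_te(g.chrom, autr, tes))
        in_sutr = bool(g.is_sutr and cutr and region_contains_te(g.chrom, cutr, tes))
        if cls == "shortened" and in_autr and not in_cutr:
            t = "1"
        elif cls == "shortened" and in_cutr and not in_autr:
            t = "2"
        elif cls == "unchanged" and in_autr:
            t = "3"
        elif g.is_sutr and in_sutr:
            t = "4"
        else:
            t = "none"
        out.append(TeGeneType(g.gene_id, cls, in_autr, in_cutr, in_sutr, t))
    return out


def te_transcript_fraction(
    matrix: PaCountMatrix,
    genes: Sequence[GeneModel],
    tes: Sequence[TeInterval],
) -> pd.Series:
    """Per-sample RPM fraction of 3'UTR isoforms whose UTR contains a TE.

    An isoform contains a TE iff a TE overlaps its 3'UTR up to its pA,
    so shortening away a TE-carrying aUTR lowers the fraction.
    """
    by_gene = {g.gene_id: g for g in genes}
    te_rpm = np.zeros(len(matrix.samples))
    all_rpm = np.zeros(len(matrix.samples))
    rpm = matrix.rpm()
    for clu in matrix.clusters:
        if clu.feature_class != PA_3UTR or clu.gene_id not in by_gene:
            continue
        g = by_gene[clu.gene_id]
        row = rpm.loc[clu.cluster_id].to_numpy(float)
        all_rpm += row
        if region_contains_te(g.chrom, g.utr3_interval(clu.summit), tes):
            te_rpm += row
    with np.errstate(invalid="ignore"):
        frac = np.where(all_rpm > 0, te_rpm / np.maximum(all_rpm, 1e-300), 0.0)
    return pd.Series(frac, index=matrix.samples)


def two_sample_compare(
    values_x: Sequence[float],
    values_y: Sequence[float],
    test: str = "ks",
    method: str = "auto",
) -> tuple[float, float]:
    """Two-sample K-S or Wilcoxon rank-sum (statistic, p).

    ``method="auto"`` uses the exact null distribution when the samples
    are small (matching permutation enumeration) and the asymptotic
    approximation otherwise.
    """
    x = np.asarray(values_x, float)
    y = np.asarray(values_y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs >= 2 values")
    if test == "ks":
        res = stats.ks_2samp(x, y, method=method)
    elif test == "wilcoxon":
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
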