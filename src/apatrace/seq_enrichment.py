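"""Cis-element (k-mer) and gene-set enrichment.

Sequence sets (cUTR / aUTR / sUTR regions, or fixed windows around
cleavage sites) are compared with Fisher's exact test on per-sequence
k-mer presence/absence; the signed significance score SS = -log10(P) x S
(S = +1 when the k-mer is enriched in the foreground, -1 otherwise) lets
enrichment profiles from different comparisons be correlated.  All k-mer
reporting uses the RNA alphabet (U); DNA input is transcribed on read.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, pearsonr

from .models import GeneModel

log = logging.getLogger(__name__)

#: windows around the cleavage site, 1-based offsets in transcript
#: orientation; -1 is the last transcribed base, +1 the first base after.
DEFAULT_FLANK_WINDOWS = {
    "paflank:-100..-41": (-100, -41),
    "paflank:-40..-1": (-40, -1),
    "paflank:+1..+100": (1, 100),
}


@dataclass
class RegionSequence:
    id: str
    label: str
    sequence: str  # RNA alphabet


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _revcomp_dna(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _fetch(genome: Mapping[str, str], chrom: str, start: int, end: int, strand: str) -> str:
    """Strand-oriented subsequence, truncated at contig edges."""
    contig = genome[chrom]
    s, e = max(0, start), min(len(contig), end)
    if (s, e) != (start, end):
        log.warning("region %s:%d-%d truncated at contig edge", chrom, start, end)
    if s >= e:
        return ""
    raw = contig[s:e]
    return _to_rna(raw if strand == "+" else _revcomp_dna(raw))


def extract_regions(
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    labels: Sequence[str] = ("cUTR", "aUTR", "sUTR"),
) -> list[RegionSequence]:
    """cUTR/aUTR/sUTR sequences per gene, strand-oriented, T->U."""
    out: list[RegionSequence] = []
    for g in genes:
        if g.stop_codon is None:
            log.warning("gene %s has no stop codon annotation; skipped", g.gene_id)
            continue
        pick: dict[str, Optional[tuple[int, int]]] = {}
        if g.is_sutr:
            pick["sUTR"] = g.cutr_interval()
        else:
            pick["cUTR"] = g.cutr_interval()
            pick["aUTR"] = g.autr_interval()
        for label, iv in pick.items():
            if label not in labels or iv is None:
                continue
            seq = _fetch(genome, g.chrom, iv[0], iv[1], g.strand)
            if seq:
                out.append(RegionSequence(g.gene_id, label, seq))
    return out


def flank_interval(strand: str, pa: int, lo: int, hi: int) -> tuple[int, int]:
    """Genomic interval of transcript-oriented offsets ``lo..hi`` from a pA."""
    def coord(i: int) -> int:
        if strand == "+":
            return pa + i + 1 if i < 0 else pa + i
        return pa - i - 1 if i < 0 else pa - i

    a, b = coord(lo), coord(hi)
    return (a, b + 1) if a <= b else (b, a + 1)


def extract_pa_flanks(
    pas: Sequence[tuple[str, str, int]],
    genome: Mapping[str, str],
    windows: Mapping[str, tuple[int, int]] = DEFAULT_FLANK_WINDOWS,
) -> dict[str, list[RegionSequence]]:
    """Per-window flank sequences for (chrom, strand, position) pA records."""
    out: dict[str, list[RegionSequence]] = {w: [] for w in windows}
    for chrom, strand, pa in pas:
        for wname, (lo, hi) in windows.items():
            s, e = flank_interval(strand, pa, lo, hi)
            seq = _fetch(genome, chrom, s, e, strand)
            if seq:
                out[wname].append(RegionSequence(f"{chrom}:{strand}:{pa}", wname, seq))
    return out


# ---------------------------------------------------------------------------
# Fisher tests
# ---------------------------------------------------------------------------

def _kmers_of(seq: str, k: int) -> set[str]:
    """Distinct k-mers (overlapping occurrences count once per sequence)."""
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def enrichment_p(
    fg_with: int, fg_total: int, bg_with: int, bg_total: int
) -> tuple[float, str]:
    """One-sided Fisher p in the direction of the observed imbalance.

    Direction "fg" when the foreground proportion is larger, "bg" when
    smaller; equal proportions report p = 1 with no enrichment.  The
    one-sided hypergeometric tail is invariant under swapping foreground
    and background (with the direction flipped), so the signed score is
    exactly antisymmetric.
    """
    n = fg_total + bg_total
    k_tot = fg_with + bg_with
    pf = fg_with / fg_total
    pb = bg_with / bg_total
    if pf == pb:
        return 1.0, "fg"
    if pf > pb:
        p = float(hypergeom.sf(fg_with - 1, n, k_tot, fg_total))
        direction = "fg"
    else:
        p = float(hypergeom.cdf(fg_with, n, k_tot, fg_total))
        direction = "bg"
    return min(max(p, 5e-324), 1.0), direction


def significance_score(p: float, direction: str) -> float:
    """SS = -log10(p), signed + for foreground / - for background."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    return -math.log10(p) * (1.0 if direction == "fg" else -1.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def kmer_fisher(
    fg: Sequence[RegionSequence | str],
    bg: Sequence[RegionSequence | str],
    k: int = 4,
) -> pd.DataFrame:
    """Per-k-mer 2x2 Fisher enrichment of foreground vs background.

    A sequence "has" a k-mer iff it occurs at least once.  Returns one
    row per k-mer observed in either set: the 2x2 table, the one-sided p
    in the observed direction, the signed score ss, and a BH-adjusted q.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    fg_seqs = [_to_rna(s.sequence if isinstance(s, RegionSequence) else s) for s in fg]
    bg_seqs = [_to_rna(s.sequence if isinstance(s, RegionSequence) else s) for s in bg]
    if not fg_seqs or not bg_seqs:
        raise ValueError("foreground and background sets must be non-empty")
    fg_sets = [_kmers_of(s, k) for s in fg_seqs]
    bg_sets = [_kmers_of(s, k) for s in bg_seqs]
    universe = sorted(set().union(*fg_sets, *bg_sets))
    nf, nb = len(fg_seqs), len(bg_seqs)
    rows = []
    for kmer in universe:
        fw = sum(kmer in s for s in fg_sets)
        bw = sum(kmer in s for s in bg_sets)
        p, direction = enrichment_p(fw, nf, bw, nb)
        rows.append((kmer, fw, nf - fw, bw, nb - bw, p, direction,
                     significance_score(p, direction)))
    out = pd.DataFrame(
        rows,
        columns=["kmer", "fg_with", "fg_without", "bg_with", "bg_without",
                 "p", "direction", "ss"],
    ).set_index("kmer")
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def pa_flank_enrichment(
    regulated: Sequence[tuple[str, str, int, str]],
    background: Sequence[tuple[str, str, int, str]],
    genome: Mapping[str, str],
    k: int = 4,
    windows: Mapping[str, tuple[int, int]] = DEFAULT_FLANK_WINDOWS,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Regulated vs other pAs per flank window, proximal and distal apart.

    pA records are (chrom, strand, position, "proximal"|"distal");
    proximal and distal sites form separate comparisons so location-
    linked elements do not masquerade as regulation-linked ones.
    """
    if not regulated:
        raise ValueError("regulated pA set is empty")
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for loc in ("proximal", "distal"):
        reg = [(c, s, p) for c, s, p, l in regulated if l == loc]
        bgp = [(c, s, p) for c, s, p, l in background if l == loc]
        if not reg or not bgp:
            continue
        reg_seqs = extract_pa_flanks(reg, genome, windows)
        bg_seqs = extract_pa_flanks(bgp, genome, windows)
        for wname in windows:
            if reg_seqs[wname] and bg_seqs[wname]:
                out[(wname, loc)] = kmer_fisher(reg_seqs[wname], bg_seqs[wname], k)
    return out


def ss_correlation(ss_x: pd.Series, ss_y: pd.Series) -> float:
    """Pearson r of two signed-score profiles over their shared k-mers."""
    shared = ss_x.index.intersection(ss_y.index)
    x = ss_x.loc[shared].to_numpy(float)
    y = ss_y.loc[shared].to_numpy(float)
    if len(shared) < 2 or np.std(x) == 0 or np.std(y) == 0:
        log.warning("SS correlation undefined (too few k-mers or zero variance)")
        return float("nan")
    return float(pearsonr(x, y)[0])


def set_enrichment(
    gene_set: set[str],
    universe: set[str],
    annotation_map: Mapping[str, set[str]],
) -> pd.DataFrame:
    """One-sided Fisher enrichment of a gene set per annotation term.

    Raw (unadjusted) p values are reported, matching -log10(P) term
    rankings; terms with no genes in the universe are skipped.
    """
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    n = len(universe)
    rows = []
    for term, members in annotation_map.items():
        in_universe = members & universe
        if not in_universe:
            continue
        x = len(in_universe & gene_set)
        p = float(hypergeom.sf(x - 1, n, len(in_universe), len(gene_set)))
        rows.append((term, x, len(in_universe), min(p, 1.0)))
    return pd.DataFrame(
        rows, columns=["term", "set_hits", "term_size", "p"]
    ).set_index("term")
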