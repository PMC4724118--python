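"""Self-contained validation studies run on synthetic data.

Each function generates its own inputs with the synthetic-data module,
runs the relevant pipeline stage, and returns the measured quantity, so
calibration, power, recovery and oracle-agreement numbers can be
recomputed from scratch on any machine.  Problem sizes follow the
package's standard study conditions (documented in the methods note).
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd

from . import apa_metrics, coverage_coupling, pass_reads, saap_gaap, seq_enrichment, te_utr
from .models import PA_3UTR, GeneModel, PaCluster, PaCountMatrix
from .synthetic_data import (
    SimDesign,
    make_annotation,
    simulate_3reads_reads,
    simulate_chipseq_reads,
    simulate_isoform_pair_counts,
    simulate_pa_counts,
    simulate_rnaseq_reads,
)


# ---------------------------------------------------------------------------
# SAAP / GAAP studies
# ---------------------------------------------------------------------------

def saap_null_calibration(
    seeds: Sequence[int] = (1, 2, 3),
    n_genes: int = 2000,
    reads_per_gene: float = 60,
    fdr_target: float = 0.05,
) -> list[float]:
    """Fraction of pure-null genes flagged at the FDR target, per seed."""
    out = []
    for seed in seeds:
        tab = simulate_isoform_pair_counts(n_genes, reads_per_gene, seed=seed)
        tab = tab[(tab.a_prx + tab.a_dis > 0) & (tab.b_prx + tab.b_dis > 0)]
        res, _ = saap_gaap.saap_analysis(
            tab[saap_gaap.COUNT_COLS], fdr_target=fdr_target, seed=seed + 1000
        )
        out.append(float(res["significant"].mean()))
    return out


def saap_power_direction(
    seed: int = 1,
    n_genes: int = 2000,
    n_shift: int = 200,
    reads_per_gene: float = 120,
    red: float = -2.0,
) -> tuple[float, float]:
    """(power, direction accuracy) on planted 3'UTR-shortening genes.

    Power = fraction of planted genes flagged at FDR 5 %; direction =
    fraction of flagged planted genes classified "shortened".
    """
    tab = simulate_isoform_pair_counts(
        n_genes, reads_per_gene, n_shift=n_shift, red=red, seed=seed
    )
    res, _ = saap_gaap.saap_analysis(tab[saap_gaap.COUNT_COLS], seed=seed + 1000)
    planted = tab["shifted"].to_numpy()
    sig = res["significant"].to_numpy()
    power = float(sig[planted].mean())
    flagged = res["fdr_class"].to_numpy()[planted & sig]
    direction = float((flagged == "shortened").mean()) if len(flagged) else 0.0
    return power, direction


def gaap_null_study(
    seed: int = 1,
    n_genes: int = 1500,
    reads_per_gene: float = 200,
    depth: int = 100_000,
    n_rep: int = 10,
) -> saap_gaap.GaapResult:
    """GAAP on a sample compared against its own duplicate (no signal)."""
    tab = simulate_isoform_pair_counts(n_genes, reads_per_gene, seed=seed)
    dup = tab[saap_gaap.COUNT_COLS].copy()
    dup["b_prx"], dup["b_dis"] = dup["a_prx"], dup["a_dis"]
    return saap_gaap.gaap(dup, depth=depth, n_rep=n_rep, seed=seed + 1000)


def gaap_recovery_study(
    seed: int = 1,
    n_genes: int = 1000,
    n_shift: int = 100,
    reads_per_gene: float = 400,
    red: float = -2.0,
    depth: int = 100_000,
    n_rep: int = 10,
) -> saap_gaap.GaapResult:
    """GAAP normalized count with planted regulated genes at high depth."""
    tab = simulate_isoform_pair_counts(
        n_genes, reads_per_gene, n_shift=n_shift, red=red, seed=seed
    )
    return saap_gaap.gaap(tab[saap_gaap.COUNT_COLS], depth=depth, n_rep=n_rep, seed=seed + 1000)


# ---------------------------------------------------------------------------
# pipeline round trip
# ---------------------------------------------------------------------------

def roundtrip_study(seed: int = 1, n_genes: int = 500) -> tuple[int, int]:
    """(max |recovered - simulated| count, number of truth pAs).

    Simulator -> SAM-dialect reads -> PASS extraction -> 24-nt
    clustering -> matrix, with decoy fraction 0 and jitter 5 nt; exact
    recovery gives 0.
    """
    design = SimDesign(n_genes=n_genes, library_size=100_000, seed=seed, decoy_fraction=0.0)
    genes, genome = make_annotation(design)
    truth = simulate_pa_counts(genes, design)
    reads, _ = simulate_3reads_reads(genes, truth, genome, design)
    called = pass_reads.call_polya_sites(
        {s: pass_reads.sam_reads_to_aligned(r) for s, r in reads.items()}, genes
    )
    by_key: dict[tuple[str, str], list[PaCluster]] = {}
    for c in called.clusters:
        by_key.setdefault((c.chrom, c.strand), []).append(c)
    max_diff = 0
    for clu in truth.clusters:
        want = truth.counts.loc[clu.cluster_id].to_numpy()
        cands = [
            c
            for c in by_key.get((clu.chrom, clu.strand), [])
            if abs(c.summit - clu.summit) <= 2 * design.jitter
        ]
        if len(cands) != 1:
            max_diff = max(max_diff, int(want.sum()))
            continue
        got = called.counts.loc[cands[0].cluster_id].to_numpy()
        max_diff = max(max_diff, int(np.abs(got - want).max()))
    if len(called.clusters) != len(truth.clusters):
        max_diff = max(max_diff, 1)
    return max_diff, len(truth.clusters)


# ---------------------------------------------------------------------------
# estimator recovery
# ---------------------------------------------------------------------------

def two_pa_gene(
    sizes: tuple[int, int] = (200, 1000), gene_id: str = "g1", chrom: str = "chrT"
) -> GeneModel:
    """A minimal + strand gene with two 3'UTR pAs at the given UTR sizes."""
    stop = 500
    pas = [(stop + s - 1, PA_3UTR) for s in sizes]
    end = stop + max(sizes) + 100
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand="+",
        tss=0,
        stop_codon=stop,
        exons=[(0, end)],
        introns=[],
        threeprime_exon=(0, end),
        pa_positions=pas,
    )


def matrix_for_gene(
    gene: GeneModel, counts: np.ndarray, samples: Sequence[str] = ("s1",)
) -> PaCountMatrix:
    """Wrap per-pA counts (n_pa x n_samples) into a one-gene matrix."""
    counts = np.atleast_2d(np.asarray(counts, int))
    if counts.shape[0] != len(gene.pa_positions):
        counts = counts.T
    clusters = []
    for (pos, cls), row in zip(gene.pa_positions, counts):
        clusters.append(
            PaCluster(
                chrom=gene.chrom,
                strand=gene.strand,
                summit=pos,
                span=(pos, pos + 1),
                counts=row,
                feature_class=cls,
                gene_id=gene.gene_id,
                utr3_size=gene.utr3_size(pos) if cls == PA_3UTR else None,
            )
        )
    df = pd.DataFrame(counts, index=[c.cluster_id for c in clusters], columns=list(samples))
    return PaCountMatrix(clusters, list(samples), df, df.sum(axis=0))


def weighted_size_recovery(
    seed: int = 1,
    sizes: tuple[int, int] = (200, 1000),
    fractions: tuple[float, float] = (0.75, 0.25),
    n_reads: int = 1000,
) -> float:
    """Weighted 3'UTR size from multinomial reads at the given usage."""
    rng = np.random.default_rng(seed)
    gene = two_pa_gene(sizes)
    counts = rng.multinomial(n_reads, fractions)
    matrix = matrix_for_gene(gene, counts[:, None])
    size = apa_metrics.weighted_utr_size(gene, matrix, "s1")
    assert size is not None
    return float(size)


# ---------------------------------------------------------------------------
# Fisher / rank-test oracles
# ---------------------------------------------------------------------------

def _hypergeom_tail_bruteforce(fw: int, nf: int, bw: int, nb: int) -> tuple[float, str]:
    """One-sided Fisher p by direct tail summation of exact table probs."""
    n, k_tot = nf + nb, fw + bw
    c = math.comb

    def pmf(x: int) -> float:
        if x < max(0, k_tot - nb) or x > min(k_tot, nf):
            return 0.0
        return c(k_tot, x) * c(n - k_tot, nf - x) / c(n, nf)

    pf, pb = fw / nf, bw / nb
    if pf == pb:
        return 1.0, "fg"
    if pf > pb:
        return sum(pmf(x) for x in range(fw, min(k_tot, nf) + 1)), "fg"
    return sum(pmf(x) for x in range(max(0, k_tot - nb), fw + 1)), "bg"


def fisher_oracle_max_dp(max_margin: int = 30) -> float:
    """Max |p_impl - p_bruteforce| over all 2x2 tables with margins <= max."""
    worst = 0.0
    for nf in range(1, max_margin + 1):
        for nb in range(1, max_margin + 1 - nf):
            for fw in range(nf + 1):
                for bw in range(nb + 1):
                    p_impl, d_impl = seq_enrichment.enrichment_p(fw, nf, bw, nb)
                    p_ref, d_ref = _hypergeom_tail_bruteforce(fw, nf, bw, nb)
                    assert d_impl == d_ref
                    worst = max(worst, abs(p_impl - p_ref))
    return worst


def _ks_stat(a: np.ndarray, b: np.ndarray) -> float:
    allv = np.sort(np.concatenate([a, b]))
    ca = np.searchsorted(np.sort(a), allv, side="right") / len(a)
    cb = np.searchsorted(np.sort(b), allv, side="right") / len(b)
    return float(np.max(np.abs(ca - cb)))


def rank_test_oracle_max_dp(seed: int = 1, n_trials: int = 5, n: int = 4) -> float:
    """Max |p_impl - p_enumeration| for K-S and rank-sum, n<=8 per group.

    The oracle enumerates every assignment of the pooled values to the
    two groups: the K-S p is the tail fraction with D* >= D, the
    rank-sum p the doubled smaller U tail (capped at 1).
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trials):
        x = rng.normal(size=n)
        y = rng.normal(0.8, size=n)
        pool = np.concatenate([x, y])
        pool_sorted = np.sort(pool)
        d_obs = _ks_stat(x, y)
        u_obs = sum(np.searchsorted(pool_sorted, v) + 1 for v in x) - n * (n + 1) / 2
        ds, us = [], []
        for comb in itertools.combinations(range(2 * n), n):
            rest = [i for i in range(2 * n) if i not in comb]
            a, b = pool[list(comb)], pool[rest]
            ds.append(_ks_stat(a, b))
            us.append(sum(np.searchsorted(pool_sorted, v) + 1 for v in a) - n * (n + 1) / 2)
        ds_arr, us_arr = np.array(ds), np.array(us)
        p_ks_ref = float(np.mean(ds_arr >= d_obs - 1e-12))
        p_w_ref = min(1.0, 2 * min(float(np.mean(us_arr <= u_obs)), float(np.mean(us_arr >= u_obs))))
        _, p_ks = te_utr.two_sample_compare(x, y, "ks", method="exact")
        _, p_w = te_utr.two_sample_compare(x, y, "wilcoxon", method="exact")
        worst = max(worst, abs(p_ks - p_ks_ref), abs(p_w - p_w_ref))
    return worst


# ---------------------------------------------------------------------------
# coverage studies
# ---------------------------------------------------------------------------

def rnaseq_ratio_sweep(
    seed: int = 1,
    long_fractions: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9),
    n_genes: int = 60,
    reads_per_gene: int = 3000,
) -> list[float]:
    """Median aUTR:cUTR log2 ratio at each simulated long-isoform fraction."""
    design = SimDesign(n_genes=n_genes, seed=seed, pa_weights=(0.0, 0.6, 0.3, 0.1))
    genes, _ = make_annotation(design)
    eligible = [g for g in genes if g.autr_interval() is not None]
    out = []
    for i, lf in enumerate(long_fractions):
        d = SimDesign(n_genes=n_genes, seed=seed + 17 * (i + 1))
        reads, _ = simulate_rnaseq_reads(
            eligible, d, {g.gene_id: lf for g in eligible}, reads_per_gene
        )
        track = coverage_coupling.dedupe_filter(reads, sample_id=f"lf{lf}")
        ratios = [coverage_coupling.autr_cutr_ratio(track, g) for g in eligible]
        out.append(float(np.median([r for r in ratios if r is not None])))
    return out


def chip_tss_recovery(
    seed: int = 1,
    n_genes: int = 24,
    multiplier: float = 4.0,
    background_per_nt: float = 0.15,
) -> float:
    """Mean TSS-flank bin score under a planted IP enrichment.

    Genes are laid out sparsely so enriched windows are a small genome
    fraction and the RPM-normalised score approaches log2(multiplier).
    """
    design = SimDesign(n_genes=n_genes, seed=seed, gene_gap=(150_000, 155_000))
    genes, genome = make_annotation(design)
    ip, inp = simulate_chipseq_reads(
        genes, genome, design, tss_multiplier=multiplier,
        background_per_nt=background_per_nt,
    )
    tip = coverage_coupling.dedupe_filter(ip, sample_id="ip")
    tin = coverage_coupling.dedupe_filter(inp, sample_id="input")
    _, agg = coverage_coupling.chip_profile(tip, tin, genes)
    labels = [f"up{-i}" for i in range(1, 1000 // 50 + 1)]
    return float(agg.loc[labels, "score"].mean())
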