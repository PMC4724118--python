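"""Synthetic data with the statistical structure the APA analysis assumes.

The generator emulates what a 3'-end sequencing (3'READS) study of a
developmental time course produces, so every downstream stage of the
pipeline is testable without any download:

* gene annotations with 1-4 polyA sites per gene (single-UTR genes,
  3'UTR-APA genes, optional intronic pAs and antisense uaRNA pAs),
* per-sample pA read counts drawn multinomially from programmable
  isoform-usage fractions (including proximal/distal usage shifts),
* raw 3'READS alignments whose poly(A)-derived 5' T-stretch appears as a
  soft-clip, plus non-PASS decoy reads carrying 0-1 Ts,
* RNA-seq and ChIP-seq coverage reads with known density structure,
* genome sequence with planted k-mers and transposable-element intervals.

Every operation takes its randomness from one seeded generator, and each
emitted read is recorded in a truth table, so tests can compare pipeline
output against ground truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import (
    PA_3UTR,
    PA_INTRON,
    PA_UARNA,
    GeneModel,
    PaCluster,
    PaCountMatrix,
    revcomp,
)

DNA = np.array(list("ACGT"))


@dataclass
class SimDesign:
    """Knobs of the simulation; defaults give a small, realistic design.

    ``te_fraction`` is the target fraction of 3'UTR-region nucleotides
    covered by TE intervals; ``motif`` is an optional
    ``(kmer, region_label, rate)`` planting spec with the k-mer in RNA
    alphabet and region_label one of cUTR/aUTR/sUTR or a pA-flank label.
    """

    n_genes: int = 50
    n_samples: int = 2
    sample_ids: Optional[list[str]] = None
    library_size: int = 100_000
    seed: int = 0
    pa_weights: tuple[float, ...] = (0.25, 0.45, 0.2, 0.1)  # P(1..4 pAs)
    jitter: int = 5  # cleavage-position jitter, +/- nt, uniform
    read_length: int = 50
    decoy_fraction: float = 0.0  # share of reads that are non-PASS decoys
    uarna_rate: float = 0.25
    uarna_expression: float = 0.05  # read share of a gene's uaRNA pA
    intron_pa_rate: float = 0.3
    intron_pa_expression: float = 0.1
    te_fraction: float = 0.12
    motif: Optional[tuple[str, str, float]] = None
    genes_per_chrom: int = 50
    #: intergenic gap range (nt); keep > 2 kb so uaRNA pAs stay clear of
    #: neighbours.  ChIP-seq simulations use much larger gaps so that
    #: enriched windows are a sparse genome fraction, as in real data.
    gene_gap: tuple[int, int] = (2500, 4000)

    def __post_init__(self) -> None:
        for name in ("decoy_fraction", "uarna_rate", "te_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i + 1}" for i in range(self.n_samples)]
        if len(self.sample_ids) != self.n_samples:
            raise ValueError("sample_ids length != n_samples")


# ---------------------------------------------------------------------------
# annotation + genome
# ---------------------------------------------------------------------------

def make_annotation(design: SimDesign) -> tuple[list[GeneModel], dict[str, str]]:
    """Generate non-overlapping gene models and a covering genome sequence.

    Genes are laid out sequentially (one synthetic chromosome per
    ``genes_per_chrom`` genes) with >2 kb gaps, so pA-to-gene assignment
    is unambiguous and uaRNA pAs fall in intergenic space.  Deterministic
    for a given design (the design carries the seed).
    """
    rng = np.random.default_rng(design.seed)
    genes: list[GeneModel] = []
    genome: dict[str, str] = {}
    if design.n_genes == 0:
        return genes, genome

    chrom_idx, cursor = 0, 0
    chrom_lengths: dict[str, int] = {}
    for gi in range(design.n_genes):
        if gi % design.genes_per_chrom == 0 and gi > 0:
            chrom_lengths[f"chrS{chrom_idx + 1}"] = cursor + 3000
            chrom_idx += 1
            cursor = 0
        chrom = f"chrS{chrom_idx + 1}"
        cursor += int(rng.integers(*design.gene_gap))
        gene, length = _build_gene(f"g{gi + 1:04d}", chrom, cursor, rng, design)
        genes.append(gene)
        cursor += length
    chrom_lengths[f"chrS{chrom_idx + 1}"] = cursor + 3000

    for chrom, length in chrom_lengths.items():
        genome[chrom] = "".join(rng.choice(DNA, size=length))
    return genes, genome


def _build_gene(
    gene_id: str, chrom: str, g0: int, rng: np.random.Generator, design: SimDesign
) -> tuple[GeneModel, int]:
    """Lay out one gene on a local 5'->3' axis, then map to the genome."""
    strand = "+" if rng.random() < 0.5 else "-"
    n_pa = int(rng.choice(np.arange(1, len(design.pa_weights) + 1), p=design.pa_weights))
    n_introns = int(rng.integers(1, 5))

    # local coordinates, 0 = TSS, increasing 5'->3'
    exons_l: list[tuple[int, int]] = []
    introns_l: list[tuple[int, int]] = []
    pos = 0
    for i in range(n_introns):
        elen = int(rng.integers(150, 300))
        exons_l.append((pos, pos + elen))
        pos += elen
        ilen = int(rng.integers(300, 800))
        introns_l.append((pos, pos + ilen))
        pos += ilen
    last_exon_start = pos
    stop_l = pos + int(rng.integers(150, 250))  # first 3'UTR base

    utr_sizes = [int(rng.integers(80, 200))]
    for _ in range(n_pa - 1):
        utr_sizes.append(utr_sizes[-1] + int(rng.integers(60, 250)))
    pa_l = [(stop_l + u - 1, PA_3UTR) for u in utr_sizes]
    length = stop_l + utr_sizes[-1] + 50
    exons_l.append((last_exon_start, length))

    if n_introns > 0 and rng.random() < design.intron_pa_rate:
        s, e = introns_l[int(rng.integers(0, n_introns))]
        pa_l.append((int(rng.integers(s + 20, e - 20)), PA_INTRON))

    if strand == "+":
        loc = lambda p: g0 + p
        ivl = lambda s, e: (g0 + s, g0 + e)
    else:
        loc = lambda p: g0 + (length - 1) - p
        ivl = lambda s, e: (g0 + length - e, g0 + length - s)

    gene = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        tss=loc(0),
        stop_codon=loc(stop_l),
        exons=[ivl(*x) for x in exons_l],
        introns=[ivl(*x) for x in introns_l],
        threeprime_exon=ivl(*exons_l[-1]),
        pa_positions=[(loc(p), c) for p, c in pa_l],
    )
    if rng.random() < design.uarna_rate:
        d = int(rng.integers(300, 1500))
        gene.uarna_pa = gene.tss - d if strand == "+" else gene.tss + d
    return gene, length


# ---------------------------------------------------------------------------
# pA counts
# ---------------------------------------------------------------------------

def _gene_pa_records(gene: GeneModel) -> list[tuple[int, str, str]]:
    """(position, feature_class, strand) for every pA of the gene."""
    anti = "-" if gene.strand == "+" else "+"
    recs = [(p, c, gene.strand) for p, c in gene.pa_positions]
    if gene.uarna_pa is not None:
        recs.append((gene.uarna_pa, PA_UARNA, anti))
    return recs


def default_usage_fractions(
    genes: Sequence[GeneModel], design: SimDesign, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-gene (n_samples, n_pa) usage fractions, constant across samples.

    3'UTR pA usage is Dirichlet(2); intronic pAs and uaRNA pAs take their
    design-level expression shares off the top.
    """
    out: dict[str, np.ndarray] = {}
    for gene in genes:
        recs = _gene_pa_records(gene)
        shares = np.zeros(len(recs))
        utr_ix = [i for i, (_, c, _) in enumerate(recs) if c == PA_3UTR]
        rest = 1.0
        for i, (_, c, _) in enumerate(recs):
            if c == PA_INTRON:
                shares[i] = design.intron_pa_expression
            elif c == PA_UARNA:
                shares[i] = design.uarna_expression
        rest -= shares.sum()
        shares[utr_ix] = rest * rng.dirichlet(np.full(len(utr_ix), 2.0))
        out[gene.gene_id] = np.tile(shares, (design.n_samples, 1))
    return out


def simulate_pa_counts(
    genes: Sequence[GeneModel],
    design: SimDesign,
    fractions: Optional[dict[str, np.ndarray]] = None,
    expression: Optional[np.ndarray] = None,
) -> PaCountMatrix:
    """Draw the truth pA x sample count matrix.

    Per sample, the library is allocated to genes multinomially (weights
    ``expression``, default Dirichlet-random), then each gene's reads are
    split multinomially over its pAs with the design fractions, so column
    sums equal the library size exactly.
    """
    rng = np.random.default_rng(design.seed + 1)
    if fractions is None:
        fractions = default_usage_fractions(genes, design, rng)
    for gid, f in fractions.items():
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError(f"usage fractions for {gid} do not sum to 1")
    if expression is None:
        expression = rng.dirichlet(np.full(len(genes), 5.0)) if genes else np.array([])

    clusters: list[PaCluster] = []
    rows: list[np.ndarray] = []
    n_s = design.n_samples
    gene_reads = np.zeros((len(genes), n_s), dtype=int)
    for s in range(n_s):
        if len(genes) and design.library_size > 0:
            gene_reads[:, s] = rng.multinomial(design.library_size, expression)

    for gi, gene in enumerate(genes):
        recs = _gene_pa_records(gene)
        frac = fractions[gene.gene_id]
        if frac.shape != (n_s, len(recs)):
            raise ValueError(
                f"fractions for {gene.gene_id} have shape {frac.shape}, "
                f"expected {(n_s, len(recs))}"
            )
        counts = np.zeros((len(recs), n_s), dtype=int)
        for s in range(n_s):
            if gene_reads[gi, s] > 0:
                counts[:, s] = rng.multinomial(gene_reads[gi, s], frac[s])
        for i, (pos, cls, strand) in enumerate(recs):
            clu = PaCluster(
                chrom=gene.chrom,
                strand=strand,
                summit=pos,
                span=(pos, pos + 1),
                counts=counts[i],
                feature_class=cls,
                gene_id=gene.gene_id,
                utr3_size=gene.utr3_size(pos) if cls == PA_3UTR else None,
            )
            clusters.append(clu)
            rows.append(counts[i])

    samples = list(design.sample_ids)
    table = pd.DataFrame(
        np.array(rows, dtype=int) if rows else np.zeros((0, n_s), dtype=int),
        index=[c.cluster_id for c in clusters],
        columns=samples,
    )
    totals = table.sum(axis=0)
    return PaCountMatrix(clusters=clusters, samples=samples, counts=table, totals=totals)


def simulate_isoform_pair_counts(
    n_genes: int,
    reads_per_gene: float,
    n_shift: int = 0,
    red: float = 0.0,
    base_odds: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-sample proximal/distal counts for SAAP/GAAP calibration studies.

    Null genes share one distal:proximal odds in both samples (pooled
    proportion); the first ``n_shift`` genes get their sample-B odds
    multiplied by ``2**red`` (negative ``red`` = 3'UTR shortening).  Reads
    per gene per sample are Poisson(``reads_per_gene``).
    """
    rng = np.random.default_rng(seed)
    odds_a = base_odds * 2.0 ** rng.normal(0.0, 0.5, n_genes)
    odds_b = odds_a.copy()
    odds_b[:n_shift] *= 2.0**red
    p_dis_a = odds_a / (1 + odds_a)
    p_dis_b = odds_b / (1 + odds_b)
    n_a = rng.poisson(reads_per_gene, n_genes)
    n_b = rng.poisson(reads_per_gene, n_genes)
    dis_a = rng.binomial(n_a, p_dis_a)
    dis_b = rng.binomial(n_b, p_dis_b)
    return pd.DataFrame(
        {
            "a_prx": n_a - dis_a,
            "a_dis": dis_a,
            "b_prx": n_b - dis_b,
            "b_dis": dis_b,
            "shifted": np.arange(n_genes) < n_shift,
        },
        index=[f"g{i + 1:05d}" for i in range(n_genes)],
    )


# ---------------------------------------------------------------------------
# 3'READS read simulation
# ---------------------------------------------------------------------------

@dataclass
class SamRead:
    """A minimal aligned-read record, writable as a SAM line."""

    qname: str
    flag: int
    chrom: str
    pos: int  # 0-based leftmost aligned base
    mapq: int
    cigar: str
    seq: str

    def to_sam_line(self) -> str:
        return "\t".join(
            [
                self.qname,
                str(self.flag),
                self.chrom,
                str(self.pos + 1),  # SAM is 1-based
                str(self.mapq),
                self.cigar,
                "*",
                "0",
                "0",
                self.seq,
                "*",
            ]
        )


def write_sam(path: str, reads: Sequence[SamRead], genome: dict[str, str], seed: Optional[int] = None) -> None:
    """Write reads as a SAM file (header + soft clips via CIGAR S ops)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, seq in genome.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{len(seq)}\n")
        if seed is not None:
            fh.write(f"@CO\tapatrace simulation seed={seed}\n")
        for r in reads:
            fh.write(r.to_sam_line() + "\n")


def _make_3reads_read(
    qname: str,
    chrom: str,
    transcript_strand: str,
    cleavage: int,
    t_run: int,
    read_len: int,
    genome: dict[str, str],
) -> SamRead:
    """One 3'READS alignment ending at ``cleavage`` (last transcribed base).

    The sequencer reads the poly(A)-derived T-stretch first, so the read
    is the reverse complement of the transcript 3' end and aligns on the
    strand opposite the transcript; the read-5' T-clip appears as a
    trailing CIGAR S (stored reverse-complemented, an A-run) for flag-16
    alignments and a leading S for forward alignments.
    """
    seq = genome[chrom]
    if transcript_strand == "+":
        start, end = cleavage - read_len + 1, cleavage + 1
        aligned = seq[start:end]
        cigar = f"{read_len}M{t_run}S" if t_run else f"{read_len}M"
        return SamRead(qname, 16, chrom, start, 30, cigar, aligned + "A" * t_run)
    start, end = cleavage, cleavage + read_len
    aligned = seq[start:end]
    cigar = f"{t_run}S{read_len}M" if t_run else f"{read_len}M"
    return SamRead(qname, 0, chrom, start, 30, cigar, "T" * t_run + aligned)


def simulate_3reads_reads(
    genes: Sequence[GeneModel],
    matrix: PaCountMatrix,
    genome: dict[str, str],
    design: SimDesign,
) -> tuple[dict[str, list[SamRead]], pd.DataFrame]:
    """Emit per-sample 3'READS alignments realising the truth count matrix.

    Each counted read gets a cleavage jitter of +/- ``design.jitter`` nt
    and a T-run of 2-8 nt (a PASS read); decoys (extra reads carrying 0-1
    Ts, at rate ``decoy_fraction`` of the final read stream) are appended
    and marked in the truth table.
    """
    rng = np.random.default_rng(design.seed + 2)
    reads: dict[str, list[SamRead]] = {s: [] for s in matrix.samples}
    truth_rows = []
    serial = 0
    f = design.decoy_fraction
    decoy_per_true = f / (1 - f) if f < 1 else 0.0

    for clu in matrix.clusters:
        row = matrix.counts.loc[clu.cluster_id]
        for si, sample in enumerate(matrix.samples):
            n = int(row.iloc[si])
            if n == 0:
                continue
            jit = rng.integers(-design.jitter, design.jitter + 1, size=n)
            t_runs = rng.integers(2, 9, size=n)
            n_decoy = rng.binomial(n, min(decoy_per_true, 1.0)) if f > 0 else 0
            for j, t in zip(jit, t_runs):
                serial += 1
                qname = f"r{serial:07d}"
                reads[sample].append(
                    _make_3reads_read(
                        qname, clu.chrom, clu.strand, clu.summit + int(j), int(t),
                        design.read_length, genome,
                    )
                )
                truth_rows.append((qname, sample, clu.cluster_id, clu.gene_id, clu.summit, False))
            for _ in range(n_decoy):
                serial += 1
                qname = f"d{serial:07d}"
                j = int(rng.integers(-design.jitter, design.jitter + 1))
                t = int(rng.integers(0, 2))
                reads[sample].append(
                    _make_3reads_read(
                        qname, clu.chrom, clu.strand, clu.summit + j, t,
                        design.read_length, genome,
                    )
                )
                truth_rows.append((qname, sample, clu.cluster_id, clu.gene_id, clu.summit, True))

    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "sample", "cluster_id", "gene_id", "true_pa", "is_decoy"],
    )
    return reads, truth


# ---------------------------------------------------------------------------
# coverage reads (RNA-seq / ChIP-seq)
# ---------------------------------------------------------------------------

def simulate_rnaseq_reads(
    genes: Sequence[GeneModel],
    design: SimDesign,
    long_fraction: dict[str, float],
    reads_per_gene: int = 2000,
) -> tuple[list[SamRead], pd.DataFrame]:
    """Strand-specific RNA-seq reads with APA-determined 3'UTR coverage.

    Read density over CDS and cUTR is uniform; density over the aUTR is
    that times the gene's long-isoform fraction (all isoforms cover the
    cUTR, only long isoforms cover the aUTR).  Returns reads plus a truth
    table of the per-gene fractions used.
    """
    rng = np.random.default_rng(design.seed + 3)
    reads: list[SamRead] = []
    rows = []
    serial = 0
    for gene in genes:
        lf = long_fraction.get(gene.gene_id, 0.0)
        regions = [(s, e, 1.0, "cds") for s, e in gene.cds_intervals()]
        cutr = gene.cutr_interval()
        if cutr:
            regions.append((*cutr, 1.0, "cUTR"))
        autr = gene.autr_interval()
        if autr:
            regions.append((*autr, lf, "aUTR"))
        weights = np.array([(e - s) * w for s, e, w, _ in regions], dtype=float)
        if weights.sum() == 0:
            continue
        picks = rng.multinomial(reads_per_gene, weights / weights.sum())
        flag = 0 if gene.strand == "+" else 16
        for (s, e, _, _), n in zip(regions, picks):
            if n == 0:
                continue
            anchors = rng.integers(s, e, size=n)
            lens = rng.integers(40, 61, size=n)
            for a, ln in zip(anchors, lens):
                serial += 1
                if gene.strand == "+":
                    pos = int(a)
                else:
                    pos = max(0, int(a) - int(ln) + 1)
                reads.append(
                    SamRead(f"q{serial:07d}", flag, gene.chrom, pos, 30, f"{int(ln)}M", "N" * int(ln))
                )
        rows.append((gene.gene_id, lf, reads_per_gene))
    truth = pd.DataFrame(rows, columns=["gene_id", "long_fraction", "reads"])
    return reads, truth


def simulate_chipseq_reads(
    genes: Sequence[GeneModel],
    genome: dict[str, str],
    design: SimDesign,
    tss_multiplier: float = 1.0,
    tss_flank: int = 1000,
    background_per_nt: float = 0.02,
    ip_total: Optional[int] = None,
) -> tuple[list[SamRead], list[SamRead]]:
    """Paired IP/input ChIP-seq reads with a planted TSS enrichment.

    Input anchors are uniform over each chromosome at ``background_per_nt``
    reads/nt; IP reads have the same background plus
    ``(tss_multiplier - 1)`` extra density within +/- ``tss_flank`` of
    every TSS, so the per-bin IP:input density ratio at the TSS equals
    the multiplier in expectation.
    """
    rng = np.random.default_rng(design.seed + 4)
    ip: list[SamRead] = []
    inp: list[SamRead] = []
    serial = [0]

    def emit(out: list[SamRead], chrom: str, anchors: np.ndarray) -> None:
        # lengths vary so deep coverage is not flattened by the
        # duplicate-collapse step downstream
        lens = rng.integers(40, 61, size=len(anchors))
        flags = rng.integers(0, 2, size=len(anchors)) * 16
        for a, ln, flag in zip(anchors, lens, flags):
            serial[0] += 1
            pos = int(a) if flag == 0 else max(0, int(a) - int(ln) + 1)
            out.append(
                SamRead(f"c{serial[0]:08d}", int(flag), chrom, pos, 30, f"{int(ln)}M", "N" * int(ln))
            )

    for chrom, seq in genome.items():
        n_bg = rng.poisson(background_per_nt * len(seq))
        emit(inp, chrom, rng.integers(0, len(seq) - 60, size=n_bg))
        n_bg_ip = rng.poisson(background_per_nt * len(seq))
        emit(ip, chrom, rng.integers(0, len(seq) - 60, size=n_bg_ip))
    if tss_multiplier != 1.0:
        for gene in genes:
            lo = max(0, gene.tss - tss_flank)
            hi = min(len(genome[gene.chrom]) - 60, gene.tss + tss_flank)
            extra = rng.poisson(background_per_nt * (tss_multiplier - 1.0) * (hi - lo))
            emit(ip, gene.chrom, rng.integers(lo, hi, size=extra))
    return ip, inp


# ---------------------------------------------------------------------------
# sequences + intervals (motif planting, TE intervals)
# ---------------------------------------------------------------------------

def _region_intervals(genes: Sequence[GeneModel], label: str) -> list[tuple[str, str, int, int, str]]:
    """(gene_id, chrom, start, end, strand) for each region of ``label``."""
    out = []
    for g in genes:
        if label == "cUTR" and not g.is_sutr:
            iv = g.cutr_interval()
        elif label == "aUTR":
            iv = g.autr_interval()
        elif label == "sUTR" and g.is_sutr:
            iv = g.cutr_interval()
        else:
            iv = None
        if iv is not None:
            out.append((g.gene_id, g.chrom, iv[0], iv[1], g.strand))
    return out


def make_sequences_and_intervals(
    genes: Sequence[GeneModel],
    genome: dict[str, str],
    design: SimDesign,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Plant motifs into UTR regions and scatter TE intervals over them.

    Returns the (possibly modified) genome, a TE interval table
    (chrom/start/end/te_class/region/gene_id) whose per-region coverage
    approximates ``design.te_fraction``, and a motif truth table.
    """
    rng = np.random.default_rng(design.seed + 5)
    editable = {c: list(s) for c, s in genome.items()}
    motif_rows = []
    if design.motif is not None:
        kmer, label, rate = design.motif
        dna = kmer.replace("U", "T").replace("u", "t")
        for gene_id, chrom, s, e, strand in _region_intervals(genes, label):
            if e - s < len(dna) or rng.random() >= rate:
                continue
            off = int(rng.integers(s, e - len(dna) + 1))
            planted = dna if strand == "+" else revcomp(dna)
            editable[chrom][off : off + len(dna)] = list(planted)
            motif_rows.append((gene_id, label, chrom, off, kmer))
    genome_out = {c: "".join(s) for c, s in editable.items()}

    te_rows = []
    te_classes = np.array(["LINE", "SINE", "LTR", "DNA"])
    for label in ("cUTR", "aUTR", "sUTR"):
        for gene_id, chrom, s, e, strand in _region_intervals(genes, label):
            target = int(round(design.te_fraction * (e - s)))
            if target <= 0:
                continue
            off = int(rng.integers(s, max(s + 1, e - target + 1)))
            te_rows.append(
                (chrom, off, min(off + target, e), str(rng.choice(te_classes)), label, gene_id)
            )
    tes = pd.DataFrame(
        te_rows, columns=["chrom", "start", "end", "te_class", "region", "gene_id"]
    )
    motifs = pd.DataFrame(
        motif_rows, columns=["gene_id", "region", "chrom", "offset", "kmer"]
    )
    return genome_out, tes, motifs


# ---------------------------------------------------------------------------
# text-format writers
# ---------------------------------------------------------------------------

def write_fasta(path: str, genome: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed12(path: str, genes: Sequence[GeneModel]) -> None:
    """Gene models as BED12 (0-based half-open, blocks = exons)."""
    with open(path, "w") as fh:
        for g in genes:
            exons = sorted(g.exons)
            start, end = exons[0][0], exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in exons)
            offs = ",".join(str(s - start) for s, _ in exons)
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            g.chrom, start, end, g.gene_id, 0, g.strand,
                            start, end, "0,0,0", len(exons), sizes, offs,
                        ],
                    )
                )
                + "\n"
            )


_CLASS_CODE = {PA_3UTR: 1, PA_INTRON: 2, "upstream_exon": 3, PA_UARNA: 4}


def write_pa_bed(path: str, genes: Sequence[GeneModel]) -> None:
    """Truth pA positions as BED6 (name=gene:index, score=class code)."""
    with open(path, "w") as fh:
        for g in genes:
            for i, (pos, cls, strand) in enumerate(_gene_pa_records(g)):
                fh.write(
                    f"{g.chrom}\t{pos}\t{pos + 1}\t{g.gene_id}:{i}\t"
                    f"{_CLASS_CODE.get(cls, 0)}\t{strand}\n"
                )


def write_te_bed(path: str, tes: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        for r in tes.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.te_class}\t0\t+\n")
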