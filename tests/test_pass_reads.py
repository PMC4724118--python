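"""PASS calling, 24-nt clustering, feature assignment, matrix building."""

import pytest

from apatrace.models import (
    PA_3UTR,
    PA_INTERGENIC,
    PA_INTRON,
    PA_UARNA,
    GeneModel,
)
from apatrace.pass_reads import (
    AlignedRead,
    assign_pa,
    build_matrix,
    call_polya_sites,
    cluster_pa,
    extract_pass_reads,
    read_sam,
    sam_reads_to_aligned,
)
from apatrace.synthetic_data import SimDesign, simulate_3reads_reads, write_sam


def _read(clip, strand="+", start=100, end=150):
    return AlignedRead("chr1", strand, start, end, clip)


@pytest.mark.parametrize(
    "clip,is_pass",
    [
        ("TT", True),   # the defining >=2-T criterion
        ("T", False),
        ("", False),
        ("ATT", True),  # Ts adjacent to the aligned bases count
        ("TTA", False),  # intervening non-T breaks the run
        ("tttt", True),
    ],
)
def test_pass_criterion_on_soft_clip(clip, is_pass):
    counts, dropped = extract_pass_reads([_read(clip)])
    assert (len(counts) == 1) == is_pass
    assert dropped == (0 if is_pass else 1)


def test_cleavage_position_is_strand_oriented():
    plus = _read("TT", strand="+", start=100, end=150)
    minus = _read("TT", strand="-", start=100, end=150)
    assert plus.cleavage_position == 149
    assert minus.cleavage_position == 100


@pytest.mark.parametrize(
    "positions,expected",
    [
        ({100: 10}, [(100, 10)]),
        ({100: 10, 124: 3}, [(100, 13)]),  # 24 nt apart: merged into summit
        ({100: 10, 125: 3}, [(100, 10), (125, 3)]),  # 25 nt: separate
    ],
)
def test_cluster_examples(positions, expected):
    pos_counts = {("chr1", "+", p): n for p, n in positions.items()}
    clusters = cluster_pa(pos_counts, window=24)
    got = sorted((c.summit, int(c.counts[0])) for c in clusters)
    assert got == sorted(expected)


def test_cluster_idempotence(rng):
    positions = rng.choice(5000, size=120, replace=False)
    pos_counts = {("chr1", "+", int(p)): int(n) for p, n in
                  zip(positions, rng.integers(1, 50, 120))}
    clusters = cluster_pa(pos_counts)
    summits = {("chr1", "+", c.summit): int(c.counts[0]) for c in clusters}
    again = cluster_pa(summits)
    assert sorted(c.summit for c in again) == sorted(c.summit for c in clusters)
    # retained summits are > window apart
    s = sorted(c.summit for c in clusters)
    assert all(b - a > 24 for a, b in zip(s, s[1:]))


def test_cluster_strand_symmetry(rng):
    positions = rng.choice(3000, size=60, replace=False)
    counts = rng.integers(1, 30, 60)
    fwd = {("chr1", "+", int(p)): int(n) for p, n in zip(positions, counts)}
    mirror = {("chr1", "-", 5000 - 1 - int(p)): int(n) for p, n in zip(positions, counts)}
    cf = cluster_pa(fwd)
    cm = cluster_pa(mirror)
    assert sorted(5000 - 1 - c.summit for c in cm) == sorted(c.summit for c in cf)


def test_pass_conservation(small_dataset, small_design):
    genes, genome, matrix = small_dataset
    d = SimDesign(n_genes=30, library_size=30_000, seed=11, decoy_fraction=0.4)
    reads, truth = simulate_3reads_reads(genes, matrix, genome, d)
    aligned = [r for s in reads.values() for r in sam_reads_to_aligned(s)]
    counts, dropped = extract_pass_reads(aligned)
    assert sum(counts.values()) + dropped == len(aligned)
    # exactly the decoys are rejected
    assert dropped == int(truth.is_decoy.sum())
    assert sum(counts.values()) == int((~truth.is_decoy).sum())


def _toy_gene():
    return GeneModel(
        gene_id="tg1", chrom="chr1", strand="+", tss=1000, stop_codon=2500,
        exons=[(1000, 1200), (2000, 3200)], introns=[(1200, 2000)],
        threeprime_exon=(2000, 3200),
        pa_positions=[(2799, PA_3UTR), (3099, PA_3UTR)],
    )


def test_assignment_classes_and_utr_size():
    gene = _toy_gene()
    pos_counts = {
        ("chr1", "+", 2799): 10,  # 3'UTR
        ("chr1", "+", 1500): 4,   # intron
        ("chr1", "-", 300): 3,    # antisense, 700 nt upstream of TSS -> uaRNA
        ("chr1", "+", 9000): 2,   # nothing nearby
    }
    clusters = assign_pa(cluster_pa(pos_counts), [gene])
    by_pos = {c.summit: c for c in clusters}
    assert by_pos[2799].feature_class == PA_3UTR
    assert by_pos[2799].utr3_size == 2799 - 2500 + 1
    assert by_pos[1500].feature_class == PA_INTRON
    assert by_pos[300].feature_class == PA_UARNA
    assert by_pos[300].gene_id == "tg1"
    assert by_pos[9000].feature_class == PA_INTERGENIC


def test_uarna_requires_2kb_window():
    gene = _toy_gene()
    near = assign_pa(cluster_pa({("chr1", "-", 1000 - 700): 1}), [gene])[0]
    far = assign_pa(cluster_pa({("chr1", "-", 1000 - 2100): 1}), [gene])[0]
    assert near.feature_class == PA_UARNA
    assert far.feature_class == PA_INTERGENIC


def test_build_matrix_rpm_and_zero_total():
    per_sample = {
        "a": {("chr1", "+", 100): 10},
        "b": {("chr1", "+", 100): 0},
    }
    m = build_matrix(per_sample)
    assert m.totals["a"] == 10
    with pytest.raises(ValueError):
        m.rpm()  # sample b has zero total
    m2 = build_matrix({"a": {("chr1", "+", 100): 10, ("chr1", "+", 500): 990}})
    assert m2.rpm().loc["chr1:+:100", "a"] == pytest.approx(10 / 1000 * 1e6)


def test_empty_input_empty_matrix():
    m = build_matrix({"a": {}})
    assert m.counts.shape == (0, 1)


def test_sam_round_trip_matches_direct_conversion(tmp_path, small_dataset, small_design):
    genes, genome, matrix = small_dataset
    reads, _ = simulate_3reads_reads(genes, matrix, genome, small_design)
    sample = matrix.samples[0]
    path = tmp_path / "s1.sam"
    write_sam(str(path), reads[sample], genome)
    via_sam = read_sam(str(path))
    direct = sam_reads_to_aligned(reads[sample])
    key = lambda r: (r.chrom, r.strand, r.aln_start, r.aln_end, r.leading_softclip_seq)
    assert sorted(map(key, via_sam)) == sorted(map(key, direct))


def test_pipeline_round_trip_recovers_truth_exactly(small_dataset, small_design):
    """Decoy-free simulated reads reproduce the simulated count matrix."""
    genes, genome, matrix = small_dataset
    reads, _ = simulate_3reads_reads(genes, matrix, genome, small_design)
    called = call_polya_sites(
        {s: sam_reads_to_aligned(r) for s, r in reads.items()}, genes
    )
    assert len(called.clusters) == len(matrix.clusters)
    for clu in matrix.clusters:
        match = [c for c in called.clusters
                 if c.chrom == clu.chrom and c.strand == clu.strand
                 and abs(c.summit - clu.summit) <= 2 * small_design.jitter]
        assert len(match) == 1
        got = called.counts.loc[match[0].cluster_id].to_numpy()
        assert (got == matrix.counts.loc[clu.cluster_id].to_numpy()).all()
        assert match[0].feature_class == clu.feature_class
        assert match[0].gene_id == clu.gene_id
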