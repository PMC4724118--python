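"""The generator's contracts: determinism, conservation, truth tables."""

import numpy as np
import pytest
from scipy.stats import binom

from apatrace.synthetic_data import (
    SimDesign,
    make_annotation,
    make_sequences_and_intervals,
    simulate_3reads_reads,
    simulate_pa_counts,
    write_bed12,
    write_fasta,
)
from apatrace.te_utr import TeInterval, te_fraction


def _bed12_string(genes):
    import tempfile, os

    with tempfile.NamedTemporaryFile("r", suffix=".bed", delete=False) as fh:
        path = fh.name
    write_bed12(path, genes)
    with open(path) as fh:
        s = fh.read()
    os.unlink(path)
    return s


def test_empty_design_gives_empty_everything():
    genes, genome = make_annotation(SimDesign(n_genes=0))
    assert genes == [] and genome == {}
    m = simulate_pa_counts(genes, SimDesign(n_genes=0))
    assert m.counts.shape[0] == 0


def test_annotation_is_deterministic_given_seed():
    d1 = SimDesign(n_genes=25, seed=42)
    d2 = SimDesign(n_genes=25, seed=42)
    g1, gen1 = make_annotation(d1)
    g2, gen2 = make_annotation(d2)
    assert _bed12_string(g1) == _bed12_string(g2)
    assert gen1 == gen2


def test_gene_models_satisfy_structural_invariants(small_dataset):
    genes, genome, _ = small_dataset
    for g in genes:
        # exons disjoint and ordered 5'->3' along the strand
        ordered = g.exons if g.strand == "+" else [(-e, -s) for s, e in g.exons]
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            assert e1 <= s2
        # every 3'UTR pA inside the 3'-most exon, downstream of the stop
        s3, e3 = g.threeprime_exon
        for pa in g.utr3_pas:
            assert s3 <= pa < e3
            assert g.utr3_size(pa) >= 1
        assert 1 <= len(g.utr3_pas) <= 4
        assert len(genome[g.chrom]) >= g.span[1]
        if g.is_sutr:
            assert g.autr_interval() is None


def test_zero_library_size_gives_all_zero_matrix():
    d = SimDesign(n_genes=5, library_size=0, seed=1)
    genes, _ = make_annotation(d)
    m = simulate_pa_counts(genes, d)
    assert (m.counts.to_numpy() == 0).all()


def test_counts_columns_sum_to_library_size(small_dataset, small_design):
    _, _, matrix = small_dataset
    assert (matrix.counts.sum(axis=0) == small_design.library_size).all()


def test_degenerate_usage_puts_all_reads_on_one_pa():
    d = SimDesign(n_genes=1, library_size=1000, seed=2, pa_weights=(0.0, 1.0),
                  uarna_rate=0.0, intron_pa_rate=0.0)
    genes, _ = make_annotation(d)
    frac = {genes[0].gene_id: np.tile([1.0, 0.0], (2, 1))}
    m = simulate_pa_counts(genes, d, fractions=frac)
    col = m.counts.to_numpy()
    assert col[0].sum() == 2000 and col[1].sum() == 0


def test_observed_usage_within_exact_binomial_interval():
    """0.8/0.2 usage at 10,000 reads lands in the binomial 99% interval."""
    d = SimDesign(n_genes=1, library_size=10_000, seed=5, pa_weights=(0.0, 1.0),
                  uarna_rate=0.0, intron_pa_rate=0.0)
    genes, _ = make_annotation(d)
    frac = {genes[0].gene_id: np.tile([0.8, 0.2], (2, 1))}
    m = simulate_pa_counts(genes, d, fractions=frac)
    lo, hi = binom.ppf([0.005, 0.995], 10_000, 0.8)
    for s in m.samples:
        assert lo <= m.counts[s].iloc[0] <= hi


def test_bad_usage_fractions_raise():
    d = SimDesign(n_genes=1, seed=4, uarna_rate=0.0, intron_pa_rate=0.0)
    genes, _ = make_annotation(d)
    n_pa = len(genes[0].pa_positions)
    bad = {genes[0].gene_id: np.full((2, n_pa), 0.9)}
    with pytest.raises(ValueError):
        simulate_pa_counts(genes, d, fractions=bad)


def test_truth_table_conserves_counts(small_dataset, small_design):
    genes, genome, matrix = small_dataset
    reads, truth = simulate_3reads_reads(genes, matrix, genome, small_design)
    per_cluster = truth[~truth.is_decoy].groupby(["cluster_id", "sample"]).size()
    for (cid, sample), n in per_cluster.items():
        assert n == matrix.counts.loc[cid, sample]
    assert truth[~truth.is_decoy].shape[0] == matrix.counts.to_numpy().sum()


def test_decoy_reads_are_extra_and_marked(small_dataset):
    genes, genome, matrix = small_dataset
    d = SimDesign(n_genes=30, library_size=30_000, seed=11, decoy_fraction=0.3)
    reads, truth = simulate_3reads_reads(genes, matrix, genome, d)
    n_decoy = int(truth.is_decoy.sum())
    assert truth[~truth.is_decoy].shape[0] == matrix.counts.to_numpy().sum()
    share = n_decoy / len(truth)
    assert 0.2 < share < 0.4  # ~decoy_fraction of the stream


def test_motif_and_te_planting_trivial_and_target_rates(small_dataset):
    genes, genome, _ = small_dataset
    # rate 0 / fraction 0: nothing planted
    d0 = SimDesign(n_genes=30, seed=11, te_fraction=0.0, motif=("UGUA", "cUTR", 0.0))
    _, tes0, motifs0 = make_sequences_and_intervals(genes, genome, d0)
    assert len(tes0) == 0 and len(motifs0) == 0
    # target 0.15 coverage on aUTRs measured back by interval arithmetic
    d1 = SimDesign(n_genes=30, seed=11, te_fraction=0.15)
    _, tes1, _ = make_sequences_and_intervals(genes, genome, d1)
    autr = [(g.chrom, *g.autr_interval()) for g in genes if g.autr_interval()]
    te_list = [TeInterval(r.chrom, r.start, r.end, r.te_class)
               for r in tes1[tes1.region == "aUTR"].itertuples()]
    assert abs(te_fraction(autr, te_list) - 0.15) <= 0.03


def test_planted_motif_present_at_recorded_offsets(small_dataset):
    genes, genome, _ = small_dataset
    d = SimDesign(n_genes=30, seed=11, motif=("UGUAAA", "aUTR", 1.0))
    genome2, _, motifs = make_sequences_and_intervals(genes, genome, d)
    assert len(motifs) > 0
    strands = {g.gene_id: g.strand for g in genes}
    for r in motifs.itertuples():
        got = genome2[r.chrom][r.offset : r.offset + 6]
        want = "TGTAAA" if strands[r.gene_id] == "+" else "TTTACA"
        assert got == want


def test_fasta_writer_round_trips(tmp_path):
    genome = {"chrA": "ACGTACGTAC" * 13}
    path = tmp_path / "g.fa"
    write_fasta(str(path), genome, width=40)
    text = path.read_text().split("\n")
    assert text[0] == ">chrA"
    assert "".join(text[1:]).strip() == genome["chrA"]
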