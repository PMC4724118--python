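"""Region extraction, k-mer Fisher tests, signed scores, set enrichment."""

import numpy as np
import pandas as pd
import pytest

from apatrace import seq_enrichment as se
from apatrace.benchmarks import _hypergeom_tail_bruteforce
from apatrace.models import PA_3UTR, GeneModel, revcomp
from apatrace.synthetic_data import SimDesign, make_sequences_and_intervals


def _plus_gene(stop=100, pas=(149,), gene_id="gp"):
    end = max(pas) + 50
    return GeneModel(gene_id, "c1", "+", 0, stop, [(0, end)], [], (0, end),
                     [(p, PA_3UTR) for p in pas])


def _minus_gene(genome_len, stop=100, pas=(149,), gene_id="gm"):
    m = lambda p: genome_len - 1 - p
    end = max(pas) + 50
    return GeneModel(gene_id, "c1", "-", m(0), m(stop),
                     [(genome_len - end, genome_len)], [],
                     (genome_len - end, genome_len),
                     [(m(p), PA_3UTR) for p in pas])


def test_sutr_extraction_coordinates():
    genome = {"c1": "A" * 100 + "CGCGCGCGCG" * 5 + "A" * 100}
    regs = se.extract_regions([_plus_gene()], genome)
    assert len(regs) == 1
    assert regs[0].label == "sUTR"
    assert regs[0].sequence == se._to_rna(genome["c1"][100:150])


def test_minus_strand_extraction_mirrors_plus():
    rng = np.random.default_rng(1)
    fwd = "".join(rng.choice(list("ACGT"), 400))
    genome_f = {"c1": fwd}
    genome_r = {"c1": revcomp(fwd)}
    gp = _plus_gene(stop=100, pas=(149, 249))
    gm = _minus_gene(400, stop=100, pas=(149, 249))
    rf = {r.label: r.sequence for r in se.extract_regions([gp], genome_f)}
    rr = {r.label: r.sequence for r in se.extract_regions([gm], genome_r)}
    assert rf == rr


def test_planted_motifs_recovered_in_regions(small_dataset):
    genes, genome, _ = small_dataset
    d = SimDesign(n_genes=30, seed=11, motif=("UGUAAA", "cUTR", 1.0))
    genome2, _, motifs = make_sequences_and_intervals(genes, genome, d)
    regs = {r.id: r for r in se.extract_regions(genes, genome2) if r.label == "cUTR"}
    assert len(motifs) > 0
    for r in motifs.itertuples():
        assert "UGUAAA" in regs[r.gene_id].sequence


def test_identical_sets_give_p1_ss0():
    seqs = ["ACGUACGU", "UUUUGGGG", "CAGUCAGU"]
    out = se.kmer_fisher(seqs, list(seqs), k=4)
    assert (out["p"] == 1.0).all()
    assert (out["ss"] == 0.0).all()


def test_kmer_fisher_matches_bruteforce_tail():
    fg = ["AUUUUA"] * 50 + ["ACGCGA"] * 50
    bg = ["AUUUUA"] * 5 + ["ACGCGA"] * 95
    out = se.kmer_fisher(fg, bg, k=4)
    rec = out.loc["UUUU"]
    assert (rec.fg_with, rec.bg_with) == (50, 5)
    p_ref, d_ref = _hypergeom_tail_bruteforce(50, 100, 5, 100)
    assert rec.p == pytest.approx(p_ref, abs=1e-12)
    assert rec.p < 1e-8 and rec.direction == "fg"


def test_k_longer_than_sequences_gives_empty_table():
    out = se.kmer_fisher(["ACGU"], ["UUUU"], k=10)
    assert len(out) == 0


def test_ss_antisymmetric_under_set_swap():
    fg = ["AUUUUA"] * 30 + ["ACGCGA"] * 70
    bg = ["AUUUUA"] * 10 + ["GCGCGC"] * 90
    a = se.kmer_fisher(fg, bg, k=4)["ss"]
    b = se.kmer_fisher(bg, fg, k=4)["ss"]
    shared = a.index.intersection(b.index)
    assert np.allclose(a.loc[shared], -b.loc[shared], atol=1e-12)


@pytest.mark.parametrize(
    "p,direction,expected",
    [(1.0, "fg", 0.0), (0.01, "fg", 2.0), (0.001, "bg", -3.0)],
)
def test_significance_score_values(p, direction, expected):
    assert se.significance_score(p, direction) == pytest.approx(expected)


def test_significance_score_rejects_nonpositive_p():
    with pytest.raises(ValueError):
        se.significance_score(0.0, "fg")


def test_ss_correlation_trivial_and_null():
    x = pd.Series(np.linspace(-3, 3, 256), index=[f"k{i}" for i in range(256)])
    assert se.ss_correlation(x, x) == pytest.approx(1.0)
    assert se.ss_correlation(x, -x) == pytest.approx(-1.0)
    rng = np.random.default_rng(0)
    hits = 0
    for _ in range(20):
        y = pd.Series(rng.normal(size=256), index=x.index)
        z = pd.Series(rng.normal(size=256), index=x.index)
        if abs(se.ss_correlation(y, z)) < 0.3:
            hits += 1
    assert hits >= 19


def test_ss_correlation_zero_variance_is_nan():
    x = pd.Series([1.0, 2.0], index=["a", "b"])
    y = pd.Series([0.5, 0.5], index=["a", "b"])
    assert np.isnan(se.ss_correlation(x, y))


def test_pa_flank_windows_are_100_40_100_nt():
    genome = {"c1": "".join(np.random.default_rng(2).choice(list("ACGT"), 600))}
    flanks = se.extract_pa_flanks([("c1", "+", 300)], genome)
    assert len(flanks["paflank:-100..-41"][0].sequence) == 60
    assert len(flanks["paflank:-40..-1"][0].sequence) == 40
    assert len(flanks["paflank:+1..+100"][0].sequence) == 100
    # -1 offset is the cleavage base itself
    assert flanks["paflank:-40..-1"][0].sequence[-1] == se._to_rna(genome["c1"][300])
    assert flanks["paflank:+1..+100"][0].sequence[0] == se._to_rna(genome["c1"][301])


def test_pa_flank_enrichment_finds_planted_window_motif():
    rng = np.random.default_rng(3)
    genome_list = list("".join(rng.choice(list("ACGT"), 40_000)))
    reg, bg = [], []
    for i in range(40):
        pos = 300 + i * 500
        if i < 20:  # regulated distal pAs: plant GGGGGG at +10..+15
            genome_list[pos + 10 : pos + 16] = list("GGGGGG")
            reg.append(("c1", "+", pos, "distal"))
        else:
            bg.append(("c1", "+", pos, "distal"))
    genome = {"c1": "".join(genome_list)}
    out = se.pa_flank_enrichment(reg, bg, genome, k=6)
    down = out[("paflank:+1..+100", "distal")]
    assert down.sort_values("p").index[0] == "GGGGGG"
    for wname in ("paflank:-100..-41", "paflank:-40..-1"):
        tab = out[(wname, "distal")]
        assert tab.loc["GGGGGG"].p > 1e-4 if "GGGGGG" in tab.index else True


def test_pa_flank_enrichment_identical_sets_all_zero_and_empty_errors():
    genome = {"c1": "".join(np.random.default_rng(4).choice(list("ACGT"), 2000))}
    pas = [("c1", "+", 300 + 200 * i, "proximal") for i in range(5)]
    out = se.pa_flank_enrichment(pas, pas, genome, k=4)
    for tab in out.values():
        assert (tab["ss"] == 0).all()
    with pytest.raises(ValueError):
        se.pa_flank_enrichment([], pas, genome)


def test_set_enrichment_trivial_and_oracle():
    universe = {f"g{i}" for i in range(40)}
    gene_set = {f"g{i}" for i in range(10)}
    ann = {"all": set(universe), "exact": set(gene_set), "none": {"g30", "g31"}}
    out = se.set_enrichment(gene_set, universe, ann)
    assert out.loc["all", "p"] == pytest.approx(1.0)
    p_ref, _ = _hypergeom_tail_bruteforce(10, 10, 0, 30)
    assert out.loc["exact", "p"] == pytest.approx(p_ref, abs=1e-12)
    assert out["p"].idxmin() == "exact"
    # empty set: p = 1 everywhere
    out0 = se.set_enrichment(set(), universe, ann)
    assert (out0["p"] == 1.0).all()


def test_set_enrichment_requires_subset():
    with pytest.raises(ValueError):
        se.set_enrichment({"x"}, {"y"}, {})
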