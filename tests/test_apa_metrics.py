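"""RE/RED arithmetic, isoform selection, weighted sizes, set aggregation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from apatrace import apa_metrics as am
from apatrace.benchmarks import matrix_for_gene, two_pa_gene
from apatrace.models import PA_3UTR, PA_INTRON, PA_UARNA, GeneModel


# -- RE / RED ---------------------------------------------------------------

def test_re_symmetry_and_log_identity():
    assert am.relative_expression(10, 10) == 0
    assert am.relative_expression(5, 10) == 1


@given(
    prx=st.floats(0.01, 1e4, allow_nan=False),
    dis=st.floats(0.01, 1e4, allow_nan=False),
)
def test_re_antisymmetry(prx, dis):
    assert am.relative_expression(prx, dis) == pytest.approx(
        -am.relative_expression(dis, prx), abs=1e-9
    )


def test_re_undefined_without_pseudocount():
    with pytest.raises(ValueError):
        am.relative_expression(0, 0, pseudo=0)


def test_pseudocount_applied_only_on_zero():
    # 0 raw count: half-read pseudocount keeps RE finite
    assert np.isfinite(am.re_from_counts(0, 10))
    # both positive: plain ratio
    assert am.re_from_counts(5, 10) == pytest.approx(1.0)


@given(a=st.floats(-5, 5), b=st.floats(-5, 5))
def test_red_antisymmetry_and_sign(a, b):
    assert am.red(a, b) == pytest.approx(-am.red(b, a))


def test_red_shortening_sign_convention():
    # RE drops from 1 to -1 between samples: RED -2, toward proximal
    assert am.red(1, -1) == -2


# -- isoform selection ------------------------------------------------------

def _three_pa_gene():
    stop = 500
    pas = [(stop + s - 1, PA_3UTR) for s in (100, 400, 800)]
    return GeneModel("g3", "chrT", "+", 0, stop, [(0, 1500)], [], (0, 1500), pas)


def test_top_two_isoform_selection_and_ordering():
    gene = _three_pa_gene()
    m = matrix_for_gene(gene, np.array([[100, 90], [50, 60], [5, 2]]), ["a", "b"])
    pair = am.select_top_isoforms(gene, m, ["a", "b"])
    assert pair is not None
    assert gene.utr3_size(pair.prox_pa.summit) == 100
    assert gene.utr3_size(pair.dist_pa.summit) == 400


def test_min_reads_threshold_discards_pair():
    gene = _three_pa_gene()
    m = matrix_for_gene(gene, np.array([[10, 1], [8, 0], [0, 0]]), ["a", "b"])
    assert am.select_top_isoforms(gene, m, ["a", "b"], min_reads=20) is None
    assert am.select_top_isoforms(gene, m, ["a", "b"], min_reads=19) is not None


def test_tie_break_is_deterministic_5prime_first():
    gene = _three_pa_gene()
    m = matrix_for_gene(gene, np.array([[50, 1], [50, 1], [50, 1]]), ["a", "b"])
    pair = am.select_top_isoforms(gene, m, ["a", "b"])
    sizes = {gene.utr3_size(pair.prox_pa.summit), gene.utr3_size(pair.dist_pa.summit)}
    assert sizes == {100, 400}  # 5'-most pAs win the three-way tie


def test_single_utr_gene_yields_no_pair():
    gene = two_pa_gene()
    m = matrix_for_gene(gene, np.array([[10, 10], [10, 10]]), ["a", "b"])
    sutr = GeneModel("s", "chrT", "+", 0, 500, [(0, 900)], [], (0, 900),
                     [(699, PA_3UTR)])
    ms = matrix_for_gene(sutr, np.array([[100, 100]]), ["a", "b"])
    assert am.select_top_isoforms(sutr, ms, ["a", "b"]) is None


# -- weighted 3'UTR size ----------------------------------------------------

@pytest.mark.parametrize(
    "counts,expected",
    [
        ([60, 0], 200),       # single expressed isoform: its own size
        ([50, 50], 600),      # sizes 200/1000 equal weights
        ([75, 25], 400),      # 0.75*200 + 0.25*1000
    ],
)
def test_weighted_utr_size_arithmetic(counts, expected):
    gene = two_pa_gene(sizes=(200, 1000))
    m = matrix_for_gene(gene, np.array(counts)[:, None])
    assert am.weighted_utr_size(gene, m, "s1") == pytest.approx(expected)


def test_weighted_utr_size_requires_min_reads():
    gene = two_pa_gene()
    m = matrix_for_gene(gene, np.array([30, 19])[:, None])
    assert am.weighted_utr_size(gene, m, "s1", min_reads=50) is None


@given(st.integers(0, 500), st.integers(0, 500))
def test_weighted_size_bounded_by_isoform_sizes(c1, c2):
    if c1 + c2 < 50:
        return
    gene = two_pa_gene(sizes=(200, 1000))
    m = matrix_for_gene(gene, np.array([c1, c2])[:, None])
    w = am.weighted_utr_size(gene, m, "s1")
    assert 200 <= w <= 1000


# -- gene expression & aggregate sets ---------------------------------------

def _mixed_gene():
    stop = 2500
    return GeneModel(
        "mx", "chr1", "+", 0, stop,
        exons=[(0, 300), (2000, 3500)], introns=[(300, 2000)],
        threeprime_exon=(2000, 3500),
        pa_positions=[(2799, PA_3UTR), (3099, PA_3UTR), (1000, PA_INTRON)],
    )


def test_gene_expression_counts_only_3p_exon_pas():
    gene = _mixed_gene()
    m = matrix_for_gene(gene, np.array([[5], [7], [4]]))
    # totals: 16 reads; RPM of 3'UTR pAs only
    assert am.gene_expression_rpm(gene, m, "s1") == pytest.approx((5 + 7) / 16 * 1e6)


def test_aggregate_sets_cds_apa():
    gene = _mixed_gene()
    m = matrix_for_gene(gene, np.array([[5], [7], [4]]))
    cds, utr = am.aggregate_sets(gene, m, "cds_apa")
    assert cds.tolist() == [4] and utr.tolist() == [12]


def test_aggregate_sets_uarna_exclusions():
    gene = _mixed_gene()
    gene2 = GeneModel(
        "mx", "chr1", "+", 0, 2500,
        exons=[(0, 300), (2000, 3500)], introns=[(300, 2000)],
        threeprime_exon=(2000, 3500),
        pa_positions=[(2799, PA_3UTR), (1000, PA_INTRON)],
    )
    m = matrix_for_gene(gene2, np.array([[8], [6]]))
    # attach a uaRNA cluster manually
    from apatrace.models import PaCluster

    ua = PaCluster("chr1", "-", 300, (300, 301), np.array([3]), PA_UARNA, "mx")
    m.clusters.append(ua)
    m.counts.loc[ua.cluster_id] = [3]
    ua_vec, sense_vec = am.aggregate_sets(gene2, m, "uarna")
    assert ua_vec.tolist() == [3]
    # intronic pA at 1000 is within 2 kb downstream of TSS: excluded
    assert sense_vec.tolist() == [8]


def test_no_cds_pa_gives_zero_vector():
    gene = two_pa_gene()
    m = matrix_for_gene(gene, np.array([[10], [10]]))
    cds, utr = am.aggregate_sets(gene, m, "cds_apa")
    assert cds.tolist() == [0] and utr.tolist() == [20]


# -- intron position groups --------------------------------------------------

def _label_oracle(i, n):
    """The stated priority rule, applied literally (5' labels first)."""
    if i == 1:
        return "+1"
    if i == 2:
        return "+2"
    if i == n:
        return "-1"
    if i == n - 1:
        return "-2"
    return "M"


@pytest.mark.parametrize("n", range(1, 6))
def test_intron_groups_match_rule_exhaustively(n):
    for i in range(1, n + 1):
        assert am.intron_position_group(i, n) == _label_oracle(i, n)


def test_intron_group_examples_and_errors():
    assert am.intron_position_group(1, 10) == "+1"
    assert am.intron_position_group(10, 10) == "-1"
    assert am.intron_position_group(5, 10) == "M"
    with pytest.raises(ValueError):
        am.intron_position_group(0, 3)


# -- sUTR regulation classes -------------------------------------------------

@pytest.mark.parametrize(
    "a,b,expected",
    [
        (10, 15, "up"),     # 1.5 > 1.4
        (10, 10, "flat"),
        (14, 10, "flat"),   # 1.4 is not > 1.4 (strict)
        (15, 10, "down"),
        (0, 10, "up"),      # pseudocount keeps the ratio defined
    ],
)
def test_sutr_fold_change_classes(a, b, expected):
    assert am.classify_sutr_regulation(a, b) == expected


def test_autr_size_bins_are_balanced():
    sizes = {f"g{i}": 100 + 10 * i for i in range(50)}
    bins = am.autr_size_bins(sizes)
    counts = np.bincount(list(bins.values()))[1:]
    assert (counts == 10).all()
    assert bins["g0"] == 1 and bins["g49"] == 5
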