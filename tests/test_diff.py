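"""Per-gene methylation-loss arithmetic against hand-computed oracles."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methscreen.diff import (
    assign_sites_to_gene,
    diff_gene_methylation,
    format_loss_percent,
    genome_wide_diff,
    promoter_window,
    relative_cds_position,
)
from methscreen.models import GeneModel, Methylome

from conftest import make_call, make_methylome


class TestSiteAssignment:
    def test_cds_call_relative_position_on_plus_strand(self, plus_gene):
        methylome = make_methylome([1212])
        cds, prom = assign_sites_to_gene(methylome, plus_gene, promoter_len=300)
        assert len(cds) == 1 and not prom
        assert relative_cds_position(plus_gene, 1212) == 213

    def test_call_nine_bp_upstream_is_promoter(self, plus_gene):
        methylome = make_methylome([991])  # 9 bp upstream of start 1000
        cds, prom = assign_sites_to_gene(methylome, plus_gene, promoter_len=300)
        assert not cds and len(prom) == 1

    def test_minus_strand_promoter_is_downstream_in_genomic_coords(self, minus_gene):
        methylome = make_methylome([1625])
        cds, prom = assign_sites_to_gene(methylome, minus_gene, promoter_len=300)
        assert not cds and len(prom) == 1

    def test_promoter_window_clipped_at_contig_start(self):
        gene = GeneModel("orf1", 1, "chr", 100, 399, "+", "p")
        assert promoter_window(gene, 300) == (1, 99)

    def test_either_strand_counts_within_cds(self, plus_gene):
        methylome = Methylome("s", [make_call(1475, "+"), make_call(1476, "-")])
        cds, _ = assign_sites_to_gene(methylome, plus_gene, 300)
        assert len(cds) == 2


class TestDiffGene:
    def test_six_of_seven_lost(self, plus_gene):
        wt = make_methylome([1000, 1100, 1200, 1300, 1400, 1500, 1600])
        mut = make_methylome([1300])
        delta = diff_gene_methylation(wt, mut, plus_gene)
        assert (delta.cds_sites_lost, delta.cds_sites_wt) == (6, 7)
        assert delta.cds_loss_fraction == pytest.approx(6 / 7)

    def test_identical_methylomes_lose_nothing(self, plus_gene):
        wt = make_methylome([1000, 1100, 1200])
        delta = diff_gene_methylation(wt, wt, plus_gene)
        assert delta.cds_sites_lost == 0
        assert delta.cds_loss_fraction == 0.0
        assert delta.promoter_loss_fraction == 0.0

    def test_abundance_loss_is_lost_over_cds_length(self):
        gene = GeneModel("orf1", 1, "chr", 1001, 1500, "+", "p")  # 500 bp
        wt = make_methylome([1001, 1101, 1201, 1301, 1401])
        mut = Methylome("mut")
        delta = diff_gene_methylation(wt, mut, gene)
        assert delta.abundance_loss_fraction == pytest.approx(0.01)

    def test_total_cds_and_promoter_loss(self, plus_gene):
        positions = [plus_gene.start + p - 1
                     for p in (213, 237, 309, 314, 423, 462, 476, 477, 554)]
        wt = make_methylome(positions + [991])
        delta = diff_gene_methylation(wt, Methylome("mut"), plus_gene)
        assert delta.cds_loss_fraction == 1.0
        assert delta.promoter_loss_fraction == 1.0
        assert delta.cds_lost_positions == (213, 237, 309, 314, 423, 462, 476, 477, 554)

    def test_minus_gene_positions_reported_on_coding_strand(self, minus_gene):
        wt = make_methylome([minus_gene.end - 212])  # relative position 213
        delta = diff_gene_methylation(wt, Methylome("mut"), minus_gene)
        assert delta.cds_lost_positions == (213,)

    def test_gene_on_absent_contig_yields_zero_delta(self, caplog):
        gene = GeneModel("orfZ", 9, "plasmid", 100, 399, "+", "p")
        wt = make_methylome([150])  # on 'chr', not 'plasmid'
        with caplog.at_level("WARNING"):
            delta = diff_gene_methylation(wt, Methylome("mut"), gene)
        assert delta.cds_sites_wt == 0 and delta.cds_loss_fraction == 0.0
        assert "plasmid" in caplog.text

    def test_min_score_drops_low_quality_calls_in_both_samples(self, plus_gene):
        wt = Methylome("wt", [make_call(1100, score=10), make_call(1200, score=50)])
        mut = Methylome("mut", [make_call(1200, score=10)])
        delta = diff_gene_methylation(wt, mut, plus_gene, min_score=30)
        # WT keeps only 1200; mutant's 1200 call is dropped, so it counts lost.
        assert (delta.cds_sites_wt, delta.cds_sites_lost) == (1, 1)


class TestGenomeWideDiff:
    def _two_genes(self):
        return [
            GeneModel("orf1", 1, "chr", 100, 399, "+", "p"),
            GeneModel("orf2", 2, "chr", 700, 999, "+", "p"),
        ]

    def test_conservation_of_totals_across_disjoint_genes(self):
        genes = self._two_genes()
        wt = make_methylome([100, 200, 300, 700, 800, 900, 950])
        deltas, totals = genome_wide_diff(wt, Methylome("mut"), genes, promoter_len=0)
        assert [(d.cds_sites_lost, d.cds_sites_wt) for d in deltas] == [(3, 3), (4, 4)]
        assert (totals.wt_total, totals.mut_total) == (7, 0)

    def test_empty_mutant_means_full_loss_wherever_wt_has_sites(self):
        genes = self._two_genes()
        wt = make_methylome([150, 750])
        deltas, _ = genome_wide_diff(wt, Methylome("mut"), genes)
        assert all(d.cds_loss_fraction == 1.0 for d in deltas)

    def test_unsorted_genes_rejected(self):
        genes = list(reversed(self._two_genes()))
        with pytest.raises(ValueError, match="sorted"):
            genome_wide_diff(Methylome("wt"), Methylome("mut"), genes)


class TestFormatLossPercent:
    @pytest.mark.parametrize(
        ("lost", "total", "expected"),
        [(6, 7, "86%"), (7, 8, "88%"), (20, 24, "83%"), (12, 13, "92%"),
         (5, 6, "83%"), (9, 9, "100%"), (11, 12, "92%")],
    )
    def test_published_site_loss_percentages(self, lost, total, expected):
        assert format_loss_percent(lost / total, 0) == expected

    def test_one_decimal_abundance_formatting(self):
        assert format_loss_percent(9 / 621, 1) == "1.4%"
        assert format_loss_percent(0.01, 1) == "1%"
        assert format_loss_percent(0.0125, 1) == "1.3%"  # half-up at the tie

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            format_loss_percent(1.2, 0)


# --- property tests ------------------------------------------------------

GENE = GeneModel("orfP", 1, "chr", 50, 150, "+", "p")

call_sets = st.lists(
    st.tuples(st.integers(1, 200), st.sampled_from("+-")),
    max_size=50, unique=True,
)


def brute_force_lost(wt: Methylome, mut: Methylome, gene: GeneModel) -> set:
    """Double loop over all call pairs: a WT CDS call is lost iff no mutant
    call matches its key exactly."""
    lost = set()
    for wt_call in wt:
        if wt_call.seqid != gene.seqid or not gene.start <= wt_call.position <= gene.end:
            continue
        if not any(mut_call.key == wt_call.key for mut_call in mut):
            lost.add(wt_call.key)
    return lost


@settings(max_examples=100, derandomize=True)
@given(wt=call_sets, mut=call_sets)
def test_diff_matches_brute_force_oracle(wt, mut):
    wt_m = Methylome("wt", (make_call(p, s) for p, s in wt))
    mut_m = Methylome("mut", (make_call(p, s) for p, s in mut))
    delta = diff_gene_methylation(wt_m, mut_m, GENE, promoter_len=0)
    assert delta.cds_sites_lost == len(brute_force_lost(wt_m, mut_m, GENE))


@settings(max_examples=100, derandomize=True)
@given(wt=call_sets, mut=call_sets)
def test_conservation_lost_plus_retained_equals_wt(wt, mut):
    wt_m = Methylome("wt", (make_call(p, s) for p, s in wt))
    mut_m = Methylome("mut", (make_call(p, s) for p, s in mut))
    delta = diff_gene_methylation(wt_m, mut_m, GENE, promoter_len=0)
    cds_keys = {
        c.key for c in wt_m if GENE.start <= c.position <= GENE.end
    }
    retained = len(cds_keys & mut_m.keys())
    assert delta.cds_sites_lost + retained == delta.cds_sites_wt


@settings(max_examples=100, derandomize=True)
@given(calls=call_sets)
def test_self_diff_is_zero(calls):
    methylome = Methylome("a", (make_call(p, s) for p, s in calls))
    delta = diff_gene_methylation(methylome, methylome, GENE)
    assert delta.cds_sites_lost == 0 and delta.promoter_sites_lost == 0


@settings(max_examples=50, derandomize=True)
@given(
    calls=st.lists(
        st.tuples(st.integers(1, 200), st.sampled_from("+-"), st.floats(0, 100)),
        max_size=50, unique_by=lambda t: (t[0], t[1]),
    ),
    thresholds=st.tuples(st.floats(0, 100), st.floats(0, 100)),
)
def test_raising_min_score_never_increases_wt_sites(calls, thresholds):
    wt = Methylome("wt", (make_call(p, s, score=q) for p, s, q in calls))
    lo, hi = sorted(thresholds)
    d_lo = diff_gene_methylation(wt, Methylome("m"), GENE, min_score=lo)
    d_hi = diff_gene_methylation(wt, Methylome("m"), GENE, min_score=hi)
    assert d_hi.cds_sites_wt <= d_lo.cds_sites_wt
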