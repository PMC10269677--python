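"""Ordinal binning, dense-region calling, and a brute-force scan oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methscreen.density import (
    DensityBin,
    call_dense_regions,
    compute_bin_densities,
    ordinal_in_regions,
)
from methscreen.models import GeneModel, PathwayAssignment


def make_genes(ordinals):
    return [
        GeneModel(f"orf{o}", o, "chr", 1000 * o, 1000 * o + 299, "+", "p")
        for o in sorted(ordinals)
    ]


def make_assignments(genes, member_ordinals):
    member_ordinals = set(member_ordinals)
    return [
        PathwayAssignment(g.gene_id, g.orf_ordinal in member_ordinals) for g in genes
    ]


class TestBinDensities:
    def test_hand_counted_small_instance(self):
        genes = make_genes(range(1, 11))
        bins = compute_bin_densities(genes, make_assignments(genes, {2, 3}), bin_size=5)
        # bin0 covers ordinals [0,5): genes 1-4 present, members {2,3}.
        assert bins[0].n_genes == 4 and bins[0].n_assigned == 2
        assert bins[0].density == pytest.approx(0.5)
        # bin1 covers [5,10): genes 5-9, no members; bin2 covers [10,15): gene 10.
        assert bins[1].density == 0.0
        assert bins[2].n_genes == 1

    def test_no_assignments_gives_all_zero_densities(self):
        genes = make_genes(range(1, 30))
        bins = compute_bin_densities(genes, make_assignments(genes, set()), bin_size=10)
        assert all(b.density == 0.0 for b in bins)

    def test_all_assigned_gives_density_one_in_occupied_bins(self):
        genes = make_genes(range(1, 30))
        bins = compute_bin_densities(
            genes, make_assignments(genes, range(1, 30)), bin_size=10
        )
        assert all(b.density == 1.0 for b in bins if b.n_genes)

    def test_counts_are_conserved_across_bins(self):
        rng = np.random.default_rng(0)
        ordinals = sorted(rng.choice(2000, size=400, replace=False) + 1)
        genes = make_genes(ordinals)
        members = set(int(o) for o in rng.choice(ordinals, size=80, replace=False))
        bins = compute_bin_densities(genes, make_assignments(genes, members), bin_size=100)
        assert sum(b.n_genes for b in bins) == len(genes)
        assert sum(b.n_assigned for b in bins) == len(members)


class TestRegionCalling:
    def _bins(self, densities, bin_size=100):
        return [
            DensityBin(k, k * bin_size, (k + 1) * bin_size, 10,
                       int(10 * d), d)
            for k, d in enumerate(densities)
        ]

    def test_adjacent_qualifying_bins_merge_into_one_region(self):
        densities = [0.0] * 7 + [0.2, 0.3] + [0.0] * 7 + [0.15]
        regions = call_dense_regions(self._bins(densities), threshold=0.10)
        assert [(r.start_ordinal, r.end_ordinal) for r in regions] == [
            (700, 900), (1600, 1700),
        ]
        assert regions[0].n_bins == 2
        assert regions[0].max_density == pytest.approx(0.3)
        assert regions[0].mean_density == pytest.approx(0.25)

    def test_no_bin_above_threshold_gives_empty_list(self):
        assert call_dense_regions(self._bins([0.05, 0.10, 0.0])) == []

    def test_threshold_is_strict(self):
        # exactly 10% does not qualify ("more than 10%")
        assert call_dense_regions(self._bins([0.10])) == []
        assert len(call_dense_regions(self._bins([0.1000001]))) == 1

    def test_unordered_bins_rejected(self):
        bins = list(reversed(self._bins([0.2, 0.2])))
        with pytest.raises(ValueError, match="ordered"):
            call_dense_regions(bins)


class TestOrdinalInRegions:
    @pytest.fixture
    def regions(self):
        densities = {7: 0.2, 8: 0.2, 16: 0.2, 22: 0.2, 47: 0.2, 48: 0.2}
        bins = [
            DensityBin(k, k * 100, (k + 1) * 100, 10, 2, densities.get(k, 0.0))
            for k in range(50)
        ]
        return call_dense_regions(bins)

    def test_published_region_set_reproduced(self, regions):
        assert [(r.start_ordinal, r.end_ordinal) for r in regions] == [
            (700, 900), (1600, 1700), (2200, 2300), (4700, 4900),
        ]

    @pytest.mark.parametrize(
        ("ordinal", "expected"),
        [(4759, True), (4820, True), (199, False), (1650, True), (4900, False),
         (700, True), (900, False)],
    )
    def test_half_open_membership(self, regions, ordinal, expected):
        assert ordinal_in_regions(ordinal, regions) is expected


# --- oracle equivalence and monotonicity ---------------------------------


def brute_force_regions(genes, assignments, bin_size, threshold):
    """Label every bin by a direct scan over genes, then merge adjacent
    qualifying bins; independent of the binned implementation."""
    member = {a.gene_id: a.in_category for a in assignments}
    last = max(g.orf_ordinal for g in genes)
    spans = []
    k = 0
    while k * bin_size <= last:
        lo, hi = k * bin_size, (k + 1) * bin_size
        present = [g for g in genes if lo <= g.orf_ordinal < hi]
        assigned = [g for g in present if member.get(g.gene_id)]
        if present and len(assigned) / len(present) > threshold:
            if spans and spans[-1][1] == lo:
                spans[-1] = (spans[-1][0], hi)
            else:
                spans.append((lo, hi))
        k += 1
    return spans


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    n=st.integers(1, 1000),
    rate=st.floats(0.0, 0.5),
    bin_size=st.sampled_from([10, 50, 100]),
)
def test_region_calls_match_brute_force_scan(seed, n, rate, bin_size):
    rng = np.random.default_rng(seed)
    ordinals = sorted(int(o) + 1 for o in rng.choice(3 * n, size=n, replace=False))
    genes = make_genes(ordinals)
    assignments = [
        PathwayAssignment(g.gene_id, bool(rng.random() < rate)) for g in genes
    ]
    bins = compute_bin_densities(genes, assignments, bin_size=bin_size)
    got = [(r.start_ordinal, r.end_ordinal)
           for r in call_dense_regions(bins, threshold=0.10)]
    assert got == brute_force_regions(genes, assignments, bin_size, 0.10)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000), t_pair=st.tuples(st.floats(0, 1), st.floats(0, 1)))
def test_raising_threshold_shrinks_regions(seed, t_pair):
    rng = np.random.default_rng(seed)
    ordinals = sorted(int(o) + 1 for o in rng.choice(600, size=200, replace=False))
    genes = make_genes(ordinals)
    assignments = [
        PathwayAssignment(g.gene_id, bool(rng.random() < 0.2)) for g in genes
    ]
    bins = compute_bin_densities(genes, assignments, bin_size=50)
    lo, hi = sorted(t_pair)
    loose = call_dense_regions(bins, threshold=lo)
    strict = call_dense_regions(bins, threshold=hi)

    def covered(regions):
        return {o for r in regions for o in range(r.start_ordinal, r.end_ordinal)}

    assert covered(strict) <= covered(loose)


def test_planted_regions_fully_recovered_at_default_rates():
    """In-region rate 0.3 vs background 0.02: every planted span is covered."""
    from methscreen.simulate import generate_annotation, generate_pathway_table

    spans = [(700, 900), (1600, 1700), (2200, 2300), (4700, 4900)]
    for seed in range(5):
        genes = generate_annotation(5000, seed=seed)
        assignments = generate_pathway_table(
            genes, spans, in_region_rate=0.3, background_rate=0.02, seed=seed + 100
        )
        bins = compute_bin_densities(genes, assignments, bin_size=100)
        regions = call_dense_regions(bins, threshold=0.10)
        covered = {
            o for r in regions for o in range(r.start_ordinal, r.end_ordinal)
        }
        for lo, hi in spans:
            assert set(range(lo, hi)) <= covered
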