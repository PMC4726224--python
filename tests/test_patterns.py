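import pytest

from gridpatterns.grid import CellCoord
from gridpatterns.patterns import (
    ComponentPool,
    cluster_components,
    filter_components,
    overlap_score,
    pool_components,
    sort_patterns,
)
from gridpatterns.quantize import Component, QuantizedSlice


def comp(gene, tp, cells):
    return Component(gene, tp, frozenset(CellCoord(*c) for c in cells))


def qslice_with(comps, n_valid=80):
    gene, tp = comps[0].gene, comps[0].timepoint
    return QuantizedSlice(gene, tp, 0.5, tuple(comps), n_valid)


BLOB_A = [(1, 1), (1, 2), (2, 1), (2, 2)]
BLOB_B = [(10, 1), (10, 2), (11, 1), (11, 2)]


class TestPooling:
    def test_only_non_global_slices_contribute(self):
        q1 = qslice_with([comp("a", "E11.5", BLOB_A)])
        q2 = qslice_with([comp("b", "E11.5", BLOB_B)])
        quantized = {("a", "E11.5"): q1, ("b", "E11.5"): q2}
        bits = {("a", "E11.5"): 1, ("b", "E11.5"): 0}
        pool = pool_components(quantized, bits)
        assert [(c.gene, c.timepoint) for c in pool.components] == [("b", "E11.5")]

    def test_all_global_gives_empty_pool(self):
        quantized = {("a", "E11.5"): qslice_with([comp("a", "E11.5", BLOB_A)])}
        assert len(pool_components(quantized, {("a", "E11.5"): 1})) == 0

    def test_two_components_both_pooled_with_tags(self):
        q = qslice_with([comp("a", "P4", BLOB_A), comp("a", "P4", BLOB_B)])
        pool = pool_components({("a", "P4"): q}, {})
        assert len(pool) == 2
        assert all((c.gene, c.timepoint) == ("a", "P4") for c in pool.components)
        assert pool.n_valid[("a", "P4")] == 80


class TestFiltering:
    def test_singleton_removed_by_default(self):
        pool = ComponentPool(
            (comp("a", "E11.5", [(1, 1)]), comp("a", "E11.5", BLOB_A)),
            {("a", "E11.5"): 80},
        )
        kept = filter_components(pool)
        assert [c.size for c in kept.components] == [4]

    def test_component_above_half_of_valid_removed(self):
        big = comp("a", "E11.5", [(i, j) for i in range(1, 15) for j in range(1, 4)])
        assert big.size == 42
        pool = ComponentPool((big,), {("a", "E11.5"): 80})
        assert len(filter_components(pool)) == 0
        # boundary: 41 cells with n_valid 80 exceeds half, 40 does not
        b41 = comp("a", "E11.5", [(i, 1) for i in range(1, 21)] + [(i, 2) for i in range(1, 21)] + [(1, 3)])
        assert b41.size == 41
        assert len(filter_components(ComponentPool((b41,), {("a", "E11.5"): 80}))) == 0
        b40 = comp("a", "E11.5", [(i, 1) for i in range(1, 21)] + [(i, 2) for i in range(1, 21)])
        assert len(filter_components(ComponentPool((b40,), {("a", "E11.5"): 80}))) == 1

    def test_permissive_parameters_are_identity(self):
        pool = ComponentPool(
            (comp("a", "E11.5", [(1, 1)]), comp("a", "E11.5", BLOB_A)),
            {("a", "E11.5"): 80},
        )
        kept = filter_components(pool, min_cells=1, max_fraction_of_valid=1.0)
        assert kept.components == pool.components


class TestOverlap:
    def test_identical_components(self):
        a = comp("a", "E11.5", BLOB_A)
        b = comp("b", "P4", BLOB_A)
        assert overlap_score(a, b) == 1.0

    def test_disjoint_components(self):
        assert overlap_score(comp("a", "E11.5", BLOB_A), comp("b", "P4", BLOB_B)) == 0.0

    def test_partial_overlap_is_jaccard(self):
        a = comp("a", "E11.5", [(1, 1), (1, 2)])
        b = comp("b", "E11.5", [(1, 2), (1, 3)])
        assert overlap_score(a, b) == pytest.approx(1 / 3)

    def test_symmetric(self):
        a = comp("a", "E11.5", [(1, 1), (1, 2), (2, 2)])
        b = comp("b", "P28", [(1, 2), (2, 2), (3, 2)])
        assert overlap_score(a, b) == overlap_score(b, a)


class TestClustering:
    def test_identical_components_one_cluster(self):
        pool = ComponentPool(
            tuple(comp(f"g{i}", "E11.5", BLOB_A) for i in range(3))
        )
        (cl,) = cluster_components(pool)
        assert cl.occurrence_count == 3
        assert cl.gene_count == 3

    def test_disjoint_groups_two_clusters(self):
        pool = ComponentPool(
            tuple(comp(f"g{i}", "E11.5", BLOB_A) for i in range(3))
            + tuple(comp(f"h{i}", "P4", BLOB_B) for i in range(2))
        )
        clusters = cluster_components(pool)
        assert [cl.occurrence_count for cl in clusters] == [3, 2]

    def test_partition_no_component_lost_or_duplicated(self):
        comps = (
            [comp(f"g{i}", "E11.5", BLOB_A) for i in range(3)]
            + [comp(f"h{i}", "P4", BLOB_B) for i in range(2)]
            + [comp("solo", "P28", [(5, 3), (5, 4)])]
        )
        pool = ComponentPool(tuple(comps))
        from collections import Counter

        for refine in (None, 0.4):
            clusters = cluster_components(pool, refine_mean_jaccard=refine)
            members = [m for cl in clusters for m in cl.members]
            assert Counter(members) == Counter(comps)

    def test_deterministic_repeated_runs(self):
        comps = tuple(
            comp(f"g{i}", "E11.5", BLOB_A if i % 2 else BLOB_B) for i in range(6)
        )
        a = cluster_components(ComponentPool(comps))
        b = cluster_components(ComponentPool(tuple(reversed(comps))))
        assert [cl.members for cl in a] == [cl.members for cl in b]

    def test_refinement_peels_chained_outlier(self):
        # two tight groups joined by a bridge component overlapping both
        tight = [comp(f"g{i}", "E11.5", BLOB_A) for i in range(4)]
        bridge = comp("x", "P4", BLOB_A[:3] + [(3, 1)])
        unrefined = cluster_components(ComponentPool(tuple(tight + [bridge])))
        assert unrefined[0].occurrence_count == 5
        refined = cluster_components(
            ComponentPool(tuple(tight + [bridge])), refine_mean_jaccard=0.8
        )
        assert refined[0].occurrence_count == 4
        assert sum(cl.occurrence_count for cl in refined) == 5

    def test_min_members_drops_small_clusters(self):
        pool = ComponentPool(
            tuple(comp(f"g{i}", "E11.5", BLOB_A) for i in range(5))
            + (comp("h", "P4", BLOB_B),)
        )
        clusters = cluster_components(pool, min_members=5)
        assert len(clusters) == 1


class TestSortingAndSummaries:
    def test_sort_by_occurrences_then_genes(self):
        big = cluster_components(
            ComponentPool(tuple(comp(f"g{i}", "E11.5", BLOB_A) for i in range(3)))
        )[0]
        small = cluster_components(
            ComponentPool(tuple(comp("h0", "E11.5", BLOB_B) for _ in range(1)))
        )[0]
        assert sort_patterns([small, big]) == [big, small]
        # same occurrences, more genes wins
        two_genes = cluster_components(
            ComponentPool((comp("a", "E11.5", BLOB_B), comp("b", "P4", BLOB_B)))
        )[0]
        one_gene = cluster_components(
            ComponentPool((comp("c", "E11.5", BLOB_A), comp("c", "P4", BLOB_A)))
        )[0]
        assert sort_patterns([one_gene, two_genes]) == [two_genes, one_gene]

    def test_frequency_map_single_member_is_indicator(self):
        (cl,) = cluster_components(ComponentPool((comp("a", "E11.5", BLOB_A),)))
        fm = cl.frequency_map()
        assert set(fm) == {CellCoord(*c) for c in BLOB_A}
        assert set(fm.values()) == {1.0}

    def test_frequency_map_partial_coverage(self):
        half = comp("a", "E11.5", BLOB_A[:2])
        full = comp("b", "P4", BLOB_A)
        (cl,) = cluster_components(ComponentPool((half, full)), jaccard_min=0.5)
        fm = cl.frequency_map()
        assert fm[CellCoord(1, 1)] == 1.0
        assert fm[CellCoord(2, 1)] == 0.5
        assert max(fm.values()) <= 1.0

    def test_time_profile_sums_to_occurrences(self):
        members = (
            comp("a", "E11.5", BLOB_A),
            comp("b", "E11.5", BLOB_A),
            comp("c", "P28", BLOB_A),
        )
        (cl,) = cluster_components(ComponentPool(members))
        profile = cl.time_profile()
        assert profile["E11.5"] == 2 and profile["P28"] == 1
        assert sum(profile.values()) == cl.occurrence_count
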