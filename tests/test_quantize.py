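import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gridpatterns.grid import CellCoord, GridSpec, build_adjacency
from gridpatterns.quantize import (
    AllMissingError,
    demarcate,
    select_structure,
    sweep_thresholds,
)

from conftest import make_line_slice, make_slice
from oracles import brute_runs, brute_select, line_adjacency


def slice_cells(sl):
    return dict(sl.observed_items())


class TestSweep:
    def test_1d_profile_runs(self, line7):
        adj = line_adjacency(7)
        runs = [(s.n_components, list(s.thetas)) for s in sweep_thresholds(line7, adj)]
        assert runs == [(1, [0.1]), (2, [0.5, 0.6]), (1, [0.7, 0.8])]

    def test_constant_slice_single_run_one_component(self):
        sl = make_slice([[0.5] * 4, [0.5] * 4])
        adj = build_adjacency(GridSpec(n_ap=4, n_dv=2, discrepancy_interfaces=()))
        (only,) = sweep_thresholds(sl, adj)
        assert only.n_components == 1
        assert only.thetas == (0.5,)
        assert len(only.components[0]) == 8

    def test_two_isolated_cells_merge_count(self):
        # cells at (1,1)=0.6 and (3,1)=0.9, nothing between
        sl = make_line_slice([0.6, None, 0.9])
        adj = line_adjacency(3)
        runs = {s.thetas: s.n_components for s in sweep_thresholds(sl, adj)}
        assert runs == {(0.6,): 2, (0.9,): 1}

    def test_all_missing_slice_raises(self):
        sl = make_line_slice([None, None])
        with pytest.raises(AllMissingError):
            sweep_thresholds(sl, line_adjacency(2))

    def test_components_connected_and_observed(self, line7):
        adj = line_adjacency(7)
        cells = slice_cells(line7)
        for s in sweep_thresholds(line7, adj):
            for comp in s.components:
                assert comp <= set(cells)
                # connectivity: flood from one member reaches all
                seen = {next(iter(comp))}
                frontier = list(seen)
                while frontier:
                    c = frontier.pop()
                    for nb in adj[c]:
                        if nb in comp and nb not in seen:
                            seen.add(nb)
                            frontier.append(nb)
                assert seen == set(comp)


class TestSelect:
    def test_1d_profile_tie_prefers_smaller_theta(self, line7):
        structures = sweep_thresholds(line7, line_adjacency(7))
        chosen = select_structure(structures)
        assert chosen.n_components == 2
        assert chosen.theta_lo == 0.5

    def test_all_below_floor_selects_none(self):
        sl = make_line_slice([0.05, 0.1, 0.15])
        assert select_structure(sweep_thresholds(sl, line_adjacency(3))) is None

    def test_single_eligible_structure_selected(self):
        sl = make_line_slice([0.5, 0.5])
        structures = sweep_thresholds(sl, line_adjacency(2))
        assert select_structure(structures) is structures[0]

    def test_strict_floor_excludes_exact_boundary(self):
        sl = make_line_slice([0.2, 0.2])
        structures = sweep_thresholds(sl, line_adjacency(2))
        assert select_structure(structures) is not None
        assert select_structure(structures, strict_floor=True) is None


class TestDemarcate:
    def test_constant_slice_theta_and_full_component(self):
        sl = make_line_slice([0.5, 0.5, 0.5])
        q = demarcate(sl, line_adjacency(3))
        assert q.theta == 0.5
        assert len(q.components) == 1
        assert q.cells == {CellCoord(i, 1) for i in (1, 2, 3)}

    def test_floor_failure_yields_empty_quantization(self):
        sl = make_line_slice([0.05, 0.1])
        q = demarcate(sl, line_adjacency(2))
        assert q.theta is None
        assert q.cells == frozenset()
        assert q.n_valid == 2

    def test_two_bump_profile_lower_vs_upper_bound(self):
        # two overlapping bumps peaking at cells 3 and 7
        profile = [0.05, 0.4, 0.7, 0.45, 0.35, 0.5, 0.8, 0.55, 0.05]
        sl = make_line_slice(profile)
        adj = line_adjacency(9)
        lower = demarcate(sl, adj, bound="lower")
        assert len(lower.components) == 2
        assert all(c.size > 1 for c in lower.components)
        assert lower.cells == {
            CellCoord(i, 1) for i in (2, 3, 4, 6, 7, 8)
        }
        upper = demarcate(sl, adj, bound="upper")
        assert len(upper.components) == 2
        assert upper.cells == {CellCoord(3, 1), CellCoord(7, 1)}

    def test_upper_bound_cells_subset_of_lower(self, line7):
        adj = line_adjacency(7)
        lower = demarcate(line7, adj, bound="lower")
        upper = demarcate(line7, adj, bound="upper")
        assert upper.cells <= lower.cells

    def test_all_missing_propagates(self):
        with pytest.raises(AllMissingError):
            demarcate(make_line_slice([None]), line_adjacency(1))


# --- oracle equivalence -----------------------------------------------------

_small_slice = st.lists(
    st.lists(
        st.one_of(st.none(), st.integers(0, 11).map(lambda k: k / 10)),
        min_size=4,
        max_size=6,
    ),
    min_size=2,
    max_size=4,
).filter(
    lambda rows: len({len(r) for r in rows}) == 1
    and any(v is not None for r in rows for v in r)
)


@given(rows=_small_slice)
@settings(max_examples=150, deadline=None)
def test_sweep_matches_brute_force_runs(rows):
    """Incremental union-find sweep equals flood-fill-at-every-threshold."""
    sl = make_slice(rows)
    spec = GridSpec(n_ap=len(rows[0]), n_dv=len(rows), discrepancy_interfaces=())
    adj = build_adjacency(spec)
    cells = slice_cells(sl)
    got = [(s.n_components, list(s.thetas)) for s in sweep_thresholds(sl, adj)]
    assert got == brute_runs(cells, adj)


@given(rows=_small_slice, stability=st.sampled_from(["count", "interval"]))
@settings(max_examples=150, deadline=None)
def test_selection_matches_brute_force(rows, stability):
    sl = make_slice(rows)
    spec = GridSpec(n_ap=len(rows[0]), n_dv=len(rows), discrepancy_interfaces=())
    adj = build_adjacency(spec)
    expected = brute_select(slice_cells(sl), adj, 0.2, stability=stability)
    q = demarcate(sl, adj, min_lower=0.2, stability=stability)
    if expected is None:
        assert q.theta is None
    else:
        assert q.theta == expected[0]
        assert len(q.components) == expected[2]


@given(rows=_small_slice)
@settings(max_examples=100, deadline=None)
def test_rank_invariance_under_monotone_transforms(rows):
    """With the absolute floor disabled, the demarcated cell sets depend only
    on the rank order of the values."""
    sl = make_slice(rows)
    spec = GridSpec(n_ap=len(rows[0]), n_dv=len(rows), discrepancy_interfaces=())
    adj = build_adjacency(spec)
    base = demarcate(sl, adj, min_lower=None)
    for transform in (lambda x: 2 * x + 1, lambda x: x**3, math.exp):
        t_rows = [
            [None if v is None else transform(v) for v in r] for r in rows
        ]
        q = demarcate(make_slice(t_rows), adj, min_lower=None)
        assert q.cells == base.cells
        assert sorted((c.cells for c in q.components), key=sorted) == sorted(
            (c.cells for c in base.components), key=sorted
        )


@given(rows=_small_slice)
@settings(max_examples=100, deadline=None)
def test_monotonicity_upper_subset_of_lower(rows):
    sl = make_slice(rows)
    spec = GridSpec(n_ap=len(rows[0]), n_dv=len(rows), discrepancy_interfaces=())
    adj = build_adjacency(spec)
    lower = demarcate(sl, adj)
    upper = demarcate(sl, adj, bound="upper")
    assert upper.cells <= lower.cells


def test_missing_cells_are_barriers():
    # a missing cell between two high cells keeps them in separate components
    sl = make_line_slice([0.6, None, 0.7])
    q = demarcate(sl, line_adjacency(3))
    assert len(q.components) == 2
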