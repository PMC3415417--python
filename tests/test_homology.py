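import itertools
import math

import numpy as np
import pytest

import topomap as tm
from topomap.ensemble import SpikeTrains
from topomap.homology import (
    Barcode,
    CoactivityParams,
    FilteredComplex,
    betti_at,
    betti_numbers,
    boundary_matrix,
    build_nerve_complex,
    build_temporal_complex,
    coactivity_sets,
    persistence,
    random_filtered_complex,
    temporal_betti_trace,
)


def simplex_set(pairs):
    return FilteredComplex(pairs)


def full_complex(vertices, max_dim, entry=0.0):
    pairs = []
    for k in range(1, max_dim + 2):
        pairs += [(c, entry) for c in itertools.combinations(vertices, k)]
    return FilteredComplex(pairs)


@pytest.fixture(scope="module")
def torus():
    tris = set()
    for i in range(7):
        tris.add(tuple(sorted((i % 7, (i + 1) % 7, (i + 3) % 7))))
        tris.add(tuple(sorted((i % 7, (i + 2) % 7, (i + 3) % 7))))
    simps = {}
    for t in tris:
        for k in (1, 2, 3):
            for c in itertools.combinations(t, k):
                simps[c] = 0.0
    return FilteredComplex(list(simps.items()))


class TestFilteredComplex:
    def test_validation_catches_missing_face(self):
        with pytest.raises(ValueError, match="not closed"):
            FilteredComplex([((0,), 0.0), ((0, 1), 0.0)])

    def test_validation_catches_non_monotone(self):
        with pytest.raises(ValueError, match="monotone"):
            FilteredComplex([((0,), 1.0), ((1,), 0.0), ((0, 1), 0.5)])

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            FilteredComplex([((0,), 0.0), ((0,), 1.0)])

    def test_canonical_order_and_roundtrip(self, rng):
        cx = random_filtered_complex(rng, 6, 25)
        keys = [(e, len(s), s) for s, e in cx.simplices]
        assert keys == sorted(keys)
        again = FilteredComplex.from_frame(cx.to_frame())
        assert again.simplices == cx.simplices


class TestCoactivity:
    def test_same_window(self):
        trains = SpikeTrains((np.array([0.10]), np.array([0.20])), duration=0.5)
        sets = coactivity_sets(trains, CoactivityParams())
        assert sets[0] == (0.25, frozenset({0, 1}))

    def test_different_windows_never_joint(self):
        trains = SpikeTrains((np.array([0.10]), np.array([0.30])), duration=0.5)
        sets = coactivity_sets(trains, CoactivityParams())
        assert sets[0][1] == {0} and sets[1][1] == {1}

    def test_min_spikes_threshold(self):
        trains = SpikeTrains((np.array([0.1, 0.6, 1.1]),), duration=1.25)
        sets = coactivity_sets(trains, CoactivityParams(min_spikes=2))
        assert all(not s for _, s in sets)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            CoactivityParams(window=0.0)
        with pytest.raises(ValueError):
            CoactivityParams(min_spikes=0)


class TestTemporalComplex:
    def test_single_window_clique(self):
        trains = SpikeTrains(
            (np.array([0.05]), np.array([0.10]), np.array([0.20])), duration=0.25
        )
        cx = build_temporal_complex(trains, CoactivityParams())
        assert len(cx) == 7  # 3 vertices + 3 edges + 1 triangle
        assert all(e == 0.25 for _, e in cx.simplices)

    def test_filtration_valid_and_vertices_first(self, small_trains):
        cx = build_temporal_complex(small_trains, CoactivityParams())
        cx.validate()  # face closure + monotonicity
        for s, e in cx.simplices:
            if len(s) == 2:
                assert cx.entry_value((s[0],)) <= e
                assert cx.entry_value((s[1],)) <= e

    def test_max_dim_cap(self, small_trains):
        cx = build_temporal_complex(small_trains, CoactivityParams(max_dim=1))
        assert cx.dimension <= 1

    def test_higher_dimensional_simplices(self):
        trains = SpikeTrains(tuple(np.array([0.1]) for _ in range(5)), duration=0.25)
        cx = build_temporal_complex(trains, CoactivityParams(max_dim=4))
        assert len(cx.simplices_of_dim(4)) == 1


class TestNerve:
    @staticmethod
    def disk(cx, cy, r):
        return lambda x, y: (x - cx) ** 2 + (y - cy) ** 2 <= r**2

    def test_two_overlapping_disks(self):
        cx = build_nerve_complex([self.disk(0.8, 1.0, 0.3), self.disk(1.2, 1.0, 0.3)])
        assert len(cx.simplices_of_dim(0)) == 2
        assert len(cx.simplices_of_dim(1)) == 1

    def test_three_disks_common_point(self):
        r = [self.disk(1.0, 1.0, 0.3), self.disk(1.3, 1.0, 0.3), self.disk(1.15, 1.25, 0.3)]
        cx = build_nerve_complex(r)
        assert len(cx.simplices_of_dim(2)) == 1
        assert betti_numbers(cx, 1) == (1, 0)

    def test_annulus_of_disks(self):
        """Eight disks around a ring with no common centre coverage give a
        nerve with the annulus topology (1, 1), per the brute-force oracle."""
        angles = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        disks = [self.disk(1 + 0.6 * np.cos(a), 1 + 0.6 * np.sin(a), 0.28) for a in angles]
        cx = build_nerve_complex(disks)
        assert betti_numbers(cx, 1) == (1, 1)


class TestBoundaryAndBetti:
    def test_edge_column(self):
        cx = simplex_set([((0,), 0.0), ((1,), 0.0), ((2,), 0.0), ((0, 2), 0.0)])
        d1 = boundary_matrix(cx, 1)
        assert d1.shape == (3, 1)
        assert list(d1[:, 0]) == [1, 0, 1]

    def test_vertex_boundary_is_zero_map(self, rng):
        cx = random_filtered_complex(rng, 5, 10)
        d0 = boundary_matrix(cx, 0)
        assert d0.shape == (0, len(cx.simplices_of_dim(0)))

    @pytest.mark.parametrize("seed", range(10))
    def test_boundary_of_boundary_vanishes(self, seed):
        rng = np.random.default_rng(seed)
        cx = random_filtered_complex(rng, 7, 40)
        for k in range(1, cx.dimension + 1):
            prod = boundary_matrix(cx, k) @ boundary_matrix(cx, k + 1)
            assert not (prod % 2).any()

    def test_fixture_betti_numbers(self, torus):
        point = simplex_set([((0,), 0.0)])
        assert betti_numbers(point, 0) == (1,)
        circle = full_complex(range(3), 1)  # 3 vertices + 3 edges, hollow
        assert betti_numbers(circle, 1) == (1, 1)
        assert betti_numbers(torus, 2) == (1, 2, 1)
        sphere = FilteredComplex(
            [(c, 0.0) for k in (1, 2, 3) for c in itertools.combinations(range(4), k)]
        )
        assert betti_numbers(sphere, 2) == (1, 0, 1)


class TestPersistence:
    def test_two_components_merge(self):
        cx = FilteredComplex([((0,), 1.0), ((1,), 1.0), ((0, 1), 2.0)])
        bars = persistence(cx)
        assert sorted(bars.in_dim(0)) == [(1.0, 2.0), (1.0, math.inf)]
        assert bars.in_dim(1) == []

    def test_hollow_then_filled_triangle(self):
        pairs = [((v,), 1.0) for v in range(3)]
        pairs += [(e, 1.0) for e in ((0, 1), (0, 2), (1, 2))]
        pairs += [((0, 1, 2), 2.0)]
        bars = persistence(FilteredComplex(pairs))
        assert bars.in_dim(1) == [(1.0, 2.0)]

    def test_empty_complex(self):
        assert persistence(FilteredComplex([])).intervals == ()

    def test_zero_bars_recorded_and_suppressible(self):
        cx = full_complex(range(3), 1)  # everything enters at once
        bars = persistence(cx)
        assert any(b == d for _, b, d in bars.intervals)
        clean = bars.without_zero_bars()
        assert all(b < d for _, b, d in clean.intervals)
        assert clean.intervals == persistence(cx, suppress_zero=True).intervals

    def test_infinite_bars_count_final_betti(self, torus):
        bars = persistence(torus)
        assert (bars.n_infinite(0), bars.n_infinite(1), bars.n_infinite(2)) == (1, 2, 1)

    def test_betti_at_edges_of_filtration(self, rng):
        cx = random_filtered_complex(rng, 6, 30)
        bars = persistence(cx)
        assert betti_at(bars, -1.0, 3) == (0, 0, 0, 0)
        t_end = max(e for _, e in cx.simplices)
        assert betti_at(bars, t_end, 3) == betti_numbers(cx, 3)

    @pytest.mark.parametrize("seed", range(20))
    def test_barcode_matches_rank_nullity_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cx = random_filtered_complex(rng, 6, 34)
        bars = persistence(cx)
        for t in sorted({e for _, e in cx.simplices}):
            assert betti_at(bars, t, 3) == betti_numbers(cx.subcomplex_at(t), 3)

    @pytest.mark.parametrize("seed", range(10))
    def test_euler_characteristic_identity(self, seed):
        rng = np.random.default_rng(seed)
        cx = random_filtered_complex(rng, 7, 40)
        bars = persistence(cx)
        for t in sorted({e for _, e in cx.simplices}):
            sub = cx.subcomplex_at(t)
            chi_simplices = sum((-1) ** (len(s) - 1) for s, _ in sub)
            chi_betti = sum((-1) ** k * b for k, b in enumerate(betti_at(bars, t, 4)))
            assert chi_simplices == chi_betti

    def test_barcode_invariant_under_tie_permutation(self, rng):
        cx = random_filtered_complex(rng, 6, 30)
        # coarsen entries to force plenty of ties, then shuffle input order
        pairs = [(s, round(2 * e) / 2) for s, e in cx.simplices]
        fixed = []
        seen = {}
        for s, e in pairs:  # re-impose monotonicity after rounding
            e = max([e] + [seen[f] for f in itertools.combinations(s, len(s) - 1) if f in seen])
            seen[s] = e
            fixed.append((s, e))
        base = sorted(persistence(FilteredComplex(fixed)).intervals)
        for _ in range(3):
            perm = list(fixed)
            rng.shuffle(perm)
            assert sorted(persistence(FilteredComplex(perm)).intervals) == base

    def test_unsorted_or_open_input_rejected(self):
        with pytest.raises(ValueError):
            FilteredComplex([((0, 1), 0.0)])


class TestTemporalTrace:
    def test_matches_full_persistence(self, small_trains):
        """Dual route: the incremental (b0, b1) trace equals barcode Betti
        of the fully materialised temporal complex at every window end."""
        params = CoactivityParams()
        trace = temporal_betti_trace(small_trains, params)
        bars = persistence(build_temporal_complex(small_trains, params))
        for t, b0, b1 in trace[["time_s", "b0", "b1"]].to_numpy():
            assert betti_at(bars, t, 1) == (int(b0), int(b1))

    def test_empty_trains(self):
        trains = SpikeTrains((np.empty(0), np.empty(0)), duration=1.0)
        trace = temporal_betti_trace(trains, CoactivityParams())
        assert (trace[["b0", "b1"]].to_numpy() == 0).all()
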