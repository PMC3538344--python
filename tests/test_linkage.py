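"""Two-point estimation, Kosambi conversion, grouping and ordering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kendalltau

from conftest import simulate_marker_pair
from radmap.genotypes import GenotypeMatrix
from radmap.linkage import (
    LinkageError, PairwiseLinkage, estimate_rf_f2, grid_search_rf,
    group_markers, inverse_kosambi, kosambi_cm, map_summary, order_markers,
    pairwise_linkage_matrices, ripple, GeneticMap, LinkageGroupResult,
)


class TestKosambi:
    @pytest.mark.parametrize("r,expected", [
        (0.0, 0.0),
        (0.25, 25.0 * np.log(3.0)),      # 27.4653 cM
        (0.1, 25.0 * np.log(1.2 / 0.8)),
    ])
    def test_known_values(self, r, expected):
        assert kosambi_cm(r) == pytest.approx(expected, abs=1e-12)

    def test_round_trip(self):
        r = np.arange(0.01, 0.50, 0.01)
        assert np.allclose(inverse_kosambi(kosambi_cm(r)), r, atol=1e-12)

    def test_inverse_monotone_bounded(self):
        d = np.linspace(0.0, 5000.0, 200)
        r = inverse_kosambi(d)
        assert (np.diff(r) >= 0).all()
        assert r[0] == 0.0 and r[-1] <= 0.5 and r[-1] > 0.4999

    def test_boundary_errors(self):
        with pytest.raises(ValueError):
            kosambi_cm(0.5)
        assert kosambi_cm(0.5, max_cm=80.0) == 80.0
        with pytest.raises(ValueError):
            inverse_kosambi(-1.0)
        with pytest.raises(ValueError):
            kosambi_cm(-0.01)


class TestEstimateRf:
    def test_complete_linkage_homozygous_columns(self):
        # only a/b calls: every individual is fully informative, so the
        # complete-linkage LOD has the closed form 2 n log10(2)
        g = np.array([0] * 50 + [2] * 50, dtype=np.int8)
        pl = estimate_rf_f2(g, g)
        assert pl.r_hat == 0.0
        assert pl.lod == pytest.approx(200 * np.log10(2), rel=1e-9)

    def test_complete_linkage_with_heterozygotes(self):
        # the double-het class only supports log10(2) per individual at
        # r=0, giving 1.5 n log10(2) for an exact 1:2:1 column
        g = np.array([0] * 25 + [1] * 50 + [2] * 25, dtype=np.int8)
        pl = estimate_rf_f2(g, g)
        assert pl.r_hat == 0.0
        assert pl.lod == pytest.approx(150 * np.log10(2), rel=1e-9)

    def test_independent_markers_near_half(self):
        rng = np.random.default_rng(0)
        g1 = rng.choice(3, 5000, p=[0.25, 0.5, 0.25]).astype(np.int8)
        g2 = rng.choice(3, 5000, p=[0.25, 0.5, 0.25]).astype(np.int8)
        pl = estimate_rf_f2(g1, g2)
        se = np.sqrt(0.25 / 5000)   # binomial bound on r-hat at 0.5
        assert pl.r_hat >= 0.5 - 2 * 2 * se
        assert pl.lod < 3.0

    @pytest.mark.parametrize("collapse", [
        (None, None), ("not_a", None), ("not_a", "not_b"),
        ("not_a", "not_a"),
    ])
    def test_matches_grid_oracle(self, collapse):
        rng = np.random.default_rng(5)
        for _ in range(15):
            r = rng.uniform(0.0, 0.5)
            n = int(rng.integers(40, 200))
            g1, g2 = simulate_marker_pair(r, n, rng, collapse)
            if (len(set(g1.tolist())) < 2 or len(set(g2.tolist())) < 2):
                continue
            em = estimate_rf_f2(g1, g2)
            r_grid, lod_grid = grid_search_rf(g1, g2)
            assert abs(em.r_hat - r_grid) <= 0.001
            assert em.lod == pytest.approx(lod_grid, abs=0.01)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(2)
        g1, g2 = simulate_marker_pair(0.1, 150, rng)
        base = estimate_rf_f2(g1, g2)
        swapped = estimate_rf_f2(g2, g1)                 # marker order
        relab = estimate_rf_f2((2 - g1).astype(np.int8), g2)  # a<->b
        for other in (swapped, relab):
            assert other.r_hat == pytest.approx(base.r_hat, abs=1e-9)
            assert other.lod == pytest.approx(base.lod, abs=1e-6)

    def test_errors(self):
        mono = np.zeros(50, dtype=np.int8)
        seg = np.array([0, 1, 2] * 17, dtype=np.int8)[:50]
        with pytest.raises(LinkageError):
            estimate_rf_f2(mono, seg)
        missing = np.full(50, -1, dtype=np.int8)
        missing[0] = 0
        with pytest.raises(LinkageError):
            estimate_rf_f2(missing, seg)


class TestGrouping:
    def _pl(self, a, b, lod):
        return PairwiseLinkage(a, b, 0.1, lod, 100)

    def test_all_below_threshold_gives_singletons(self):
        links = [self._pl("a", "b", 2.0), self._pl("b", "c", 1.0)]
        groups = group_markers(links, 6.0)
        assert groups == [["a"], ["b"], ["c"]]

    def test_transitive_closure(self):
        links = [self._pl("a", "b", 8.0), self._pl("b", "c", 8.0),
                 self._pl("a", "c", 2.0)]
        assert group_markers(links, 6.0) == [["a", "b", "c"]]

    def test_input_order_invariance(self):
        rng = np.random.default_rng(3)
        ids = [f"m{i}" for i in range(12)]
        links = [self._pl(ids[i], ids[j], float(rng.uniform(0, 12)))
                 for i in range(12) for j in range(i + 1, 12)]
        base = group_markers(links, 6.0)
        rng.shuffle(links)
        assert group_markers(links, 6.0) == base


class TestOrdering:
    def _matrix_from_columns(self, cols, ids=None):
        codes = np.array(cols, dtype=np.int8)
        ids = ids or [f"M{i}" for i in range(len(cols))]
        return GenotypeMatrix(ids, [f"i{j}" for j in range(codes.shape[1])],
                              ["aaxbb"] * len(cols), codes)

    def _simulate_chain(self, positions, n, seed):
        """Markov-linked columns whose adjacent r follow the positions."""
        rng = np.random.default_rng(seed)
        r = inverse_kosambi(np.diff(np.asarray(positions, dtype=float)))
        m = len(positions)
        hap = []
        for _ in range(2):
            start = rng.random(n) < 0.5
            rec = rng.random((n, m - 1)) < r
            flips = np.concatenate([np.zeros((n, 1), dtype=int),
                                    np.cumsum(rec, axis=1)], axis=1) % 2
            hap.append(start[:, None].astype(int) ^ flips)
        return (hap[0] + hap[1]).astype(np.int8).T

    def test_three_marker_chain(self):
        cols = self._simulate_chain([0.0, 6.0, 12.0], 400, seed=1)
        res = order_markers(self._matrix_from_columns(list(cols)))
        assert res.marker_ids in (["M0", "M1", "M2"], ["M2", "M1", "M0"])

    def test_single_pair_positions(self):
        cols = self._simulate_chain([0.0, 10.0], 500, seed=2)
        mat = self._matrix_from_columns(list(cols))
        res = order_markers(mat)
        pl = estimate_rf_f2(cols[0], cols[1])
        assert res.positions[0] == 0.0
        assert res.positions[1] == pytest.approx(kosambi_cm(pl.r_hat),
                                                 abs=1e-6)

    def test_recovers_true_order(self):
        pos = np.linspace(0, 60, 15)
        cols = self._simulate_chain(pos, 343, seed=3)
        res = order_markers(self._matrix_from_columns(list(cols)))
        got = [int(m[1:]) for m in res.marker_ids]
        assert abs(kendalltau(got, range(15)).statistic) == 1.0
        assert res.unplaced == []

    def test_no_usable_pair_raises(self):
        rng = np.random.default_rng(4)
        cols = [rng.choice(3, 60, p=[0.25, 0.5, 0.25]).astype(np.int8)
                for _ in range(3)]
        with pytest.raises(LinkageError):
            order_markers(self._matrix_from_columns(cols))

    def test_ripple_repairs_adjacent_swap(self):
        pos = np.linspace(0, 40, 8)
        cols = self._simulate_chain(pos, 343, seed=5)
        mat = self._matrix_from_columns(list(cols))
        res = order_markers(mat)
        true_order = [int(m[1:]) for m in res.marker_ids]
        objective_calls = []

        def objective(order):
            # weighted misfit of adjacent distances as a simple objective
            idx = [mat.marker_index(m) for m in order]
            total = 0.0
            for a, b in zip(idx, idx[1:]):
                pl = estimate_rf_f2(mat.codes[a], mat.codes[b])
                total += pl.r_hat
            objective_calls.append(order)
            return total

        swapped = list(res.marker_ids)
        swapped[3], swapped[4] = swapped[4], swapped[3]
        repaired = ripple(swapped, window=3, objective=objective)
        assert repaired in (list(res.marker_ids), list(res.marker_ids)[::-1])

    def test_ripple_window_too_large_warns(self):
        with pytest.warns(UserWarning):
            out = ripple(["a", "b"], window=3, objective=lambda o: 0.0)
        assert out == ["a", "b"]


class TestMapSummary:
    def _map_from_positions(self, positions_per_group):
        groups = [
            LinkageGroupResult(f"LG{i+1}", [f"G{i}M{j}"
                                            for j in range(len(p))],
                               np.asarray(p, dtype=float))
            for i, p in enumerate(positions_per_group)
        ]
        return GeneticMap(groups)

    def test_single_group_arithmetic(self):
        s = map_summary(self._map_from_positions([[0.0, 10.0, 20.0]]))
        assert s.total_cm == 20.0
        assert s.mean_spacing_cm == 10.0
        assert s.max_gap_cm == 10.0
        assert s.n_cosegregating == 0

    def test_cosegregating_markers_counted(self):
        s = map_summary(self._map_from_positions(
            [[0.0, 0.0, 5.0], [0.0, 3.0, 3.0, 9.0]]))
        assert s.n_cosegregating == 2
        assert s.pct_cosegregating == pytest.approx(100 * 2 / 7)

    def test_empty_map_raises(self):
        with pytest.raises(ValueError):
            map_summary(GeneticMap([]))


class TestGroupingStatistics:
    def test_independence_option_available(self, small_clean_dataset):
        ds = small_clean_dataset
        mat = GenotypeMatrix(ds.f2.marker_ids, ds.f2.individual_ids,
                             ds.seg_types, ds.f2_true)
        _, grp_lnk, lod, _ = pairwise_linkage_matrices(mat, stat="linkage")
        _, grp_ind, _, _ = pairwise_linkage_matrices(mat,
                                                     stat="independence")
        assert np.array_equal(grp_lnk, lod)
        # both statistics separate the three simulated chromosomes
        for stat in (grp_lnk, grp_ind):
            parts = group_markers(stat, 6.0, marker_ids=mat.marker_ids)
            assert sum(1 for g in parts if len(g) > 1) == 3


@given(r=st.floats(min_value=0.0, max_value=0.49))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_kosambi_inverse_property(r):
    assert inverse_kosambi(kosambi_cm(r)) == pytest.approx(r, abs=1e-9)


def test_ordering_objective_invariant_under_reversal():
    from radmap.linkage import (_WlsOrderFitter, pairwise_distance_variance,
                                pairwise_linkage_matrices)
    rng = np.random.default_rng(11)
    from conftest import simulate_marker_pair
    # correlated chain of 8 markers
    n, m = 200, 8
    gm, gp = rng.random(n) < 0.5, rng.random(n) < 0.5
    cols = [(gm.astype(np.int8) + gp.astype(np.int8))]
    for _ in range(m - 1):
        gm = gm ^ (rng.random(n) < 0.05)
        gp = gp ^ (rng.random(n) < 0.05)
        cols.append((gm.astype(np.int8) + gp.astype(np.int8)))
    mat = GenotypeMatrix([f"M{i}" for i in range(m)],
                         [f"i{j}" for j in range(n)], ["aaxbb"] * m,
                         np.array(cols))
    r, _, lod, _ = pairwise_linkage_matrices(mat)
    var = pairwise_distance_variance(mat.codes, r)
    usable = (r <= 0.4) & (lod >= 1.0)
    np.fill_diagonal(usable, False)
    dist = np.zeros_like(r)
    dist[usable] = kosambi_cm(np.minimum(r[usable], 0.499))
    fitter = _WlsOrderFitter(dist, np.where(usable, 1 / var, 0), usable)
    order = np.arange(m)
    assert fitter.objective(order) == pytest.approx(
        fitter.objective(order[::-1]), rel=1e-9)
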