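"""Synthetic pedigree generator: truth consistency and distributions."""

import numpy as np
import pytest
from scipy import stats

from radmap.genotypes import A, B, H, MISSING, NOT_A, NOT_B
from radmap.linkage import estimate_rf_f2, inverse_kosambi
from radmap.qc import chi_square_1_2_1
from radmap.sim import (
    SelectionBlock, SimConfig, TrueGroup, TrueMap, apply_viability_selection,
    build_mutation_survey, build_true_map, inject_de_novo_mutations,
    simulate_dataset, simulate_depths_and_missingness, simulate_f2,
    simulate_parents,
)


class TestConfigAndTrueMap:
    def test_defaults_emulate_study_scale(self):
        cfg = SimConfig()
        tm = build_true_map(cfg)
        assert tm.n_markers == 755
        assert len(tm.groups) == 25
        assert tm.total_cm == pytest.approx(1427, abs=2)

    def test_two_marker_group_even_placement(self):
        cfg = SimConfig(n_groups=1, markers_per_group=[2],
                        group_lengths_cm=[10.0], distortion_blocks=[],
                        marker_placement="even", seed=0)
        tm = build_true_map(cfg)
        assert np.allclose(tm.groups[0].positions_cm, [0.0, 10.0])
        assert tm.groups[0].rec_fractions[0] == pytest.approx(
            inverse_kosambi(10.0))

    def test_zero_interval_gives_zero_r(self):
        assert inverse_kosambi(0.0) == 0.0

    @pytest.mark.parametrize("bad", [
        dict(n_f2=0), dict(missing_rate=1.5), dict(mean_depth=0.0),
        dict(group_lengths_cm=[-1.0], n_groups=1, markers_per_group=[5],
             distortion_blocks=[]),
        dict(markers_per_group=[1], n_groups=1, group_lengths_cm=[10.0],
             distortion_blocks=[]),
        dict(distortion_blocks=[SelectionBlock(1, 0, 5, "het_advantage",
                                               1.5)]),
        dict(seg_type_weights={"abxab": 0.5}),
    ])
    def test_invalid_configs_raise(self, bad):
        with pytest.raises(ValueError):
            SimConfig(**bad)


class TestParents:
    @pytest.mark.parametrize("frac,check", [
        (1.0, lambda t: (t == "aaxbb").all()),
        (0.0, lambda t: not (t == "aaxbb").any()),
    ])
    def test_fixed_fraction_boundaries(self, frac, check):
        cfg = SimConfig(n_groups=2, markers_per_group=[50, 50],
                        group_lengths_cm=[60.0, 60.0],
                        fixed_diff_fraction=frac, distortion_blocks=[],
                        seed=1)
        types = simulate_parents(cfg, np.random.default_rng(1))
        assert check(types)

    def test_fixed_fraction_binomial_band(self):
        n = 10_000
        cfg = SimConfig(n_groups=1, markers_per_group=[n],
                        group_lengths_cm=[60.0], fixed_diff_fraction=0.185,
                        distortion_blocks=[], seed=2)
        types = simulate_parents(cfg, np.random.default_rng(2))
        k = int((types == "aaxbb").sum())
        lo, hi = stats.binom.interval(0.999, n, 0.185)
        assert lo <= k <= hi


class TestF2Genotypes:
    def test_coincident_markers_have_identical_columns(self):
        tm = TrueMap([TrueGroup(1, ["m1", "m2"],
                                np.array([0.0, 1e-12]),
                                np.array([inverse_kosambi(1e-12)]))])
        cfg = SimConfig(n_groups=1, markers_per_group=[2],
                        group_lengths_cm=[1.0], n_f2=300,
                        distortion_blocks=[], seed=3)
        mat = simulate_f2(cfg, tm, np.array(["aaxbb", "aaxbb"]),
                          np.random.default_rng(3))
        assert np.array_equal(mat.codes[0], mat.codes[1])

    def test_unlinked_groups_segregate_independently(self):
        cfg = SimConfig(n_groups=2, markers_per_group=[2, 2],
                        group_lengths_cm=[1.0, 1.0], n_f2=5000,
                        fixed_diff_fraction=1.0, distortion_blocks=[],
                        marker_placement="even", seed=4)
        tm = build_true_map(cfg)
        mat = simulate_f2(cfg, tm, simulate_parents(
            cfg, np.random.default_rng(4)), np.random.default_rng(5))
        pl = estimate_rf_f2(mat.codes[0], mat.codes[2])
        se = np.sqrt(0.25 / 5000)
        assert pl.r_hat >= 0.5 - 4 * se

    def test_mendelian_1_2_1_at_large_n(self):
        cfg = SimConfig(n_groups=1, markers_per_group=[2],
                        group_lengths_cm=[50.0], n_f2=10_000,
                        fixed_diff_fraction=1.0, distortion_blocks=[],
                        marker_placement="even", seed=6)
        tm = build_true_map(cfg)
        mat = simulate_f2(cfg, tm, simulate_parents(
            cfg, np.random.default_rng(6)), np.random.default_rng(7))
        counts = [(mat.codes[0] == g).sum() for g in (A, H, B)]
        _, p = chi_square_1_2_1(counts)
        assert p > 0.05 / 10   # chi-square acceptance at alpha ~ 5e-3

    def test_clean_simulation_passes_segregation_tests(self):
        # zero error / missingness / selection: nearly every marker of
        # 1000 passes the 1:2:1 test at alpha = 0.001
        cfg = SimConfig(n_groups=4, markers_per_group=[250] * 4,
                        group_lengths_cm=[60.0] * 4, n_f2=343,
                        fixed_diff_fraction=1.0, missing_rate=0.0,
                        genotyping_error_rate=0.0, distortion_blocks=[],
                        seed=8)
        ds = simulate_dataset(cfg)
        counts = ds.f2.genotype_counts()
        pvals = np.array([chi_square_1_2_1(c)[1] for c in counts])
        assert (pvals >= 0.001).sum() >= 990

    def test_observed_codes_match_segregation_type(self, messy_dataset):
        f2 = messy_dataset.f2
        for i, seg in enumerate(f2.seg_types):
            observed = set(f2.codes[i].tolist()) - {MISSING}
            if seg == "aaxab":
                assert observed <= {A, NOT_A}
            elif seg == "abxaa":
                assert observed <= {B, NOT_B}
            else:
                assert observed <= {A, H, B}


class TestDepthsAndMissingness:
    def _true_matrix(self, n_markers=40, n_f2=100, seed=9):
        cfg = SimConfig(n_groups=1, markers_per_group=[n_markers],
                        group_lengths_cm=[60.0], n_f2=n_f2,
                        fixed_diff_fraction=1.0, distortion_blocks=[],
                        seed=seed)
        tm = build_true_map(cfg)
        rng = np.random.default_rng(seed)
        return cfg, simulate_f2(cfg, tm, simulate_parents(cfg, rng), rng)

    def test_zero_missing_rate(self):
        cfg, mat = self._true_matrix()
        cfg = SimConfig(**{**cfg.__dict__, "missing_rate": 0.0})
        out = simulate_depths_and_missingness(mat, cfg,
                                              np.random.default_rng(1))
        assert not (out.codes == MISSING).any()

    def test_depth_mean_and_missing_fraction(self):
        cfg, mat = self._true_matrix(n_markers=1000, n_f2=100)
        out = simulate_depths_and_missingness(mat, cfg,
                                              np.random.default_rng(2))
        n_calls = mat.codes.size
        miss = (out.codes == MISSING).mean()
        se_miss = np.sqrt(0.25 * 0.75 / n_calls)
        assert abs(miss - 0.25) < 4 * se_miss
        depth = out.total_depth[out.codes != MISSING]
        se_mean = depth.std() / np.sqrt(len(depth))
        assert abs(depth.mean() - 15.0) < 4 * se_mean
        # dispersion matches the configured negative binomial (SD ~ 5.1)
        assert 4.8 < depth.std() < 5.4

    def test_het_calls_get_both_alleles(self):
        cfg, mat = self._true_matrix()
        out = simulate_depths_and_missingness(mat, cfg,
                                              np.random.default_rng(3))
        het = out.codes == H
        assert (out.depth_a[het] + out.depth_b[het] ==
                out.total_depth[het]).all()
        hom_a = out.codes == A
        assert (out.depth_b[hom_a] == 0).all()


class TestMutations:
    def test_zero_rate_empty_truth(self):
        cfg = SimConfig(n_groups=1, markers_per_group=[4],
                        group_lengths_cm=[10.0], n_f2=20, mutation_rate=0.0,
                        distortion_blocks=[], seed=10)
        ds = simulate_dataset(cfg)
        assert len(ds.mutations) == 0

    def test_injected_count_poisson_band(self):
        u, n_loci, length = 1e-5, 2000, 100
        cfg = SimConfig(n_groups=1, markers_per_group=[4],
                        group_lengths_cm=[10.0], n_f2=100, mutation_rate=u,
                        n_loci_total=n_loci, locus_length_bp=length,
                        distortion_blocks=[], seed=11)
        ds = simulate_dataset(cfg)
        lam = 2 * n_loci * length * u * (100 + 2)   # F2 cohort plus two F1s
        lo, hi = stats.poisson.interval(0.999, lam)
        assert lo <= len(ds.mutations) <= hi

    def test_survey_materialises_mutations(self):
        cfg = SimConfig(n_groups=1, markers_per_group=[10],
                        group_lengths_cm=[50.0], n_f2=10, mutation_rate=1e-4,
                        n_loci_total=500, locus_length_bp=100,
                        missing_rate=0.0, genotyping_error_rate=0.0,
                        fixed_diff_fraction=1.0, distortion_blocks=[],
                        mean_depth=30.0, seed=12)
        ds = simulate_dataset(cfg)
        survey = build_mutation_survey(ds, np.random.default_rng(0),
                                       n_f2_sampled=10)
        truth = ds.mutations
        surveyed = set(survey.individuals)
        expected = truth[truth.individual.isin(surveyed)]
        # nearly all mutations of surveyed individuals appear as calls
        assert len(survey.calls) >= 0.8 * len(expected)
        assert set(survey.calls.alleleB) <= {"C", "G", "T"}


class TestSelection:
    def _selected_dataset(self, mode, s, n=20_000, seed=13):
        blk = SelectionBlock(1, 20.0, 40.0, mode, s)
        cfg = SimConfig(n_groups=1, markers_per_group=[3],
                        group_lengths_cm=[60.0], n_f2=n,
                        fixed_diff_fraction=1.0, missing_rate=0.0,
                        genotyping_error_rate=0.0, marker_placement="even",
                        distortion_blocks=[blk], seed=seed)
        return blk, simulate_dataset(cfg)

    def test_against_maternal_expected_ratios(self):
        # survivors at the causal locus follow 1-s : 2(1-s/2) : 1
        blk, ds = self._selected_dataset("against_maternal", 0.5)
        geno = ds.latent_genotypes[(1, blk.causal_cm)]
        counts = np.array([(geno == g).sum() for g in (0, 1, 2)])
        w = np.array([0.5, 2 * 0.75, 1.0])
        expected = w / w.sum() * counts.sum()
        assert stats.chisquare(counts, f_exp=expected).pvalue > 1e-3
        assert counts[2] > counts[0]          # paternal-homozygote excess

    def test_het_advantage_gives_het_excess(self):
        blk, ds = self._selected_dataset("het_advantage", 0.5)
        geno = ds.latent_genotypes[(1, blk.causal_cm)]
        counts = np.array([(geno == g).sum() for g in (0, 1, 2)])
        w = np.array([0.5, 2.0, 0.5])
        expected = w / w.sum() * counts.sum()
        assert stats.chisquare(counts, f_exp=expected).pvalue > 1e-3
        assert counts[1] > counts[0] + counts[2]

    def test_zero_selection_keeps_mendelian_ratios(self):
        blk, ds = self._selected_dataset("against_maternal", 0.0, n=10_000)
        geno = ds.latent_genotypes[(1, blk.causal_cm)]
        counts = [(geno == g).sum() for g in (0, 1, 2)]
        assert chi_square_1_2_1(counts)[1] > 1e-3

    def test_apply_selection_returns_survivor_subset(self):
        blk, ds = self._selected_dataset("against_maternal", 0.0, n=500)
        cfg = SimConfig(**{**ds.config.__dict__, "distortion_blocks":
                           [SelectionBlock(1, 20.0, 40.0,
                                           "against_maternal", 0.8)]})
        out = apply_viability_selection(ds, cfg, np.random.default_rng(1))
        assert 0 < out.f2.n_individuals < ds.f2.n_individuals
        kept = set(out.f2.individual_ids)
        assert kept <= set(ds.f2.individual_ids)

    def test_distortion_monotone_in_selection_coefficient(self):
        # stronger selection => larger median distortion chi-square
        medians = []
        for s in (0.0, 0.3, 0.6):
            chis = []
            for seed in range(3):
                blk, ds = self._selected_dataset("against_maternal", s,
                                                 n=343, seed=40 + seed)
                counts = ds.f2.genotype_counts()
                chis.extend(chi_square_1_2_1(c)[0] for c in counts)
            medians.append(np.median(chis))
        assert medians[0] <= medians[1] <= medians[2]


class TestDeterminism:
    def test_identical_datasets_from_same_seed(self):
        cfg_kwargs = dict(n_groups=2, markers_per_group=[6, 6],
                          group_lengths_cm=[30.0, 30.0], n_f2=50,
                          mutation_rate=1e-6, seed=99,
                          distortion_blocks=[SelectionBlock(
                              1, 5.0, 15.0, "against_paternal", 0.4)])
        a = simulate_dataset(SimConfig(**cfg_kwargs))
        b = simulate_dataset(SimConfig(**cfg_kwargs))
        assert a.f2 == b.f2
        assert a.mutations.equals(b.mutations)
        assert all(np.array_equal(x.positions_cm, y.positions_cm)
                   for x, y in zip(a.true_map.groups, b.true_map.groups))

    def test_seed_changes_output(self):
        base = dict(n_groups=1, markers_per_group=[6],
                    group_lengths_cm=[30.0], n_f2=50, distortion_blocks=[])
        a = simulate_dataset(SimConfig(**base, seed=1))
        b = simulate_dataset(SimConfig(**base, seed=2))
        assert not np.array_equal(a.f2.codes, b.f2.codes)


class TestSuppliedPositions:
    def test_supplied_positions_used_verbatim(self):
        cfg = SimConfig(n_groups=1, markers_per_group=[3],
                        group_lengths_cm=[20.0], distortion_blocks=[],
                        seed=0)
        tm = build_true_map(cfg, positions_cm=[[0.0, 4.0, 20.0]])
        assert np.allclose(tm.groups[0].positions_cm, [0.0, 4.0, 20.0])
        assert np.allclose(tm.groups[0].rec_fractions,
                           inverse_kosambi(np.array([4.0, 16.0])))

    def test_non_increasing_positions_rejected(self):
        cfg = SimConfig(n_groups=1, markers_per_group=[3],
                        group_lengths_cm=[20.0], distortion_blocks=[],
                        seed=0)
        with pytest.raises(ValueError):
            build_true_map(cfg, positions_cm=[[0.0, 5.0, 5.0]])
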