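"""Parameter-recovery studies run against the synthetic-pedigree generator.

Each study simulates data with known truth under fixed, documented
conditions, runs the corresponding pipeline stage, and reports how well
the truth is recovered.  They serve both as validation experiments and as
reproducible benchmarks; conditions (cohort size, marker density, rates)
follow the emulated cross unless a study needs desk-scale counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .distortion import find_distortion_blocks
from .genotypes import GenotypeMatrix
from .linkage import (
    GeneticMap, LinkageGroupResult, _order_group, estimate_rf_f2,
    grid_search_rf, group_markers, pairwise_distance_variance,
    pairwise_linkage_matrices,
)
from .murate import MutationRateModel, het_depth_pairs_from_matrix
from .qc import marker_qc
from .sim import (
    SelectionBlock, SimConfig, build_mutation_survey, simulate_dataset,
)


def _clean_config(n_groups: int, markers_per_group: int, n_f2: int,
                  length_cm: float, seed: int, **overrides) -> SimConfig:
    """Error-free, fully codominant, complete-data simulation settings."""
    base = dict(
        n_groups=n_groups,
        markers_per_group=[markers_per_group] * n_groups,
        group_lengths_cm=[length_cm] * n_groups,
        n_f2=n_f2, fixed_diff_fraction=1.0, missing_rate=0.0,
        genotyping_error_rate=0.0, mutation_rate=0.0,
        distortion_blocks=[], marker_placement="even", seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


def em_grid_agreement(n_tables: int = 500, seed: int = 0,
                      grid_step: float = 0.001) -> dict:
    """EM recombination fractions vs a brute-force likelihood grid.

    Random joint-count tables are produced by simulating marker pairs with
    recombination fractions uniform on [0, 0.5] and 50-200 individuals;
    reports the largest |r_EM - r_grid| over all tables.
    """
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_tables):
        r = rng.uniform(0.0, 0.5)
        n = int(rng.integers(50, 201))
        gm, gp = rng.random(n) < 0.5, rng.random(n) < 0.5
        rec_m, rec_p = rng.random(n) < r, rng.random(n) < r
        g1 = (gm.astype(np.int8) + gp.astype(np.int8))
        g2 = ((gm ^ rec_m).astype(np.int8) + (gp ^ rec_p).astype(np.int8))
        if len(set(g1.tolist())) < 2 or len(set(g2.tolist())) < 2:
            continue
        em = estimate_rf_f2(g1, g2)
        grid_r, _ = grid_search_rf(g1, g2, step=grid_step)
        max_diff = max(max_diff, abs(em.r_hat - grid_r))
    return {"max_abs_diff": max_diff, "n_tables": n_tables}


def map_recovery_study(n_seeds: int = 20, n_groups: int = 24,
                       markers_per_group: int = 30, n_f2: int = 343,
                       length_cm: float = 60.0, base_seed: int = 0
                       ) -> pd.DataFrame:
    """Grouping, ordering and map-length recovery on clean simulations.

    Per seed: simulate the cross, group all markers at LOD 6 and LOD 10,
    order every group, and compare against the simulated truth.  Columns:
    ``n_groups_lod6``, ``n_groups_lod10``, ``min_abs_tau`` (worst
    per-group Kendall tau between estimated and true order),
    ``total_cm``, ``true_cm``, ``length_err_pct``.
    """
    rows = []
    for s in range(n_seeds):
        cfg = _clean_config(n_groups, markers_per_group, n_f2, length_cm,
                            seed=base_seed + 1000 + s)
        ds = simulate_dataset(cfg)
        mat = GenotypeMatrix(ds.f2.marker_ids, ds.f2.individual_ids,
                             ds.seg_types, ds.f2_true)
        r, lod, _, _ = pairwise_linkage_matrices(mat)
        parts6 = group_markers(lod, 6.0, marker_ids=mat.marker_ids)
        parts10 = group_markers(lod, 10.0, marker_ids=mat.marker_ids)
        n6 = sum(1 for g in parts6 if len(g) > 1)
        n10 = sum(1 for g in parts10 if len(g) > 1)
        id_to_idx = {m: i for i, m in enumerate(mat.marker_ids)}
        true_rank = {m: j for tg in ds.true_map.groups
                     for j, m in enumerate(tg.marker_ids)}
        taus, total = [], 0.0
        var_full = np.full_like(r, np.inf)
        for members in (g for g in parts6 if len(g) > 1):
            idx = np.array([id_to_idx[m] for m in members])
            var_full[np.ix_(idx, idx)] = pairwise_distance_variance(
                mat.codes[idx], r[np.ix_(idx, idx)])
            res = _order_group(idx, mat.marker_ids, r, lod, var_full,
                               max_rf=0.400, min_lod=1.0,
                               jump_threshold=5.00, ripple_window=3,
                               group_id="g")
            got = [true_rank[m] for m in res.marker_ids]
            tau = kendalltau(got, np.arange(len(got))).statistic
            taus.append(abs(tau))
            total += res.length_cm
        rows.append((n6, n10, min(taus) if taus else np.nan, total,
                     ds.true_map.total_cm,
                     100.0 * (total - ds.true_map.total_cm)
                     / ds.true_map.total_cm))
    return pd.DataFrame(rows, columns=[
        "n_groups_lod6", "n_groups_lod10", "min_abs_tau", "total_cm",
        "true_cm", "length_err_pct"])


def mutation_recovery_study(n_seeds: int = 20, n_individuals: int = 50,
                            n_sites: int = 1_000_000, rate: float = 5e-7,
                            base_seed: int = 0) -> pd.DataFrame:
    """End-to-end mutation-rate recovery at a desk-scale inflated rate.

    The full detect/filter/deduplicate/estimate path runs on an
    error-free survey of ``n_individuals`` F2 offspring over ``n_sites``
    sites per individual (loci of 100 bp).  Surveyed individuals are
    sequenced deep (mean 30x), as a pedigree mutation study targets
    high-coverage samples; the surveyed-site denominator is the callable
    sites (locus depth >= coverage minimum), matching the locus-inclusion
    rule of the estimator.  Columns: per-seed estimate, injected truth
    count, and the 2-Poisson-SE band around the true rate.
    """
    n_loci = n_sites // 100
    rows = []
    for s in range(n_seeds):
        cfg = _clean_config(2, 10, n_individuals, 60.0,
                            seed=base_seed + 2000 + s,
                            mutation_rate=rate, locus_length_bp=100,
                            n_loci_total=n_loci, mean_depth=30.0)
        ds = simulate_dataset(cfg)
        rng = np.random.default_rng(cfg.seed + 1)
        survey = build_mutation_survey(ds, rng, n_f2_sampled=n_individuals)
        callable_sites = survey.callable_sites(min_total=8)
        f2_rows = [i for i, g in enumerate(survey.generations) if g == "F2"]
        sites = float(np.mean(callable_sites[f2_rows]))
        model = MutationRateModel(
            survey.calls[survey.calls.generation == "F2"],
            survey.parental_alleles,
            het_depth_pairs_from_matrix(ds.f2),
            n_sites=sites, n_individuals={"F2": n_individuals})
        est = model.fit().estimates["F2"]
        true_n = int((ds.mutations.generation == "F2").sum())
        se2 = 2.0 * np.sqrt(rate / (2.0 * n_individuals * sites))
        rows.append((est.rate, est.n_mutations, true_n, rate - se2,
                     rate + se2))
    return pd.DataFrame(rows, columns=[
        "rate_hat", "n_retained", "n_injected", "band_lo", "band_hi"])


def _true_order_map(ds) -> GeneticMap:
    groups = [LinkageGroupResult(f"LG{tg.group}", list(tg.marker_ids),
                                 tg.positions_cm - tg.positions_cm[0])
              for tg in ds.true_map.groups]
    return GeneticMap(groups)


def distortion_power_study(n_seeds: int = 50, n_f2: int = 343,
                           markers: int = 30, length_cm: float = 60.0,
                           s: float = 0.5, base_seed: int = 0
                           ) -> pd.DataFrame:
    """Power to flag a viability-selected locus as a distortion block.

    One group of ``markers`` markers with a single selected causal locus
    at its centre; per seed, blocks are scanned along the true marker
    order at the default thresholds and a hit is a block whose span covers
    the causal position.
    """
    causal = length_cm / 2.0
    rows = []
    for sd in range(n_seeds):
        cfg = _clean_config(
            1, markers, n_f2, length_cm, seed=base_seed + 3000 + sd,
            distortion_blocks=[SelectionBlock(1, causal - 5, causal + 5,
                                              "against_maternal", s)])
        ds = simulate_dataset(cfg)
        qc = marker_qc(ds.f2)
        blocks = find_distortion_blocks(_true_order_map(ds), qc)
        hit = any(b.start_cm <= causal <= b.end_cm for b in blocks)
        rows.append((hit, len(blocks)))
    return pd.DataFrame(rows, columns=["detected", "n_blocks"])


def distortion_fpr_study(n_seeds: int = 100, groups_per_seed: int = 5,
                         n_f2: int = 343, markers: int = 30,
                         spacing_cm: float = 50.0, base_seed: int = 0
                         ) -> pd.DataFrame:
    """Fraction of distortion-free groups yielding a (false) block.

    The default wide spacing (50 cM, r ~ 0.38) makes neighbouring
    segregation tests approximately independent, so the result is the
    false-alarm rate intrinsic to the run rule.  At dense map spacing the
    tests are strongly correlated and chance dips cluster into runs, so
    the group-level rate rises steeply with density (pass a small
    ``spacing_cm`` to measure that regime).
    """
    length_cm = spacing_cm * (markers - 1)
    rows = []
    for sd in range(n_seeds):
        cfg = _clean_config(groups_per_seed, markers, n_f2, length_cm,
                            seed=base_seed + 4000 + sd)
        ds = simulate_dataset(cfg)
        qc = marker_qc(ds.f2)
        blocks = find_distortion_blocks(_true_order_map(ds), qc)
        with_block = {b.group_id for b in blocks}
        rows.append((groups_per_seed, len(with_block)))
    df = pd.DataFrame(rows, columns=["n_groups", "n_groups_with_block"])
    return df
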