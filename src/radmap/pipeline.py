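"""End-to-end orchestration: QC -> linkage map -> distortion (-> synteny,
mutation rate), with a run manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .distortion import find_distortion_blocks
from .genotypes import GenotypeMatrix
from .linkage import LinkageMapModel, LinkageMapResults
from .murate import MutationRateModel, het_depth_pairs_from_matrix
from .qc import marker_qc, filter_individuals, filter_markers, \
    select_mapping_markers
from .synteny import (
    conserved_synteny_percent, oxford_grid, parse_hits, resolve_multi_hits,
)

log = logging.getLogger("radmap")


@dataclass
class PipelineConfig:
    """All stage thresholds, at their standard defaults, plus the seed."""

    min_individuals: int = 90          # marker presence floor
    min_call_depth: int = 5            # per-call depth floor
    min_individual_mean_depth: float = 6.0
    alpha_clean: float = 0.05
    alpha_floor: float = 0.001
    alpha_exclude: float = 0.0001
    grouping_lod: float = 6.0
    grouping_stat: str = "linkage"
    max_rf: float = 0.400
    ordering_min_lod: float = 1.0
    jump_threshold: float = 5.00
    ripple_window: int = 3
    distortion_alpha: float = 0.05
    distortion_min_run: int = 3
    distortion_max_skip: int = 1
    e_value_cutoff: float = 1e-15
    min_bit_gap: float = 20.0
    mutation_min_total: int = 8
    mutation_min_per_allele: int = 4
    ratio_bounds: tuple[float, float] = (0.5, 2.0)
    ci_level: float = 0.95
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    qc_report: pd.DataFrame
    selection_plan: pd.DataFrame
    map_results: LinkageMapResults
    distortion_blocks: list
    synteny: object | None = None
    oxford: pd.DataFrame | None = None
    murate: object | None = None
    manifest: dict = field(default_factory=dict)


def _qc_frame(qc_list, plan) -> pd.DataFrame:
    df = pd.DataFrame([{
        "marker_id": m.marker_id, "seg_type": m.segregation_type,
        "n_genotyped": m.n_genotyped, "n_a": m.genotype_counts[0],
        "n_h": m.genotype_counts[1], "n_b": m.genotype_counts[2],
        "chi_square": (round(m.chi_square, 4)
                       if np.isfinite(m.chi_square) else ""),
        "p_value": m.p_value,
    } for m in qc_list])
    return df.merge(plan[["marker_id", "tier", "addition_order"]],
                    on="marker_id", how="left")


def run_pipeline(matrix: GenotypeMatrix, config: PipelineConfig,
                 outdir: str | Path | None = None, *,
                 synteny_hits=None, reference_lengths: dict | None = None,
                 linked_reference_ids: set | None = None,
                 murate_calls: pd.DataFrame | None = None,
                 murate_parents: pd.DataFrame | None = None,
                 murate_n_sites: float | None = None,
                 murate_n_individuals: dict | None = None
                 ) -> PipelineResult:
    """Run QC, mapping and distortion scanning; optional synteny and
    mutation-rate stages run only when their inputs are supplied.

    Writes TSV reports and a JSON manifest under ``outdir`` when given.
    """
    log.info("qc: %d markers x %d individuals in", matrix.n_markers,
             matrix.n_individuals)
    filtered, ind_report = filter_individuals(
        matrix, config.min_individual_mean_depth)
    filtered, marker_report = filter_markers(
        filtered, config.min_individuals, config.min_call_depth)
    qc_list = marker_qc(filtered)
    plan = select_mapping_markers(qc_list, config.alpha_clean,
                                  config.alpha_floor, config.alpha_exclude)
    keep = plan.loc[plan.addition_order >= 0, "marker_id"]
    mapping = filtered.take_markers(
        [filtered.marker_index(m) for m in keep])
    log.info("qc: %d individuals, %d markers retained for mapping",
             mapping.n_individuals, mapping.n_markers)

    model = LinkageMapModel(
        mapping, grouping_lod=config.grouping_lod,
        grouping_stat=config.grouping_stat, max_rf=config.max_rf,
        min_lod=config.ordering_min_lod,
        jump_threshold=config.jump_threshold,
        ripple_window=config.ripple_window)
    map_results = model.fit()
    log.info("map: %d groups, %d markers, %.1f cM",
             map_results.map.n_groups, map_results.map.n_markers,
             map_results.map.total_cm)

    # paternal-allele origin: for fixed-difference markers the b allele is
    # the sire's by the generator/file convention (parent1 = dam)
    origin = {m.marker_id: "b" for m in qc_list
              if m.segregation_type == "aaxbb"}
    blocks = find_distortion_blocks(
        map_results.map, qc_list, alpha=config.distortion_alpha,
        min_run=config.distortion_min_run,
        max_skip=config.distortion_max_skip, parental_origin=origin)
    log.info("distortion: %d block(s)", len(blocks))

    syn = grid = None
    if synteny_hits is not None:
        hits = (parse_hits(synteny_hits, config.e_value_cutoff)
                if isinstance(synteny_hits, (str, Path)) else synteny_hits)
        assigned, excl = resolve_multi_hits(
            hits, config.min_bit_gap, linked_reference_ids)
        syn = conserved_synteny_percent(assigned, map_results.map, excl)
        if reference_lengths:
            grid = oxford_grid(map_results.map, assigned, reference_lengths)
        log.info("synteny: %.1f%% conserved (%d/%d)", syn.conserved_percent,
                 syn.n_on_modal, syn.n_qualifying)
    else:
        log.info("synteny: no alignment hits supplied; stage skipped")

    mur = None
    if murate_calls is not None and murate_parents is not None:
        mur = MutationRateModel(
            murate_calls, murate_parents,
            het_depth_pairs_from_matrix(filtered),
            n_sites=murate_n_sites,
            n_individuals=murate_n_individuals or {"F2": 1},
            min_total=config.mutation_min_total,
            min_per_allele=config.mutation_min_per_allele,
            ratio_bounds=config.ratio_bounds,
            ci_level=config.ci_level).fit()
        log.info("murate: mean rate %.3g", mur.mean_rate)
    else:
        log.info("murate: no survey supplied; stage skipped")

    manifest = {
        "config": asdict(config), "config_digest": config.digest(),
        "seed": config.seed, "radmap_version": __version__,
        "n_markers_in": int(matrix.n_markers),
        "n_individuals_in": int(matrix.n_individuals),
        "n_markers_mapped": int(map_results.map.n_markers),
        "n_groups": int(map_results.map.n_groups),
        "total_cm": round(map_results.map.total_cm, 2),
        "n_distortion_blocks": len(blocks),
    }
    result = PipelineResult(config, _qc_frame(qc_list, plan), plan,
                            map_results, blocks, syn, grid, mur, manifest)
    if outdir is not None:
        _write_outputs(result, ind_report, marker_report, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, ind_report, marker_report,
                   outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    ind_report.to_csv(outdir / "individual_filter.tsv", sep="\t",
                      index=False)
    marker_report.to_csv(outdir / "marker_filter.tsv", sep="\t", index=False)
    result.qc_report.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    result.map_results.to_frame().to_csv(outdir / "map.tsv", sep="\t",
                                         index=False, float_format="%.2f")
    result.map_results.pairwise_frame().to_csv(
        outdir / "pairwise_linkage.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "group": b.group_id, "start_marker": b.marker_ids[0],
        "end_marker": b.marker_ids[-1], "span_cM": round(b.span_cm, 2),
        "n_markers": b.n_markers, "direction": b.direction,
        "whole_group": b.whole_group,
    } for b in result.distortion_blocks]).to_csv(
        outdir / "distortion_blocks.tsv", sep="\t", index=False)
    if result.synteny is not None:
        result.synteny.assignments.to_csv(outdir / "synteny_assignments.tsv",
                                          sep="\t", index=False)
        result.synteny.per_group.to_csv(outdir / "synteny_groups.tsv",
                                        sep="\t", index=False)
    if result.oxford is not None:
        result.oxford.to_csv(outdir / "oxford_grid.tsv", sep="\t",
                             index=False)
    if result.murate is not None:
        result.murate.candidate_frame().to_csv(
            outdir / "mutation_candidates.tsv", sep="\t", index=False)
        (outdir / "mutation_rate.txt").write_text(
            result.murate.summary() + "\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
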