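"""Conserved-synteny scoring from tabular marker-vs-genome alignment hits.

Marker sequences from the focal genetic map are aligned (externally) to a
reference genome; the 12-column tabular hit format is filtered by e-value,
multi-hit markers are resolved by requiring a clear bit-score gap between
best and second-best hit, and hits landing on unassembled scaffolds are
discarded.  Conserved synteny is then the percentage of markers that land
on their focal group's modal orthologous reference group; markers whose
reference group attracted no other marker are excluded from the
denominator, as are focal groups with fewer than two qualifying markers.
An Oxford grid (both coordinates size-normalised to [0, 1]) summarises
marker-order conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linkage import GeneticMap

BLAST6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                  "gapopen", "qstart", "qend", "sstart", "send", "evalue",
                  "bitscore"]


@dataclass(frozen=True)
class AlignmentHit:
    marker_id: str
    reference_id: str
    reference_pos: int        # 1-based start of the hit on the reference
    e_value: float
    bit_score: float

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("e-value must be >= 0")
        if self.bit_score <= 0:
            raise ValueError("bit score must be > 0")


@dataclass
class SyntenyResult:
    """Per-group assignments and the overall conservation percentage."""

    assignments: pd.DataFrame        # marker, focal group, reference group
    per_group: pd.DataFrame          # modal ref group, on/off counts, status
    conserved_percent: float
    n_on_modal: int
    n_qualifying: int
    exclusions: pd.DataFrame         # marker, reason


def parse_hits(path, e_value_cutoff: float) -> list[AlignmentHit]:
    """Read 12-column tabular hits, keeping those with e <= cutoff."""
    try:
        df = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, header=None,
                         comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty alignment file: {path}")
    if df.empty:
        raise ValueError(f"empty alignment file: {path}")
    if df[["qseqid", "sseqid", "evalue", "bitscore"]].isna().any().any():
        bad = int(df[["evalue", "bitscore"]].isna().any(axis=1).idxmax()) + 1
        raise ValueError(f"malformed alignment row at line {bad}")
    df = df[df.evalue <= e_value_cutoff]
    return [
        AlignmentHit(str(r.qseqid), str(r.sseqid), int(min(r.sstart, r.send)),
                     float(r.evalue), float(r.bitscore))
        for r in df.itertuples()
    ]


def resolve_multi_hits(hits: list[AlignmentHit], min_bit_gap: float = 20.0,
                       linked_reference_ids: set[str] | None = None):
    """Resolve each marker to a unique reference location or exclude it.

    Markers with a single hit keep it; with several, the best hit is kept
    only when its bit score exceeds the second best by more than
    ``min_bit_gap``.  Markers whose retained hit lands outside
    ``linked_reference_ids`` (the assembled linkage groups / chromosomes)
    are excluded as unlinked-scaffold hits.

    Returns ``(assignments, exclusions)``: a marker -> AlignmentHit dict
    and a DataFrame of (marker_id, reason).
    """
    by_marker: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_marker.setdefault(h.marker_id, []).append(h)
    assigned: dict[str, AlignmentHit] = {}
    excluded = []
    for mid in sorted(by_marker):
        hs = sorted(by_marker[mid], key=lambda h: (-h.bit_score, h.e_value,
                                                   h.reference_id))
        if len(hs) > 1 and hs[0].bit_score - hs[1].bit_score <= min_bit_gap:
            excluded.append((mid, "ambiguous_multi_hit"))
            continue
        best = hs[0]
        if (linked_reference_ids is not None
                and best.reference_id not in linked_reference_ids):
            excluded.append((mid, "unlinked_scaffold"))
            continue
        assigned[mid] = best
    return assigned, pd.DataFrame(excluded, columns=["marker_id", "reason"])


def conserved_synteny_percent(assignments: dict[str, AlignmentHit],
                              focal_map: GeneticMap,
                              prior_exclusions: pd.DataFrame | None = None
                              ) -> SyntenyResult:
    """Score conserved synteny of the focal map against a reference genome.

    Markers mapping to a reference group hit by no other marker are
    dropped ("lone" hits); each focal group's modal reference group is
    found among its remaining markers, focal groups with fewer than two
    qualifying markers (or a tied mode) are reported but excluded, and the
    statistic is ``100 * sum(on-modal) / sum(qualifying)``.
    """
    marker_group = {m: g.group_id for g in focal_map.groups
                    for m in g.marker_ids}
    rows = []
    for mid, hit in assignments.items():
        if mid in marker_group:
            rows.append((mid, marker_group[mid], hit.reference_id,
                         hit.reference_pos))
    df = pd.DataFrame(rows, columns=["marker_id", "focal_group",
                                     "reference_group", "reference_pos"])
    exclusions = (prior_exclusions.copy() if prior_exclusions is not None
                  else pd.DataFrame(columns=["marker_id", "reason"]))
    if df.empty:
        raise ValueError("no assigned markers located on the focal map")
    ref_counts = df.reference_group.value_counts()
    lone = df.reference_group.map(ref_counts) < 2
    exclusions = pd.concat([
        exclusions,
        pd.DataFrame({"marker_id": df.loc[lone, "marker_id"],
                      "reason": "lone_reference_group"}),
    ], ignore_index=True)
    kept = df[~lone]
    if kept.empty:
        raise ValueError("no qualifying markers after lone-hit exclusion")
    per_group_rows = []
    n_on = n_qual = 0
    for fg, sub in kept.groupby("focal_group", sort=True):
        counts = sub.reference_group.value_counts()
        top = counts.max()
        modal = sorted(counts[counts == top].index)
        tied = len(modal) > 1
        status = ("tied_mode" if tied
                  else "too_few_markers" if len(sub) < 2 else "ok")
        on = int((sub.reference_group == modal[0]).sum()) if not tied else 0
        per_group_rows.append((fg, "|".join(modal), on, len(sub) - on,
                               status))
        if status == "ok":
            n_on += on
            n_qual += len(sub)
    per_group = pd.DataFrame(
        per_group_rows, columns=["focal_group", "modal_reference_group",
                                 "n_on_modal", "n_off_modal", "status"])
    if n_qual == 0:
        raise ValueError("no focal group qualifies for the statistic")
    return SyntenyResult(
        assignments=df.reset_index(drop=True), per_group=per_group,
        conserved_percent=100.0 * n_on / n_qual,
        n_on_modal=n_on, n_qualifying=n_qual, exclusions=exclusions,
    )


def oxford_grid(focal_map: GeneticMap, assignments: dict[str, AlignmentHit],
                reference_lengths: dict[str, float]) -> pd.DataFrame:
    """Size-normalised marker coordinates for an Oxford grid.

    Each assigned marker is emitted as (focal group, focal position /
    group length, reference group, reference position / reference length),
    all normalised coordinates in [0, 1].  Zero-length groups raise.
    """
    rows = []
    for g in focal_map.groups:
        length = g.length_cm
        for mid, pos in zip(g.marker_ids, g.positions):
            hit = assignments.get(mid)
            if hit is None or hit.reference_id not in reference_lengths:
                continue
            if length <= 0:
                raise ValueError(f"zero-length focal group {g.group_id}")
            ref_len = reference_lengths[hit.reference_id]
            if ref_len <= 0:
                raise ValueError(
                    f"zero reference length for {hit.reference_id}")
            rows.append((g.group_id, float(pos) / length, hit.reference_id,
                         hit.reference_pos / ref_len, mid))
    grid = pd.DataFrame(rows, columns=["focal_group", "focal_coord",
                                       "reference_group", "reference_coord",
                                       "marker_id"])
    return grid
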