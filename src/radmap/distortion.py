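"""Detection of segregation-distortion blocks along the genetic map.

Isolated distorted markers are commonly genotyping artefacts; runs of
map-adjacent markers that deviate in the same way point to a biological
cause such as viability selection against one parental allele.  A block is
a maximal run of consecutive distorted markers (allowing a bounded number
of interior skips), with its direction classified from the standardized
residuals of the genotype counts against the 1:2:1 expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .linkage import GeneticMap
from .qc import MarkerQC

DIRECTIONS = ("paternal_excess", "maternal_excess", "het_excess",
              "het_deficit", "a_excess", "b_excess", "mixed")


@dataclass(frozen=True)
class DistortionBlock:
    group_id: str
    marker_ids: tuple[str, ...]
    start_cm: float
    end_cm: float
    direction: str
    n_markers: int
    whole_group: bool = False

    @property
    def span_cm(self) -> float:
        return self.end_cm - self.start_cm


def distortion_direction(counts, parental_origin: str | None = None) -> str:
    """Direction of a distorted marker's deviation from 1:2:1.

    ``parental_origin`` names the homozygote class carrying the paternal
    allele (``"a"`` or ``"b"``); without it, homozygote deviations are
    reported at the allele level (``a_excess`` / ``b_excess``).

    The call is driven by the standardized residuals ``(O-E)/sqrt(E)``: a
    dominant heterozygote residual gives ``het_excess``/``het_deficit``;
    otherwise the larger positive homozygote residual names the allele (or
    parent) in excess.  Undistorted counts (all residuals zero) raise.
    """
    n_a, n_h, n_b = (int(c) for c in counts)
    n = n_a + n_h + n_b
    if n == 0:
        raise ValueError("no genotyped individuals")
    expected = np.array([n / 4, n / 2, n / 4])
    resid = (np.array([n_a, n_h, n_b]) - expected) / np.sqrt(expected)
    if np.allclose(resid, 0.0):
        raise ValueError("counts match 1:2:1 exactly; no direction")
    if np.abs(resid[1]) >= np.abs(resid[[0, 2]]).max():
        return "het_excess" if resid[1] > 0 else "het_deficit"
    hom = "a" if resid[0] >= resid[2] else "b"
    if parental_origin is None:
        return f"{hom}_excess"
    if parental_origin not in ("a", "b"):
        raise ValueError("parental_origin must be 'a' or 'b'")
    return ("paternal_excess" if hom == parental_origin
            else "maternal_excess")


def _runs_with_skips(flags: np.ndarray, max_skip: int):
    """Maximal runs of True allowing up to ``max_skip`` interior False.

    Runs start and end on True; yields (start, end) inclusive index pairs.
    """
    idx = np.nonzero(flags)[0]
    if len(idx) == 0:
        return
    start = prev = idx[0]
    skips = 0
    for i in idx[1:]:
        gap = i - prev - 1
        if gap + skips <= max_skip:
            skips += gap
            prev = i
        else:
            yield start, prev
            start = prev = i
            skips = 0
    yield start, prev


def find_distortion_blocks(gmap: GeneticMap, qc: list[MarkerQC],
                           alpha: float = 0.05, min_run: int = 3,
                           max_skip: int = 1,
                           parental_origin: dict[str, str] | None = None
                           ) -> list[DistortionBlock]:
    """Scan each linkage group for blocks of distorted markers.

    A block is a maximal run of map-consecutive markers with ``p < alpha``
    permitting up to ``max_skip`` undistorted markers inside the run; runs
    with fewer than ``min_run`` distorted members are discarded, except
    that a group whose every marker is distorted is always reported (with
    ``whole_group=True``), since short groups can be distorted end to end.
    Block direction is the modal member direction (``mixed`` without a
    majority).  ``parental_origin`` optionally maps marker_id -> "a"/"b".
    """
    by_id = {m.marker_id: m for m in qc}
    origin = parental_origin or {}
    blocks: list[DistortionBlock] = []
    for group in gmap.groups:
        mids = group.marker_ids
        if not mids:
            continue
        pvals = np.array([by_id[m].p_value if m in by_id else np.nan
                          for m in mids])
        with np.errstate(invalid="ignore"):
            flags = pvals < alpha
        whole = bool(flags.all()) and len(mids) >= 2
        for start, end in _runs_with_skips(flags, max_skip):
            members = [m for m in mids[start:end + 1]]
            n_dist = int(flags[start:end + 1].sum())
            if n_dist < min_run and not whole:
                continue
            dirs = []
            for m in members:
                q = by_id.get(m)
                if q is None or not (q.p_value < alpha):
                    continue
                try:
                    dirs.append(distortion_direction(
                        q.genotype_counts, origin.get(m)))
                except ValueError:
                    continue
            if dirs:
                vals, cnts = np.unique(dirs, return_counts=True)
                best = cnts.max()
                winners = vals[cnts == best]
                direction = (str(winners[0])
                             if len(winners) == 1 and best > len(dirs) / 2
                             else "mixed")
            else:
                direction = "mixed"
            blocks.append(DistortionBlock(
                group.group_id, tuple(members),
                float(group.positions[start]), float(group.positions[end]),
                direction, n_dist, whole_group=whole))
    return blocks
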