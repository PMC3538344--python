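"""Genotype quality control and segregation testing.

Filters mirror a standard RADSeq F2 workflow: individuals with low mean
coverage are dropped first, calls below a per-call depth floor are masked,
markers genotyped in too few individuals are removed, and each marker is
tested against its Mendelian expectation (1:2:1 for codominant markers,
1:3 for one-sided markers).  The mapping marker set is then assembled in
tiers: undistorted markers form the base set, moderately distorted markers
are queued for step-wise addition from least to most significant, and
severely distorted markers are excluded because extreme ratios inflate
distances and can create false linkages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import (
    A, B, CODOMINANT_TYPES, GenotypeMatrix, H, MISSING, NOT_A, NOT_B,
    classify_segregation_type,
)

__all__ = [
    "MarkerQC", "chi_square_1_2_1", "classify_segregation_type",
    "filter_individuals", "filter_markers", "marker_qc",
    "select_mapping_markers", "snp_density_summary",
]


@dataclass(frozen=True)
class MarkerQC:
    """Per-marker segregation test result and inclusion tier."""

    marker_id: str
    segregation_type: str
    n_genotyped: int
    genotype_counts: tuple[int, int, int]
    chi_square: float
    p_value: float
    informative: bool
    inclusion_tier: str = "clean"     # clean | distorted_included | excluded


def filter_individuals(matrix: GenotypeMatrix, min_mean_depth: float = 6.0):
    """Drop individuals whose mean per-call read depth is below threshold.

    The mean is taken over that individual's non-missing calls.  Returns
    the filtered matrix and a report of removals.
    """
    if matrix.n_individuals == 0 or matrix.n_markers == 0:
        raise ValueError("empty genotype matrix")
    called = matrix.codes != MISSING
    total = matrix.total_depth
    with np.errstate(invalid="ignore"):
        mean_depth = np.where(called.sum(0) > 0,
                              (total * called).sum(0) /
                              np.maximum(called.sum(0), 1), 0.0)
    keep = mean_depth >= min_mean_depth
    report = pd.DataFrame({
        "individual": matrix.individual_ids,
        "mean_depth": np.round(mean_depth, 3),
        "removed": ~keep,
    })
    return matrix.take_individuals(np.nonzero(keep)[0]), report


def filter_markers(matrix: GenotypeMatrix, min_individuals: int = 90,
                   min_call_depth: int = 5):
    """Mask low-depth calls, then drop sparsely genotyped markers.

    Calls with total depth below ``min_call_depth`` are set missing first;
    markers genotyped in fewer than ``min_individuals`` individuals are
    then removed.  Idempotent.
    """
    out = matrix.copy()
    low = (out.total_depth < min_call_depth) & (out.codes != MISSING)
    out.codes[low] = MISSING
    out.depth_a[low] = 0
    out.depth_b[low] = 0
    n_geno = out.n_genotyped()
    keep = n_geno >= min_individuals
    report = pd.DataFrame({
        "marker_id": matrix.marker_ids,
        "n_genotyped_after_depth_mask": n_geno,
        "removed": ~keep,
    })
    return out.take_markers(np.nonzero(keep)[0]), report


def chi_square_1_2_1(counts) -> tuple[float, float]:
    """Pearson chi-square of (n_a, n_h, n_b) against 1:2:1, df = 2."""
    n_a, n_h, n_b = (int(c) for c in counts)
    n = n_a + n_h + n_b
    if n == 0:
        raise ValueError("no genotyped individuals")
    expected = np.array([n / 4, n / 2, n / 4])
    chi2 = float((((np.array([n_a, n_h, n_b]) - expected) ** 2)
                  / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=2))


def _chi_square_one_sided(n_hom: int, n_rest: int) -> tuple[float, float]:
    """Chi-square of a one-sided marker's (hom, not-hom) counts vs 1:3."""
    n = n_hom + n_rest
    if n == 0:
        raise ValueError("no genotyped individuals")
    expected = np.array([n / 4, 3 * n / 4])
    chi2 = float((((np.array([n_hom, n_rest]) - expected) ** 2)
                  / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def marker_qc(matrix: GenotypeMatrix) -> list[MarkerQC]:
    """Segregation test for every marker, honouring its type.

    Codominant markers are tested 1:2:1 (df 2); one-sided markers test the
    distinguishable homozygote against the collapsed class 1:3 (df 1).
    Markers with no genotyped individuals come back uninformative with
    ``p = nan``.
    """
    results = []
    codes = matrix.codes
    for i, (mid, seg) in enumerate(zip(matrix.marker_ids, matrix.seg_types)):
        row = codes[i]
        n_a = int((row == A).sum())
        n_h = int((row == H).sum())
        n_b = int((row == B).sum())
        n_c = int((row == NOT_A).sum())
        n_d = int((row == NOT_B).sum())
        n = n_a + n_h + n_b + n_c + n_d
        if n == 0:
            results.append(MarkerQC(mid, seg, 0, (0, 0, 0), float("nan"),
                                    float("nan"), False))
            continue
        if seg in CODOMINANT_TYPES:
            chi2, p = chi_square_1_2_1((n_a, n_h, n_b))
            counts = (n_a, n_h, n_b)
        elif seg == "aaxab":
            chi2, p = _chi_square_one_sided(n_a, n_c + n_h + n_b)
            counts = (n_a, n_h + n_c, n_b)
        elif seg == "abxaa":
            chi2, p = _chi_square_one_sided(n_b, n_d + n_h + n_a)
            counts = (n_a, n_h + n_d, n_b)
        else:
            results.append(MarkerQC(mid, seg, n, (n_a, n_h, n_b),
                                    float("nan"), float("nan"), False))
            continue
        results.append(MarkerQC(mid, seg, n, counts, chi2, p, True))
    return results


def select_mapping_markers(qc: list[MarkerQC], alpha_clean: float = 0.05,
                           alpha_floor: float = 0.001,
                           alpha_exclude: float = 0.0001,
                           include_gap: bool = True) -> pd.DataFrame:
    """Assemble the mapping marker set with the step-wise distortion policy.

    Tier 1 (``clean``): p >= ``alpha_clean``.  Tier 2
    (``distorted_included``): ``alpha_floor`` <= p < ``alpha_clean``,
    ordered for step-wise addition from least to most significant
    (descending p).  Markers with p < ``alpha_exclude`` are excluded.  The
    band ``alpha_exclude <= p < alpha_floor`` is appended to the tail of
    the tier-2 addition order when ``include_gap`` is set (default),
    otherwise excluded.  Uninformative markers (p = nan) are excluded.

    Returns a frame with columns marker_id, p_value, tier, addition_order
    (0 for the base set; 1.. for the step-wise queue; -1 for excluded).
    """
    rows = []
    for m in qc:
        p = m.p_value
        if not m.informative or np.isnan(p):
            tier = "excluded"
        elif p >= alpha_clean:
            tier = "clean"
        elif p >= alpha_floor:
            tier = "distorted_included"
        elif p >= alpha_exclude and include_gap:
            tier = "distorted_included_gap"
        else:
            tier = "excluded"
        rows.append((m.marker_id, p, tier))
    df = pd.DataFrame(rows, columns=["marker_id", "p_value", "tier"])
    df["addition_order"] = -1
    df.loc[df.tier == "clean", "addition_order"] = 0
    queue = pd.concat([
        df[df.tier == "distorted_included"].sort_values(
            "p_value", ascending=False, kind="stable"),
        df[df.tier == "distorted_included_gap"].sort_values(
            "p_value", ascending=False, kind="stable"),
    ])
    df.loc[queue.index, "addition_order"] = np.arange(1, len(queue) + 1)
    return df


def snp_density_summary(n_snps: int, n_loci: int,
                        effective_locus_length_bp: float) -> float:
    """SNPs per kilobase of surveyed locus sequence.

    The effective locus length is an explicit parameter: reported SNP/kb
    figures depend on how much of each locus is actually surveyed, which
    can differ from the nominal read length.
    """
    if n_loci <= 0:
        raise ValueError("n_loci must be > 0")
    if effective_locus_length_bp <= 0:
        raise ValueError("effective locus length must be > 0")
    return n_snps / (n_loci * effective_locus_length_bp / 1000.0)
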