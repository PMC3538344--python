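"""Pedigree-based de novo mutation-rate estimation from allele depths.

Progeny read data are screened for alleles absent from both parents at a
locus.  A candidate is retained only when the locus is covered well enough
to trust the call (total depth >= 8, each allele >= 4 reads), its
original-to-novel allele depth ratio lies inside hard bounds [0.5, 2.0],
and that ratio also falls within the central 95% interval of the empirical
allele-balance distribution observed at genuine heterozygous marker calls
— the signature of a true heterozygous carrier rather than a collapsed
repeat or sequencing artefact.  Identical mutations observed in several
individuals of one generation are counted once.  The per-generation rate
is ``m / (2 * n_individuals * n_sites)`` over the diploid surveyed sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STATUSES = ("retained", "fail_coverage", "fail_ratio_bounds",
            "fail_empirical_ci", "duplicate")


@dataclass(frozen=True)
class MutationCandidate:
    individual: str
    generation: str
    locus: int
    position: int
    parental_alleles: str
    novel_allele: str
    depth_original: int
    depth_novel: int
    status: str = "candidate"

    @property
    def ratio(self) -> float:
        return (self.depth_original / self.depth_novel
                if self.depth_novel > 0 else float("inf"))


@dataclass(frozen=True)
class MutationRateEstimate:
    generation: str
    n_mutations: int
    n_individuals: int
    n_sites: float            # surveyed sites per individual
    rate: float

    @property
    def poisson_se(self) -> float:
        denom = 2.0 * self.n_individuals * self.n_sites
        return float(np.sqrt(max(self.n_mutations, 1)) / denom)


def empirical_ratio_ci(het_depth_pairs, level: float = 0.95,
                       min_calls: int = 100) -> tuple[float, float]:
    """Central ``level`` interval of the heterozygous allele-depth ratio.

    ``het_depth_pairs`` is an (n, 2) array of (depth_a, depth_b) from
    heterozygous marker calls; pairs with a zero depth are dropped.
    ``level=1.0`` returns the full observed range.
    """
    pairs = np.asarray(het_depth_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of depth pairs")
    ok = (pairs > 0).all(axis=1)
    ratios = pairs[ok, 0] / pairs[ok, 1]
    if len(ratios) < min_calls:
        raise ValueError(
            f"need >= {min_calls} heterozygous calls, got {len(ratios)}")
    if not 0.0 < level <= 1.0:
        raise ValueError("level must be in (0, 1]")
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(ratios, alpha)),
            float(np.quantile(ratios, 1.0 - alpha)))


def detect_candidates(progeny_calls: pd.DataFrame,
                      parental_genotypes: pd.DataFrame,
                      min_total: int = 8, min_per_allele: int = 4
                      ) -> list[MutationCandidate]:
    """Screen progeny calls for alleles present in neither parent.

    ``progeny_calls`` columns: individual, generation, locus, position,
    alleleA, depthA, alleleB, depthB (alleleA the putatively inherited
    allele).  ``parental_genotypes`` columns: locus, alleles (comma-joined
    alleles seen in either parent).  Loci absent from the parental table
    are skipped.  Coverage below ``min_total`` in total or
    ``min_per_allele`` on either allele marks the candidate
    ``fail_coverage``.
    """
    parents = {int(r.locus): set(str(r.alleles).split(","))
               for r in parental_genotypes.itertuples()}
    out = []
    for r in progeny_calls.itertuples():
        alleles = parents.get(int(r.locus))
        if alleles is None:
            continue
        calls = [(str(r.alleleA), int(r.depthA)),
                 (str(r.alleleB), int(r.depthB))]
        novel = [(a, d) for a, d in calls if d > 0 and a not in alleles]
        if not novel:
            continue
        inherited = [(a, d) for a, d in calls if a in alleles]
        d_orig = inherited[0][1] if inherited else 0
        for allele, d_nov in novel:
            total = d_orig + d_nov
            ok = (total >= min_total and d_nov >= min_per_allele
                  and d_orig >= min_per_allele)
            out.append(MutationCandidate(
                str(r.individual), str(r.generation), int(r.locus),
                int(r.position), ",".join(sorted(alleles)), allele,
                d_orig, d_nov,
                status="candidate" if ok else "fail_coverage"))
    return out


def filter_candidates(candidates: list[MutationCandidate],
                      ci: tuple[float, float],
                      bounds: tuple[float, float] = (0.5, 2.0)
                      ) -> list[MutationCandidate]:
    """Apply the hard allele-ratio bounds and the empirical CI conjunctively.

    Candidates already failing coverage keep that status; the rest are
    retained only when ``bounds[0] <= ratio <= bounds[1]`` and
    ``ci[0] <= ratio <= ci[1]``.
    """
    lo, hi = bounds
    clo, chi = ci
    out = []
    for c in candidates:
        if c.status == "fail_coverage":
            out.append(c)
            continue
        r = c.ratio
        if not lo <= r <= hi:
            status = "fail_ratio_bounds"
        elif not clo <= r <= chi:
            status = "fail_empirical_ci"
        else:
            status = "retained"
        out.append(MutationCandidate(**{**c.__dict__, "status": status}))
    return out


def deduplicate(candidates: list[MutationCandidate]
                ) -> list[MutationCandidate]:
    """Collapse retained candidates identical in (generation, locus,
    position, novel allele); later occurrences are marked ``duplicate``.
    Idempotent."""
    seen = set()
    out = []
    for c in candidates:
        if c.status != "retained":
            out.append(c)
            continue
        key = (c.generation, c.locus, c.position, c.novel_allele)
        if key in seen:
            out.append(MutationCandidate(**{**c.__dict__,
                                            "status": "duplicate"}))
        else:
            seen.add(key)
            out.append(c)
    return out


def estimate_rate(n_mutations: int, n_individuals: int, n_sites: float,
                  generation: str = "F2") -> MutationRateEstimate:
    """Per-nucleotide per-generation rate over 2 genome copies:
    ``rate = m / (2 * n_individuals * n_sites)``."""
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rate = n_mutations / (2.0 * n_individuals * n_sites)
    return MutationRateEstimate(generation, int(n_mutations),
                                int(n_individuals), float(n_sites), rate)


def average_rates(estimates) -> float:
    """Unweighted arithmetic mean of per-generation rates."""
    rates = [e.rate if isinstance(e, MutationRateEstimate) else float(e)
             for e in estimates]
    if not rates:
        raise ValueError("no rate estimates to average")
    return float(np.mean(rates))


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------

class MutationRateModel:
    """De novo mutation-rate estimator over a parent/progeny survey.

    Parameters
    ----------
    progeny_calls : DataFrame
        Variant calls (individual, generation, locus, position, alleleA,
        depthA, alleleB, depthB).
    parental_genotypes : DataFrame
        Per-locus alleles present in the parents (locus, alleles).
    het_depth_pairs : (n, 2) array
        Allele depths of heterozygous marker calls, the empirical
        allele-balance null.
    n_sites : float or mapping generation -> float
        Surveyed (callable) sites per individual.
    n_individuals : mapping generation -> int
        Surveyed individuals per generation.
    """

    def __init__(self, progeny_calls: pd.DataFrame,
                 parental_genotypes: pd.DataFrame, het_depth_pairs,
                 n_sites, n_individuals: dict[str, int], *,
                 min_total: int = 8, min_per_allele: int = 4,
                 ratio_bounds: tuple[float, float] = (0.5, 2.0),
                 ci_level: float = 0.95, min_het_calls: int = 100):
        self.progeny_calls = progeny_calls
        self.parental_genotypes = parental_genotypes
        self.het_depth_pairs = np.asarray(het_depth_pairs)
        self.n_sites = n_sites
        self.n_individuals = dict(n_individuals)
        self.min_total = min_total
        self.min_per_allele = min_per_allele
        self.ratio_bounds = tuple(ratio_bounds)
        self.ci_level = ci_level
        self.min_het_calls = min_het_calls

    def _sites_for(self, generation: str) -> float:
        if isinstance(self.n_sites, dict):
            return float(self.n_sites[generation])
        return float(self.n_sites)

    def fit(self, apply_filters: bool = True) -> "MutationRateResults":
        ci = empirical_ratio_ci(self.het_depth_pairs, self.ci_level,
                                self.min_het_calls)
        cands = detect_candidates(self.progeny_calls,
                                  self.parental_genotypes,
                                  self.min_total, self.min_per_allele)
        if apply_filters:
            cands = filter_candidates(cands, ci, self.ratio_bounds)
        else:
            cands = [MutationCandidate(**{**c.__dict__, "status": "retained"})
                     for c in cands]
        cands = deduplicate(cands)
        estimates = {}
        for gen, n_ind in sorted(self.n_individuals.items()):
            m = sum(1 for c in cands
                    if c.generation == gen and c.status == "retained")
            estimates[gen] = estimate_rate(m, n_ind, self._sites_for(gen),
                                           generation=gen)
        return MutationRateResults(self, ci, cands, estimates)


class MutationRateResults:
    """Candidate table, per-generation estimates and their average."""

    def __init__(self, model: MutationRateModel, ci: tuple[float, float],
                 candidates: list[MutationCandidate],
                 estimates: dict[str, MutationRateEstimate]):
        self.model = model
        self.ratio_ci = ci
        self.candidates = candidates
        self.estimates = estimates

    @property
    def mean_rate(self) -> float:
        return average_rates(list(self.estimates.values()))

    def candidate_frame(self) -> pd.DataFrame:
        rows = [{**c.__dict__, "ratio": (round(c.ratio, 4)
                                         if np.isfinite(c.ratio) else "inf")}
                for c in self.candidates]
        return pd.DataFrame(rows)

    def raw_counts(self) -> dict[str, int]:
        """Retained-candidate counts per generation before deduplication."""
        out: dict[str, int] = {}
        for c in self.candidates:
            if c.status in ("retained", "duplicate"):
                out[c.generation] = out.get(c.generation, 0) + 1
        return out

    def summary(self) -> str:
        lines = [
            "De novo mutation-rate estimate (pedigree, diploid denominator)",
            "=" * 64,
            f"coverage filter            >= {self.model.min_total} total, "
            f">= {self.model.min_per_allele} per allele",
            f"allele-ratio hard bounds   [{self.model.ratio_bounds[0]}, "
            f"{self.model.ratio_bounds[1]}]",
            f"empirical ratio {self.model.ci_level:.0%} CI     "
            f"[{self.ratio_ci[0]:.3f}, {self.ratio_ci[1]:.3f}]",
            "-" * 64,
        ]
        raw = self.raw_counts()
        for gen, est in sorted(self.estimates.items()):
            lines.append(
                f"{gen}: {est.n_mutations} mutations"
                f" (raw {raw.get(gen, 0)}) / {est.n_individuals} individuals"
                f" x {est.n_sites:.3g} sites -> {est.rate:.2e}"
                " per site per generation")
        lines.append("-" * 64)
        lines.append(f"average rate               {self.mean_rate:.2e}")
        return "\n".join(lines)


def het_depth_pairs_from_matrix(matrix) -> np.ndarray:
    """(n, 2) allele depths of heterozygous calls in a genotype matrix."""
    from .genotypes import H
    het = matrix.codes == H
    return np.column_stack([matrix.depth_a[het], matrix.depth_b[het]])
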