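"""Synthetic P -> F1 -> F2 pedigree generator with known truth.

Emulates a ddRADSeq genotyping experiment on an interspecific F2 cross:
two parental individuals from diverged lines, an F1 sibling pair, and a
cohort of F2 offspring genotyped at RAD markers spread over linkage groups.
Every downstream stage of the pipeline (QC, linkage mapping, distortion
scanning, mutation-rate estimation) can be exercised against the generator's
recorded truth: the genetic map, the viability-selection blocks, and the
injected de novo mutations.

Crossovers are drawn, by default, from a stationary gamma-renewal chiasma
process (shape 2.6, rate 2 per Morgan, chiasmata thinned 1/2 per gamete)
whose two-point recombination fraction matches Kosambi's map function to
within 0.0011 across 0-60 cM, so the distances the mapping stage estimates
under the Kosambi convention coincide with the simulated truth at every
span, not just between adjacent markers.  A no-interference Markov process
over adjacent intervals is available as ``interference="none"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import (
    A, B, GenotypeMatrix, H, MISSING, NOT_A, NOT_B, ONE_SIDED_TYPES,
)
from .linkage import inverse_kosambi

#: gamma-renewal shape reproducing Kosambi-level crossover interference
KOSAMBI_NU = 2.6

SELECTION_MODES = ("against_maternal", "against_paternal",
                   "het_advantage", "het_disadvantage")


@dataclass(frozen=True)
class SelectionBlock:
    """Viability selection acting at one causal locus on a linkage group.

    ``group`` is the 1-based true linkage-group number; the causal locus
    sits at the midpoint of ``[start_cm, end_cm]`` and linked markers in
    that window (and beyond, attenuating with distance) show distorted
    segregation in the surviving cohort.
    """

    group: int
    start_cm: float
    end_cm: float
    mode: str
    s: float

    @property
    def causal_cm(self) -> float:
        return 0.5 * (self.start_cm + self.end_cm)

    def fitness(self) -> np.ndarray:
        """Relative fitness of genotypes (maternal hom, het, paternal hom)."""
        s = self.s
        return {
            "against_maternal": np.array([1 - s, 1 - s / 2, 1.0]),
            "against_paternal": np.array([1.0, 1 - s / 2, 1 - s]),
            "het_advantage": np.array([1 - s, 1.0, 1 - s]),
            "het_disadvantage": np.array([1.0, 1 - s, 1.0]),
        }[self.mode]


def _default_group_lengths() -> list[float]:
    # 23 full-sized groups plus two short ones; totals ~1427 cM
    return list(np.linspace(51.5, 72.2, 23)) + [2.5, 2.0]


def _default_markers_per_group(lengths: list[float], total: int = 755
                               ) -> list[int]:
    small = [3, 2]  # the two short groups
    big = np.asarray(lengths[:-2])
    remaining = total - sum(small)
    raw = remaining * big / big.sum()
    counts = np.floor(raw).astype(int)
    # largest-remainder rounding
    for i in np.argsort(raw - counts)[::-1][: remaining - counts.sum()]:
        counts[i] += 1
    return list(counts) + small


def _default_blocks() -> list[SelectionBlock]:
    return [
        SelectionBlock(1, 10.0, 35.0, "against_maternal", 0.5),
        SelectionBlock(6, 20.0, 30.0, "against_paternal", 0.5),
        SelectionBlock(15, 50.0, 62.0, "het_advantage", 0.5),
        SelectionBlock(23, 40.0, 55.0, "het_advantage", 0.5),
        SelectionBlock(24, 0.0, 2.5, "against_paternal", 0.5),
    ]


@dataclass
class SimConfig:
    """Simulation parameters; the defaults emulate the study cross.

    25 linkage groups carrying 755 informative markers over ~1427 cM, 343
    F2 offspring, negative-binomial read depth with mean 15 and SD ~5.1,
    25% missing calls, 18.5% of markers fixed between the parental lines,
    viability-selection blocks on five groups, and de novo mutations at
    6.6e-8 per site per generation.
    """

    n_groups: int = 25
    markers_per_group: list[int] | None = None
    group_lengths_cm: list[float] | None = None
    n_f2: int = 343
    fixed_diff_fraction: float = 0.185
    seg_type_weights: dict[str, float] = field(default_factory=lambda: {
        "aaxab": 0.2, "abxaa": 0.2, "abxab": 0.2, "abxac": 0.2, "abxcc": 0.2,
    })
    mean_depth: float = 15.0
    depth_dispersion: float = 20.4   # NB size k: var = mean + mean^2/k
    missing_rate: float = 0.25
    genotyping_error_rate: float = 0.001
    mutation_rate: float = 6.6e-8
    locus_length_bp: int = 110
    n_loci_total: int = 38203
    distortion_blocks: list[SelectionBlock] = field(
        default_factory=_default_blocks)
    marker_placement: str = "random"      # or "even"
    interference: str = "kosambi"         # or "none" (Markov intervals)
    seed: int = 0

    def __post_init__(self):
        if self.group_lengths_cm is None:
            self.group_lengths_cm = (_default_group_lengths()
                                     if self.n_groups == 25
                                     else [60.0] * self.n_groups)
        if self.markers_per_group is None:
            self.markers_per_group = (
                _default_markers_per_group(self.group_lengths_cm)
                if self.n_groups == 25 else [30] * self.n_groups)
        self.validate()

    def validate(self) -> None:
        for name in ("fixed_diff_fraction", "missing_rate",
                     "genotyping_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if len(self.group_lengths_cm) != self.n_groups:
            raise ValueError("group_lengths_cm length != n_groups")
        if len(self.markers_per_group) != self.n_groups:
            raise ValueError("markers_per_group length != n_groups")
        if any(l <= 0 for l in self.group_lengths_cm):
            raise ValueError("group lengths must be > 0")
        if any(m < 2 for m in self.markers_per_group):
            raise ValueError("every group needs at least 2 markers")
        if self.n_f2 < 1:
            raise ValueError("n_f2 must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")
        w = self.seg_type_weights
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("seg_type_weights must sum to 1")
        for blk in self.distortion_blocks:
            if not 0.0 <= blk.s <= 1.0:
                raise ValueError("selection coefficient must be in [0, 1]")
            if blk.mode not in SELECTION_MODES:
                raise ValueError(f"unknown selection mode {blk.mode!r}")
            if not 1 <= blk.group <= self.n_groups:
                raise ValueError(f"block group {blk.group} out of range")
        if self.marker_placement not in ("random", "even"):
            raise ValueError("marker_placement must be 'random' or 'even'")
        if self.interference not in ("kosambi", "none"):
            raise ValueError("interference must be 'kosambi' or 'none'")


# ---------------------------------------------------------------------------
# True map
# ---------------------------------------------------------------------------

@dataclass
class TrueGroup:
    group: int
    marker_ids: list[str]
    positions_cm: np.ndarray
    rec_fractions: np.ndarray    # adjacent-interval r, inverse-Kosambi


@dataclass
class TrueMap:
    groups: list[TrueGroup]

    @property
    def n_markers(self) -> int:
        return sum(len(g.marker_ids) for g in self.groups)

    @property
    def total_cm(self) -> float:
        return float(sum(g.positions_cm[-1] - g.positions_cm[0]
                         for g in self.groups))

    def all_marker_ids(self) -> list[str]:
        return [m for g in self.groups for m in g.marker_ids]

    def to_frame(self) -> pd.DataFrame:
        rows = [(g.group, m, round(float(p), 4))
                for g in self.groups
                for m, p in zip(g.marker_ids, g.positions_cm)]
        return pd.DataFrame(rows, columns=["group", "marker", "cM"])


def build_true_map(config: SimConfig, rng: np.random.Generator | None = None,
                   positions_cm: list | None = None) -> TrueMap:
    """Place markers on each group and derive adjacent recombination
    fractions by the inverse Kosambi function.

    Placement is uniform-random (sorted) or evenly spaced per
    ``config.marker_placement``; alternatively ``positions_cm`` supplies
    one strictly increasing position array per group.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    groups = []
    for g in range(config.n_groups):
        m = config.markers_per_group[g]
        length = config.group_lengths_cm[g]
        if positions_cm is not None:
            pos = np.asarray(positions_cm[g], dtype=float)
            if len(pos) != m or np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"group {g + 1}: need {m} strictly increasing positions")
        elif config.marker_placement == "even":
            pos = np.linspace(0.0, length, m)
        else:
            # group length is the marker span: anchor ends, interior uniform
            pos = np.sort(rng.uniform(0.0, length, m))
            while np.any(np.diff(pos) <= 0):   # enforce strict increase
                pos = np.sort(rng.uniform(0.0, length, m))
            pos = (pos - pos[0]) * (length / (pos[-1] - pos[0]))
        ids = [f"G{g + 1:02d}M{i + 1:03d}" for i in range(m)]
        groups.append(TrueGroup(g + 1, ids, pos,
                                inverse_kosambi(np.diff(pos))))
    return TrueMap(groups)


# ---------------------------------------------------------------------------
# Parents and F2 genotypes
# ---------------------------------------------------------------------------

def simulate_parents(config: SimConfig, rng: np.random.Generator
                     ) -> np.ndarray:
    """Assign each marker a parental segregation type.

    A fraction ``fixed_diff_fraction`` are fixed differences (aaxbb); the
    rest are drawn among the five other informative types with
    ``seg_type_weights``.
    """
    n = sum(config.markers_per_group)
    types = np.empty(n, dtype=object)
    fixed = rng.random(n) < config.fixed_diff_fraction
    types[fixed] = "aaxbb"
    others = list(config.seg_type_weights)
    w = np.array([config.seg_type_weights[t] for t in others])
    types[~fixed] = rng.choice(others, size=int((~fixed).sum()), p=w / w.sum())
    return types


_PARENT_GENOTYPES = {
    "aaxbb": ("aa", "bb"), "aaxab": ("aa", "ab"), "abxaa": ("ab", "aa"),
    "abxab": ("ab", "ab"), "abxac": ("ab", "ac"), "abxcc": ("ab", "cc"),
}


def parent_table(true_map: TrueMap, seg_types: np.ndarray) -> pd.DataFrame:
    ids = true_map.all_marker_ids()
    p1, p2 = zip(*(_PARENT_GENOTYPES[t] for t in seg_types))
    return pd.DataFrame({"marker_id": ids, "seg_type": seg_types,
                         "parent1": p1, "parent2": p2})


def _gamete_phases(positions_cm: np.ndarray, n: int,
                   rng: np.random.Generator, interference: str
                   ) -> np.ndarray:
    """(n, m) 0/1 parental-line phase of ``n`` gametes at marker positions."""
    m = len(positions_cm)
    start = rng.integers(0, 2, n)
    if interference == "none":
        r = inverse_kosambi(np.diff(positions_cm))
        rec = rng.random((n, m - 1)) < r
        flips = np.concatenate(
            [np.zeros((n, 1), dtype=np.int64), np.cumsum(rec, axis=1)], axis=1)
        return (start[:, None] + flips) % 2
    # gamma-renewal chiasma process, burn-in for stationarity
    length = positions_cm[-1] - positions_cm[0]
    burn = 500.0
    scale = 50.0 / KOSAMBI_NU          # chiasma rate 2 per Morgan
    n_pts = max(int((length + burn) / 50.0 * 4) + 30, 40)
    gaps = rng.gamma(KOSAMBI_NU, scale, size=(n, n_pts))
    pts = np.cumsum(gaps, axis=1) - burn + positions_cm[0]
    thin = rng.random((n, n_pts)) < 0.5   # chiasma -> gamete crossover
    xo = np.where(thin, pts, np.inf)
    counts = (xo[:, :, None] < positions_cm[None, None, :]).sum(axis=1)
    return (start[:, None] + counts) % 2


def _simulate_true_genotypes(config: SimConfig, true_map: TrueMap,
                             rng: np.random.Generator, n: int,
                             latent: dict[int, list[float]] | None = None):
    """True F2 genotype values (0/1/2) plus genotypes at latent loci.

    ``latent`` maps group number -> extra cM positions (e.g. causal loci of
    selection blocks) whose genotypes are simulated jointly with the
    markers but returned separately.
    """
    latent = latent or {}
    blocks_g: list[np.ndarray] = []
    latent_g: dict[tuple[int, float], np.ndarray] = {}
    for tg in true_map.groups:
        extra = sorted(latent.get(tg.group, []))
        pos = np.concatenate([tg.positions_cm, np.array(extra)])
        order = np.argsort(pos, kind="stable")
        maternal = _gamete_phases(pos[order], n, rng, config.interference)
        paternal = _gamete_phases(pos[order], n, rng, config.interference)
        geno_sorted = maternal + paternal           # (n, m+extra)
        geno = np.empty_like(geno_sorted)
        geno[:, order] = geno_sorted
        m = len(tg.positions_cm)
        blocks_g.append(geno[:, :m].T.astype(np.int8))
        for j, cm in enumerate(extra):
            latent_g[(tg.group, cm)] = geno[:, m + j].astype(np.int8)
    return np.vstack(blocks_g), latent_g


def simulate_f2(config: SimConfig, true_map: TrueMap, seg_types: np.ndarray,
                rng: np.random.Generator) -> GenotypeMatrix:
    """Simulate true F2 genotypes (codes a/h/b, no depths or missingness).

    Each F2 receives one maternal and one paternal F1 gamete; gametes are
    generated along each group under the configured crossover process and
    unlinked groups segregate independently.
    """
    codes, _ = _simulate_true_genotypes(config, true_map, rng, config.n_f2)
    return GenotypeMatrix(
        true_map.all_marker_ids(),
        [f"F2_{i + 1:04d}" for i in range(config.n_f2)],
        seg_types, codes,
    )


def encode_observed(codes: np.ndarray, seg_types: np.ndarray) -> np.ndarray:
    """Collapse true genotypes to what each segregation type can observe.

    One-sided markers distinguish only one homozygote class: aaxab yields
    ``a`` vs ``c`` (= h or b), abxaa yields ``b`` vs ``d`` (= a or h).
    Fully codominant types pass through unchanged.
    """
    out = codes.copy()
    for seg, collapsed in ONE_SIDED_TYPES.items():
        rows = np.asarray(seg_types) == seg
        if not rows.any():
            continue
        sub = out[rows]
        if collapsed == NOT_A:
            sub[np.isin(sub, (H, B))] = NOT_A
        else:
            sub[np.isin(sub, (A, H))] = NOT_B
        out[rows] = sub
    return out


def simulate_depths_and_missingness(matrix: GenotypeMatrix, config: SimConfig,
                                    rng: np.random.Generator
                                    ) -> GenotypeMatrix:
    """Add read depths, genotyping error, missingness; collapse codes.

    Total depth per call is negative-binomial (mean ``mean_depth``, size
    ``depth_dispersion``) split binomially between the two alleles of a
    heterozygote.  Miscalls flip between adjacent codes (a<->h, h<->b) at
    ``genotyping_error_rate`` before depths are drawn, so calls and depths
    stay mutually consistent; calls are then masked missing independently
    at ``missing_rate``, and one-sided segregation types are collapsed to
    their observable codes.
    """
    if config.mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    codes = matrix.codes.copy()
    shape = codes.shape
    # symmetric adjacent-code miscalls
    err = rng.random(shape) < config.genotyping_error_rate
    if err.any():
        flip_dir = rng.random(shape) < 0.5   # for h: to a or to b
        new = codes.copy()
        new[err & (codes == A)] = H
        new[err & (codes == B)] = H
        new[err & (codes == H) & flip_dir] = A
        new[err & (codes == H) & ~flip_dir] = B
        codes = new
    k = config.depth_dispersion
    p = k / (k + config.mean_depth)
    total = rng.negative_binomial(k, p, size=shape).astype(np.int32)
    depth_a = np.where(codes == A, total, 0).astype(np.int32)
    het = codes == H
    depth_a[het] = rng.binomial(total[het], 0.5)
    depth_b = (total - depth_a).astype(np.int32)
    depth_b[codes == A] = 0
    # missingness, independent per call
    miss = rng.random(shape) < config.missing_rate
    observed = encode_observed(codes, matrix.seg_types)
    observed[miss] = MISSING
    depth_a[miss] = 0
    depth_b[miss] = 0
    return GenotypeMatrix(matrix.marker_ids, matrix.individual_ids,
                          matrix.seg_types, observed, depth_a, depth_b)


# ---------------------------------------------------------------------------
# Pedigree dataset, mutations, selection
# ---------------------------------------------------------------------------

@dataclass
class PedigreeDataset:
    """A simulated cross with its recorded truth."""

    config: SimConfig
    true_map: TrueMap
    seg_types: np.ndarray
    parents: pd.DataFrame            # marker_id, seg_type, parent genotypes
    f1_genotypes: pd.DataFrame       # both F1s are heterozygous carriers
    f2: GenotypeMatrix               # observed codes with depths
    f2_true: np.ndarray              # uncollapsed true codes (pre-error)
    latent_genotypes: dict = field(default_factory=dict)
    mutations: pd.DataFrame | None = None


def inject_de_novo_mutations(dataset: PedigreeDataset, config: SimConfig,
                             rng: np.random.Generator) -> PedigreeDataset:
    """Draw de novo mutations for every progeny individual.

    Per individual, per surveyed site, per inherited genome copy a mutation
    occurs with probability ``mutation_rate``; counts are drawn Poisson
    with mean ``2 * L * u`` (L = n_loci_total * locus_length_bp) and placed
    uniformly.  The truth list records individual, generation, locus,
    position, genome copy and novel allele.  Both F1 individuals and all
    F2 offspring are mutated; the read-level consequences are materialised
    by :func:`build_mutation_survey` for the individuals it surveys.
    """
    if config.mutation_rate < 0:
        raise ValueError("mutation_rate must be >= 0")
    sites = config.n_loci_total * config.locus_length_bp
    lam = 2.0 * sites * config.mutation_rate
    individuals = (["F1_1", "F1_2"], ["F1"] * 2)
    f2_ids = list(dataset.f2.individual_ids)
    names = individuals[0] + f2_ids
    gens = individuals[1] + ["F2"] * len(f2_ids)
    rows = []
    for name, gen in zip(names, gens):
        k = rng.poisson(lam)
        for _ in range(k):
            locus = int(rng.integers(config.n_loci_total))
            offset = int(rng.integers(config.locus_length_bp))
            copy = int(rng.integers(2))
            allele = str(rng.choice(["C", "G", "T"]))
            rows.append((name, gen, locus, offset, copy, allele))
    mutations = pd.DataFrame(
        rows, columns=["individual", "generation", "locus", "position",
                       "copy", "novel_allele"])
    return replace(dataset, mutations=mutations)


def apply_viability_selection(dataset: PedigreeDataset, config: SimConfig,
                              rng: np.random.Generator) -> PedigreeDataset:
    """Filter the F2 cohort by genotype-dependent survival.

    Each individual survives with probability equal to the product of
    relative fitnesses over all configured block causal loci (genotypes
    taken from ``dataset.latent_genotypes``).  Returns the surviving
    subset; :func:`simulate_dataset` uses batch rejection to deliver a
    full-size post-selection cohort.
    """
    if not config.distortion_blocks:
        return dataset
    n = dataset.f2.n_individuals
    surv_p = np.ones(n)
    for blk in config.distortion_blocks:
        geno = dataset.latent_genotypes[(blk.group, blk.causal_cm)]
        surv_p *= blk.fitness()[geno]
    keep = np.nonzero(rng.random(n) < surv_p)[0]
    return replace(
        dataset,
        f2=dataset.f2.take_individuals(keep),
        f2_true=dataset.f2_true[:, keep],
        latent_genotypes={k: v[keep]
                          for k, v in dataset.latent_genotypes.items()},
    )


def simulate_dataset(config: SimConfig) -> PedigreeDataset:
    """Run the full generator: map, parents, selected F2 cohort, depths,
    missingness and de novo mutations.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    true_map = build_true_map(config, rng)
    seg_types = simulate_parents(config, rng)
    latent_spec: dict[int, list[float]] = {}
    for blk in config.distortion_blocks:
        latent_spec.setdefault(blk.group, []).append(blk.causal_cm)

    fitness_of = None
    if config.distortion_blocks:
        def fitness_of(latent_g, n):
            p = np.ones(n)
            for blk in config.distortion_blocks:
                p *= blk.fitness()[latent_g[(blk.group, blk.causal_cm)]]
            return p

    chunks, latent_chunks, collected = [], [], 0
    for _ in range(200):   # rejection batches; guard against s ~ 1
        codes, latent_g = _simulate_true_genotypes(
            config, true_map, rng, config.n_f2, latent_spec)
        if fitness_of is not None:
            keep = np.nonzero(
                rng.random(config.n_f2) < fitness_of(latent_g, config.n_f2)
            )[0]
            codes = codes[:, keep]
            latent_g = {k: v[keep] for k, v in latent_g.items()}
        chunks.append(codes)
        latent_chunks.append(latent_g)
        collected += codes.shape[1]
        if collected >= config.n_f2:
            break
    if collected < config.n_f2:
        raise RuntimeError("viability selection rejected too many offspring")
    true_codes = np.concatenate(chunks, axis=1)[:, : config.n_f2]
    latent = {k: np.concatenate([c[k] for c in latent_chunks])[: config.n_f2]
              for k in latent_chunks[0]}

    ids = [f"F2_{i + 1:04d}" for i in range(config.n_f2)]
    true_matrix = GenotypeMatrix(true_map.all_marker_ids(), ids, seg_types,
                                 true_codes)
    observed = simulate_depths_and_missingness(true_matrix, config, rng)
    dataset = PedigreeDataset(
        config=config, true_map=true_map, seg_types=seg_types,
        parents=parent_table(true_map, seg_types),
        f1_genotypes=pd.DataFrame({"individual": ["F1_1", "F1_2"],
                                   "genotype": ["ab", "ab"]}),
        f2=observed, f2_true=true_codes, latent_genotypes=latent,
    )
    return inject_de_novo_mutations(dataset, config, rng)


# ---------------------------------------------------------------------------
# Mutation survey (read-level view for the rate estimator)
# ---------------------------------------------------------------------------

@dataclass
class MutationSurvey:
    """Per-locus read depths and variant calls for surveyed individuals.

    ``locus_depths`` holds the total depth of every surveyed locus for each
    surveyed individual (RAD loci share one depth across their sites);
    ``calls`` lists only sites where an individual shows an allele, with
    the original- and novel-allele depths; all surveyed loci are
    monomorphic for the parental allele unless mutated.
    """

    individuals: list[str]
    generations: list[str]
    locus_depths: np.ndarray          # (n_individuals, n_loci)
    calls: pd.DataFrame
    parental_alleles: pd.DataFrame    # locus -> alleles present in P
    locus_length_bp: int

    def callable_sites(self, min_total: int = 8) -> np.ndarray:
        """Surveyed sites per individual with locus depth >= min_total."""
        return ((self.locus_depths >= min_total).sum(axis=1)
                * self.locus_length_bp)


def build_mutation_survey(dataset: PedigreeDataset,
                          rng: np.random.Generator | None = None,
                          n_f2_sampled: int = 8) -> MutationSurvey:
    """Materialise the read-level survey the rate estimator consumes.

    Surveys both F1 individuals plus ``n_f2_sampled`` randomly chosen F2
    offspring, mirroring a high-coverage parent/progeny comparison.  Locus
    depths are negative-binomial per locus; a true mutation at a surveyed
    locus appears as a novel allele carried by about half the reads
    (binomial split); sequencing errors spawn spurious low-support novel
    alleles at rate ``genotyping_error_rate`` per read and site.
    """
    cfg = dataset.config
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    f2_ids = list(dataset.f2.individual_ids)
    chosen = sorted(rng.choice(len(f2_ids), size=min(n_f2_sampled,
                                                     len(f2_ids)),
                               replace=False).tolist())
    individuals = ["F1_1", "F1_2"] + [f2_ids[i] for i in chosen]
    generations = ["F1", "F1"] + ["F2"] * len(chosen)
    n_ind, n_loci = len(individuals), cfg.n_loci_total
    k = cfg.depth_dispersion
    p = k / (k + cfg.mean_depth)
    depths = rng.negative_binomial(k, p, size=(n_ind, n_loci)).astype(
        np.int32)
    rows = []
    muts = dataset.mutations
    if muts is None:
        muts = pd.DataFrame(columns=["individual", "generation", "locus",
                                     "position", "copy", "novel_allele"])
    by_ind = {name: sub for name, sub in muts.groupby("individual")}
    for i, (name, gen) in enumerate(zip(individuals, generations)):
        for _, mut in by_ind.get(name, muts.iloc[:0]).iterrows():
            t = int(depths[i, int(mut.locus)])
            if t == 0:
                continue
            novel = int(rng.binomial(t, 0.5))
            if novel == 0:
                continue   # mutation present but not covered by any read
            rows.append((name, gen, int(mut.locus), int(mut.position),
                         "A", t - novel, mut.novel_allele, novel))
        # sequencing-error artefacts: a spurious novel allele needs >= 2
        # concordant erroneous reads at one site (single-read errors are
        # dropped by any caller); its read support stays near that floor
        e = cfg.genotyping_error_rate
        if e > 0:
            from scipy.stats import binom as _binom
            t_i = depths[i].astype(np.int64)
            p_site = 3.0 * _binom.sf(1, t_i, e / 3.0)
            n_err = rng.binomial(cfg.locus_length_bp, p_site)
            for locus in np.nonzero(n_err)[0]:
                t = int(depths[i, locus])
                for _ in range(int(n_err[locus])):
                    bad = 2 + int(rng.binomial(max(t - 2, 0), e / 3.0))
                    rows.append((name, gen, int(locus),
                                 int(rng.integers(cfg.locus_length_bp)),
                                 "A", t - bad,
                                 str(rng.choice(["C", "G", "T"])), bad))
    calls = pd.DataFrame(
        rows, columns=["individual", "generation", "locus", "position",
                       "alleleA", "depthA", "alleleB", "depthB"])
    parental = pd.DataFrame({"locus": np.arange(n_loci), "alleles": "A"})
    return MutationSurvey(individuals, generations, depths, calls, parental,
                          cfg.locus_length_bp)
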