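"""Two-point linkage-map construction for an F2 intercross.

The map is built in three stages, mirroring classical two-point mapping
software:

1. **Pairwise estimation** — for every marker pair the recombination
   fraction ``r`` is estimated by maximum likelihood with an EM algorithm
   over the joint F2 genotype classes.  The only ambiguous class for fully
   codominant markers is the double heterozygote, which is a phase mixture
   of zero- and two-recombinant gamete configurations; collapsed one-sided
   codes (``c``/``d``) simply widen the set of compatible configurations.
   The linkage LOD is ``log10 L(r_hat) - log10 L(0.5)``.
2. **Grouping** — single-linkage transitive closure over pairs whose
   grouping LOD exceeds a threshold (default 6.0).
3. **Ordering** — a regression-mapping style build per group: markers are
   inserted one at a time in decreasing order of linkage information, each
   candidate position scored by a weighted least-squares fit of pairwise
   Kosambi distances (weights = LOD; pairs used only when ``r <= max_rf``
   and ``LOD >= min_lod``), with a window-permutation "ripple" after each
   insertion and a goodness-of-fit jump test that postpones poorly fitting
   markers.

Distances are reported in Kosambi centimorgans, which allow for partial
crossover interference: ``d = 25 ln((1+2r)/(1-2r))`` cM.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.special import xlogy

from .genotypes import A, B, CODE_SETS, GenotypeMatrix, H, MISSING, NOT_A, NOT_B

LN10 = np.log(10.0)


class LinkageError(ValueError):
    """Raised when a linkage quantity cannot be computed from the data."""


# ---------------------------------------------------------------------------
# Kosambi mapping function
# ---------------------------------------------------------------------------

def kosambi_cm(r, max_cm: float | None = None):
    """Kosambi map distance in cM for recombination fraction ``r``.

    ``d = 25 * ln((1+2r)/(1-2r))``.  Values of ``r >= 0.5`` have infinite
    map distance; they raise unless a finite ``max_cm`` cap is supplied.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("recombination fraction must be >= 0")
    over = r >= 0.5
    if np.any(over):
        if max_cm is None:
            raise ValueError("r >= 0.5 has infinite Kosambi distance")
        r = np.where(over, 0.5, r)
    with np.errstate(divide="ignore"):
        d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    if max_cm is not None:
        d = np.minimum(d, max_cm)
    return float(d) if d.ndim == 0 else d


def inverse_kosambi(d):
    """Recombination fraction for a Kosambi distance ``d`` in cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    r = 0.5 * np.tanh(2.0 * d / 100.0)
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# Pairwise recombination-fraction estimation (EM)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseLinkage:
    """Estimated linkage between one marker pair."""

    marker_a: str
    marker_b: str
    r_hat: float
    lod: float
    n_informative: int


def _build_states():
    """The 16 phased two-locus gamete-pair configurations of an F2.

    Each individual receives one maternal and one paternal F1 gamete; a
    gamete carries one allele (0/1, by parental line of origin) at each
    locus and is recombinant when the two differ.
    """
    g1 = np.empty(16, dtype=np.int64)   # genotype (allele count) at locus 1
    g2 = np.empty(16, dtype=np.int64)   # genotype at locus 2
    k = np.empty(16, dtype=np.int64)    # number of recombinant gametes (0-2)
    for s, (x1, x2, y1, y2) in enumerate(itertools.product((0, 1), repeat=4)):
        g1[s] = x1 + y1
        g2[s] = x2 + y2
        k[s] = int(x1 != x2) + int(y1 != y2)
    return g1, g2, k


_G1, _G2, _K = _build_states()

#: mask[5*c1 + c2, state] — is the state compatible with observed code pair
_CLASS_MASK = np.zeros((25, 16), dtype=float)
for _c1 in range(5):
    for _c2 in range(5):
        ok1 = np.isin(_G1, CODE_SETS[_c1])
        ok2 = np.isin(_G2, CODE_SETS[_c2])
        _CLASS_MASK[5 * _c1 + _c2] = (ok1 & ok2).astype(float)


def _state_probs(r):
    """(…, 16) probabilities of the phased configurations at ``r``."""
    r = np.asarray(r, dtype=float)[..., None]
    return ((1.0 - r) / 2.0) ** (2 - _K) * (r / 2.0) ** _K


def _ll10_classes(counts: np.ndarray, r) -> np.ndarray:
    """log10 likelihood of (P, 25) class counts at per-pair ``r``."""
    s = _state_probs(np.asarray(r, dtype=float)) @ _CLASS_MASK.T
    return xlogy(counts, s).sum(axis=1) / LN10


def _em_batch(class_counts: np.ndarray, max_iter: int = 200,
              tol: float = 1e-10):
    """Vectorised EM over (n_pairs, 25) observed-class count tables.

    Returns ``(r_hat, lod, n, r_phase)`` arrays; works for any mix of
    codominant and collapsed genotype codes.  The labelling of a marker's
    alleles is arbitrary, so the linkage phase is a nuisance: the EM runs
    over ``r in (0, 1)`` from both a coupling (0.25) and a repulsion
    (0.75) start, the better mode wins, and ``r_hat = min(r, 1-r)`` is
    reported (``r_phase`` keeps the unfolded value).
    """
    counts = np.asarray(class_counts, dtype=float)
    n = counts.sum(axis=1)
    mask_t = _CLASS_MASK.T  # (16, 25)
    k_mask_t = (_CLASS_MASK * _K).T

    def run(start):
        r = np.full(counts.shape[0], start)
        for _ in range(max_iter):
            p = _state_probs(r)                  # (P, 16)
            s = p @ mask_t                       # (P, 25)
            er = p @ k_mask_t
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(s > 0, er / np.where(s > 0, s, 1.0), 0.0)
            e_rec = (counts * ratio).sum(axis=1)
            r_new = np.clip(e_rec / (2.0 * np.maximum(n, 1)), 1e-9,
                            1.0 - 1e-9)
            delta = np.abs(r_new - r).max() if r.size else 0.0
            r = r_new
            if delta < tol:
                break
        return r

    # two EM starts cover coupling/repulsion modes; the boundaries are
    # checked explicitly because weakly informative collapsed pairs can
    # have a global mode at r ~ 0 or ~ 1 that EM approaches only slowly
    cands = [run(0.25), run(0.75),
             np.full(counts.shape[0], 1e-9),
             np.full(counts.shape[0], 1.0 - 1e-9)]
    lls = np.stack([_ll10_classes(counts, rc) for rc in cands])
    pick = np.argmax(lls, axis=0)
    r_phase = np.choose(pick, np.stack(cands))
    r_phase = np.where(np.minimum(r_phase, 1 - r_phase) <= 1e-8,
                       np.round(r_phase), r_phase)
    r_hat = np.minimum(r_phase, 1.0 - r_phase)
    lod = np.maximum(
        _ll10_classes(counts, r_phase)
        - _ll10_classes(counts, np.full_like(r_phase, 0.5)), 0.0)
    return r_hat, lod, n.astype(np.int64), r_phase


def _distance_variance(class_counts: np.ndarray, r_hat: np.ndarray,
                       h: float = 1e-4) -> np.ndarray:
    """Approximate Var(d_hat) of the Kosambi distance per pair.

    The empirical Fisher information ``sum_c n_c (d log p_c / dr)^2`` is
    evaluated at ``r_hat`` (clamped away from the boundaries) by numerical
    differentiation of the class probabilities; the delta method maps it
    through the Kosambi function, ``Var(d) = d'(r)^2 / I(r)``.
    """
    counts = np.asarray(class_counts, dtype=float)
    r_f = np.clip(np.asarray(r_hat, dtype=float), 0.01, 0.49)
    # evaluate at the better-supported phase; |d folding slope| = 1
    repulsion = _ll10_classes(counts, 1.0 - r_f) > _ll10_classes(counts, r_f)
    r = np.where(repulsion, 1.0 - r_f, r_f)
    mask_t = _CLASS_MASK.T
    s_hi = _state_probs(r + h) @ mask_t
    s_lo = _state_probs(r - h) @ mask_t
    s = _state_probs(r) @ mask_t
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(s > 0, (s_hi - s_lo) / (2 * h * np.where(s > 0, s,
                                                                  1.0)), 0.0)
    info = (counts * score**2).sum(axis=1)
    dprime = 100.0 / (1.0 - 4.0 * r_f**2)
    with np.errstate(divide="ignore"):
        return np.where(info > 0, dprime**2 / np.maximum(info, 1e-300),
                        np.inf)


def _class_counts_pair(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    both = (g1 != MISSING) & (g2 != MISSING)
    combo = 5 * g1[both].astype(np.int64) + g2[both].astype(np.int64)
    return np.bincount(combo, minlength=25)[None, :]


def _class_counts_all_pairs(codes: np.ndarray):
    """Observed-class counts (n_pairs, 25) for all i<j marker pairs."""
    m = codes.shape[0]
    x = [(codes == g).astype(np.float64) for g in range(5)]
    iu, ju = np.triu_indices(m, 1)
    counts = np.empty((len(iu), 25))
    for c1 in range(5):
        for c2 in range(5):
            t = x[c1] @ x[c2].T
            counts[:, 5 * c1 + c2] = t[iu, ju]
    return counts, iu, ju


def pairwise_distance_variance(codes: np.ndarray, r: np.ndarray
                               ) -> np.ndarray:
    """Symmetric matrix of Var(d_hat) for all marker pairs."""
    counts, iu, ju = _class_counts_all_pairs(codes)
    v = _distance_variance(counts, r[iu, ju])
    out = np.full(r.shape, np.inf)
    out[iu, ju] = v
    out[ju, iu] = v
    return out


def estimate_rf_f2(g1, g2, marker_a: str = "m1", marker_b: str = "m2",
                   max_iter: int = 200) -> PairwiseLinkage:
    """Maximum-likelihood recombination fraction for one F2 marker pair.

    ``g1``/``g2`` are genotype-code columns (one entry per individual) using
    the integer codes of :mod:`radmap.genotypes`.  Collapsed one-sided codes
    are handled by mixing over all compatible genotype configurations in the
    E-step.  Raises :class:`LinkageError` when fewer than two individuals
    are jointly genotyped or a column is monomorphic.
    """
    g1 = np.asarray(g1, dtype=np.int8)
    g2 = np.asarray(g2, dtype=np.int8)
    if g1.shape != g2.shape:
        raise LinkageError("genotype columns differ in length")
    both = (g1 != MISSING) & (g2 != MISSING)
    if both.sum() < 2:
        raise LinkageError("fewer than 2 jointly genotyped individuals")
    for g in (g1, g2):
        if len(set(g[both].tolist())) < 2:
            raise LinkageError("monomorphic genotype column")
    counts = _class_counts_pair(g1, g2)
    r, lod, n, _ = _em_batch(counts, max_iter=max_iter)
    return PairwiseLinkage(marker_a, marker_b, float(r[0]), float(lod[0]),
                           int(n[0]))


def grid_search_rf(g1, g2, step: float = 0.001) -> tuple[float, float]:
    """Brute-force likelihood-grid estimate of ``(r_hat, lod)``.

    Independent validation route: the joint-class probabilities are written
    directly from the classical F2 two-locus table rather than derived from
    the phased-configuration enumeration used by the EM fit.
    """
    g1 = np.asarray(g1, dtype=np.int8)
    g2 = np.asarray(g2, dtype=np.int8)
    both = (g1 != MISSING) & (g2 != MISSING)
    pairs: dict[tuple[int, int], int] = {}
    for a, b in zip(g1[both].tolist(), g2[both].tolist()):
        pairs[(a, b)] = pairs.get((a, b), 0) + 1

    def cell_probs(r):
        # classical 9-class F2 table
        t = np.empty((3, 3))
        t[0, 0] = t[2, 2] = (1 - r) ** 2 / 4
        t[0, 2] = t[2, 0] = r**2 / 4
        t[0, 1] = t[1, 0] = t[1, 2] = t[2, 1] = r * (1 - r) / 2
        t[1, 1] = ((1 - r) ** 2 + r**2) / 2
        return t

    def ll10(r):
        t = cell_probs(r)
        total = 0.0
        for (ca, cb), cnt in pairs.items():
            p = sum(t[u, v] for u in CODE_SETS[ca] for v in CODE_SETS[cb])
            if p <= 0:
                return -np.inf
            total += cnt * np.log10(p)
        return total

    # the allele labelling (phase) is arbitrary: search r over (0, 1) and
    # fold the best point onto [0, 0.5]
    grid = np.arange(0.0, 1.0 + step / 2, step)
    lls = np.array([ll10(r) for r in grid])
    best = int(np.argmax(lls))
    r_best = float(grid[best])
    return (min(r_best, 1.0 - r_best),
            float(max(lls[best] - ll10(0.5), 0.0)))


# ---------------------------------------------------------------------------
# All-pairs estimation
# ---------------------------------------------------------------------------

def _pair_tables_codominant(codes: np.ndarray) -> np.ndarray:
    """(3, 3, M, M) joint genotype counts for all marker pairs."""
    x = [(codes == g).astype(np.float64) for g in (A, H, B)]
    m = codes.shape[0]
    c = np.empty((3, 3, m, m))
    for i in range(3):
        for j in range(3):
            c[i, j] = x[i] @ x[j].T
    return c


def _em_codominant_matrix(c: np.ndarray, max_iter: int = 120):
    """EM on (3,3,M,M) count tables; closed-form update per iteration.

    Runs from coupling and repulsion starts over ``r in (0, 1)`` and folds
    the better mode onto [0, 0.5] (allele labels are arbitrary).
    """
    s1 = c[0, 1] + c[1, 0] + c[1, 2] + c[2, 1]
    s2 = c[0, 2] + c[2, 0]
    hh = c[1, 1]
    n = c.sum(axis=(0, 1))
    denom = 2.0 * np.maximum(n, 1.0)

    def run(start):
        r = np.full_like(n, start)
        for _ in range(max_iter):
            w = r * r / ((1.0 - r) ** 2 + r * r)
            r = np.clip((s1 + 2.0 * s2 + 2.0 * w * hh) / denom, 1e-9,
                        1.0 - 1e-9)
        return r

    def ll10(rv):
        rv = np.asarray(rv, dtype=float)
        p = np.empty_like(c)
        p[0, 0] = p[2, 2] = (1 - rv) ** 2 / 4
        p[0, 2] = p[2, 0] = rv**2 / 4
        p[0, 1] = p[1, 0] = p[1, 2] = p[2, 1] = rv * (1 - rv) / 2
        p[1, 1] = ((1 - rv) ** 2 + rv**2) / 2
        return xlogy(c, p).sum(axis=(0, 1)) / LN10

    cands = [run(0.25), run(0.75), np.full_like(n, 1e-9),
             np.full_like(n, 1.0 - 1e-9)]
    lls = np.stack([ll10(rc) for rc in cands])
    pick = np.argmax(lls, axis=0)
    r_phase = np.choose(pick, np.stack(cands))
    r_phase = np.where(np.minimum(r_phase, 1 - r_phase) <= 1e-8,
                       np.round(r_phase), r_phase)
    r = np.minimum(r_phase, 1.0 - r_phase)
    lod = np.maximum(ll10(r_phase) - ll10(np.full_like(r, 0.5)), 0.0)
    return r, lod, n.astype(np.int64)


def _independence_lod_from_tables(c: np.ndarray) -> np.ndarray:
    """G2 independence-test LOD, ``G2 / (2 ln 10)``, from (K,K,M,M) tables."""
    n = c.sum(axis=(0, 1))
    row = c.sum(axis=1)         # (K, M, M)
    col = c.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = row[:, None] * col[None, :] / np.maximum(n, 1.0)
        term = xlogy(c, c) - xlogy(c, np.where(e > 0, e, 1.0))
    g2 = 2.0 * term.sum(axis=(0, 1))
    return np.maximum(g2, 0.0) / (2.0 * LN10)


def pairwise_linkage_matrices(matrix: GenotypeMatrix,
                              stat: str = "linkage"):
    """All-pairs ``(r_hat, grouping_lod, linkage_lod, n)`` square matrices.

    ``stat`` selects the grouping statistic: ``"linkage"`` (two-point
    likelihood-ratio LOD, the default) or ``"independence"`` (G2 test of
    the joint genotype table rescaled to a LOD; robust under segregation
    distortion but with a markedly heavier null tail).
    """
    codes = matrix.codes
    codominant = not np.isin(codes, (NOT_A, NOT_B)).any()
    if codominant:
        tables = _pair_tables_codominant(codes)
        r, lod, n = _em_codominant_matrix(tables)
        ind = (_independence_lod_from_tables(tables)
               if stat == "independence" else None)
    else:
        m = codes.shape[0]
        x = [(codes == g).astype(np.float64) for g in range(5)]
        iu, ju = np.triu_indices(m, 1)
        counts = np.empty((len(iu), 25))
        tables5 = np.empty((5, 5, m, m)) if stat == "independence" else None
        for c1 in range(5):
            for c2 in range(5):
                t = x[c1] @ x[c2].T
                counts[:, 5 * c1 + c2] = t[iu, ju]
                if tables5 is not None:
                    tables5[c1, c2] = t
        rv, lodv, nv, _ = _em_batch(counts)
        r = np.zeros((m, m))
        lod = np.zeros((m, m))
        n = np.zeros((m, m), dtype=np.int64)
        r[iu, ju] = rv; r[ju, iu] = rv
        lod[iu, ju] = lodv; lod[ju, iu] = lodv
        n[iu, ju] = nv; n[ju, iu] = nv
        ind = (_independence_lod_from_tables(tables5)
               if stat == "independence" else None)
    np.fill_diagonal(r, 0.0)
    np.fill_diagonal(lod, 0.0)
    grouping = ind if stat == "independence" else lod
    if stat == "independence":
        np.fill_diagonal(grouping, 0.0)
    return r, grouping, lod, n


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

def group_markers(linkages, lod_threshold: float = 6.0,
                  marker_ids=None) -> list[list[str]]:
    """Partition markers by single-linkage closure at ``lod >= threshold``.

    ``linkages`` is either a list of :class:`PairwiseLinkage` or a square
    LOD matrix (then ``marker_ids`` names its rows).  Returns groups sorted
    by decreasing size (ties by first marker id), members sorted by id;
    unlinked markers come back as singletons.
    """
    if isinstance(linkages, np.ndarray):
        if marker_ids is None:
            raise ValueError("marker_ids required with a LOD matrix")
        ids = list(marker_ids)
        iu, ju = np.nonzero(np.triu(linkages >= lod_threshold, 1))
        edges = [(ids[i], ids[j]) for i, j in zip(iu, ju)]
    else:
        ids = sorted({pl.marker_a for pl in linkages}
                     | {pl.marker_b for pl in linkages})
        edges = [(pl.marker_a, pl.marker_b) for pl in linkages
                 if pl.lod >= lod_threshold]
    parent = {m: m for m in ids}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    comps: dict[str, list[str]] = {}
    for m in ids:
        comps.setdefault(find(m), []).append(m)
    groups = [sorted(v) for v in comps.values()]
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups


# ---------------------------------------------------------------------------
# Ordering (regression-mapping style WLS with ripple)
# ---------------------------------------------------------------------------

@dataclass
class LinkageGroupResult:
    """One ordered linkage group with cumulative Kosambi positions."""

    group_id: str
    marker_ids: list[str]
    positions: np.ndarray
    postponed: list[str] = field(default_factory=list)
    unplaced: list[str] = field(default_factory=list)

    @property
    def length_cm(self) -> float:
        return float(self.positions[-1]) if len(self.positions) else 0.0

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


class _WlsOrderFitter:
    """Weighted least-squares scorer for candidate marker orders.

    Distances between placed markers are the multipoint-adjusted interval
    lengths solving ``min sum_ij w_ij (d_ij - |x_i - x_j|)^2`` over
    non-negative adjacent intervals, where ``d_ij`` are pairwise Kosambi
    distances and ``w_ij = LOD_ij`` for pairs passing the usability
    thresholds.
    """

    def __init__(self, dist: np.ndarray, weight: np.ndarray,
                 usable: np.ndarray):
        self.dist = dist
        self.weight = weight
        self.usable = usable

    def fit(self, order: np.ndarray):
        """Return ``(intervals, sse, n_pairs)`` for an index order."""
        m = len(order)
        if m < 2:
            return np.zeros(0), 0.0, 0
        ri, rj = np.triu_indices(m, 1)
        oi, oj = order[ri], order[rj]
        keep = self.usable[oi, oj]
        ri, rj, oi, oj = ri[keep], rj[keep], oi[keep], oj[keep]
        if len(ri) == 0:
            return np.zeros(m - 1), np.inf, 0
        d = self.dist[oi, oj]
        sw = np.sqrt(self.weight[oi, oj])
        k = np.arange(m - 1)
        a = ((k >= ri[:, None]) & (k < rj[:, None])).astype(float)
        x, rnorm = nnls(a * sw[:, None], d * sw)
        return x, float(rnorm**2), len(d)

    def objective(self, order: np.ndarray) -> float:
        """Normalised goodness of fit (weighted SSE per pair used)."""
        _, sse, npairs = self.fit(order)
        return sse / npairs if npairs else np.inf


def _ripple_inplace(order: np.ndarray, window: int, fitter: _WlsOrderFitter,
                    lo: int | None = None, hi: int | None = None,
                    max_passes: int = 8) -> np.ndarray:
    """Window-permutation improvement over window start range [lo, hi]."""
    m = len(order)
    if window > m:
        return order
    lo = 0 if lo is None else max(lo, 0)
    hi = m - window if hi is None else min(hi, m - window)
    best = fitter.objective(order)
    for _ in range(max_passes):
        improved = False
        for s in range(lo, hi + 1):
            seg = order[s:s + window].copy()
            for perm in itertools.permutations(range(window)):
                if perm == tuple(range(window)):
                    continue
                cand = order.copy()
                cand[s:s + window] = seg[list(perm)]
                obj = fitter.objective(cand)
                if obj < best - 1e-12:
                    order, best = cand, obj
                    improved = True
                    seg = order[s:s + window].copy()
        if not improved:
            break
    return order


def ripple(order: list, window: int = 3, objective=None) -> list:
    """Exhaustive sliding-window permutation polish of a marker order.

    All permutations of each window of ``window`` consecutive markers are
    scored with ``objective`` (lower is better) and the best kept, repeating
    until no window improves.  A window larger than the order is a no-op
    with a warning.
    """
    if objective is None:
        raise ValueError("an objective callable is required")
    order = list(order)
    if window > len(order):
        warnings.warn("ripple window exceeds order length; returning order "
                      "unchanged", stacklevel=2)
        return order
    best = objective(order)
    improved = True
    while improved:
        improved = False
        for s in range(len(order) - window + 1):
            seg = order[s:s + window]
            for perm in itertools.permutations(seg):
                if list(perm) == seg:
                    continue
                cand = order[:s] + list(perm) + order[s + window:]
                obj = objective(cand)
                if obj < best - 1e-12:
                    order, best = cand, obj
                    improved = True
                    break
    return order


def _order_group(indices: np.ndarray, ids: np.ndarray, r: np.ndarray,
                 lod: np.ndarray, var_d: np.ndarray, *, max_rf: float,
                 min_lod: float, jump_threshold: float, ripple_window: int,
                 group_id: str) -> LinkageGroupResult:
    """Order the markers whose global indices are ``indices``.

    Pairs enter the distance fit when ``r <= max_rf`` and
    ``LOD >= min_lod``; they are weighted by the inverse variance of their
    Kosambi distance estimate, which puts the goodness-of-fit measure on
    the chi-square scale the jump threshold assumes (a well-fitting pair
    contributes ~1) and is LOD-proportional at fixed ``r``.
    """
    idx = np.asarray(indices)
    m = len(idx)
    rs = r[np.ix_(idx, idx)]
    ls = lod[np.ix_(idx, idx)]
    vs = var_d[np.ix_(idx, idx)]
    usable = (rs <= max_rf) & (ls >= min_lod) & np.isfinite(vs) & (vs > 0)
    np.fill_diagonal(usable, False)
    if not usable.any():
        raise LinkageError(
            f"group {group_id}: no marker pair satisfies r <= {max_rf} "
            f"and LOD >= {min_lod}")
    dist = np.zeros_like(rs)
    dist[usable] = kosambi_cm(np.minimum(rs[usable], 0.499999))
    weight = np.where(usable, 1.0 / np.where(usable, vs, 1.0), 0.0)
    fitter = _WlsOrderFitter(dist, weight, usable)

    # seed with the most strongly linked usable pair (ties: lexicographic)
    masked = np.where(usable, ls, -np.inf)
    best_flat = np.argmax(masked)
    i0, j0 = np.unravel_index(best_flat, masked.shape)
    if ids[idx[i0]] > ids[idx[j0]]:
        i0, j0 = j0, i0
    order = np.array([i0, j0])

    info = weight.sum(axis=1)
    rest = [k for k in range(m) if k not in (i0, j0)]
    rest.sort(key=lambda k: (-info[k], ids[idx[k]]))
    unplaced: list[str] = []
    postponed_idx: list[int] = []
    placed_round2: list[str] = []

    def try_insert(k: int, current: np.ndarray):
        if not usable[k, current].any():
            return None, None
        base_obj = fitter.objective(current)
        best_obj, best_order = np.inf, None
        for slot in range(len(current) + 1):
            cand = np.insert(current, slot, k)
            obj = fitter.objective(cand)
            if obj < best_obj - 1e-12:
                best_obj, best_order = obj, cand
        jump = best_obj - base_obj
        return best_order, jump

    def local_ripple(current: np.ndarray, k: int) -> np.ndarray:
        pos = int(np.nonzero(current == k)[0][0])
        return _ripple_inplace(current, ripple_window, fitter,
                               lo=pos - ripple_window + 1, hi=pos)

    deferred: list[int] = []
    queue = list(rest)
    while queue:
        k = queue.pop(0)
        cand, jump = try_insert(k, order)
        if cand is None:
            deferred.append(k)
            continue
        if jump is not None and jump > jump_threshold:
            postponed_idx.append(k)
            continue
        order = local_ripple(cand, k)
    # markers with no usable link to the seed chain: one retry now that
    # more markers are placed
    for k in deferred:
        cand, jump = try_insert(k, order)
        if cand is None:
            unplaced.append(ids[idx[k]])
        elif jump is not None and jump > jump_threshold:
            postponed_idx.append(k)
        else:
            order = local_ripple(cand, k)
    # second round for postponed markers
    for k in postponed_idx:
        cand, jump = try_insert(k, order)
        if cand is None or (jump is not None and jump > jump_threshold):
            unplaced.append(ids[idx[k]])
        else:
            order = local_ripple(cand, k)
            placed_round2.append(ids[idx[k]])

    order = _ripple_inplace(order, ripple_window, fitter)
    intervals, _, _ = fitter.fit(order)
    positions = np.concatenate([[0.0], np.cumsum(intervals)])
    # canonical orientation: first marker id < last marker id
    ordered_ids = [ids[idx[k]] for k in order]
    if ordered_ids[0] > ordered_ids[-1]:
        ordered_ids = ordered_ids[::-1]
        positions = positions[-1] - positions[::-1]
    return LinkageGroupResult(group_id, ordered_ids, positions,
                              postponed=sorted(placed_round2),
                              unplaced=sorted(unplaced))


def order_markers(matrix: GenotypeMatrix, marker_ids=None, *,
                  max_rf: float = 0.400, min_lod: float = 1.0,
                  jump_threshold: float = 5.00, ripple_window: int = 3,
                  group_id: str = "LG1") -> LinkageGroupResult:
    """Order one linkage group's markers and assign Kosambi positions.

    ``marker_ids`` restricts the matrix to a subset (default: all markers).
    """
    if marker_ids is not None:
        sel = [matrix.marker_index(mid) for mid in marker_ids]
        matrix = matrix.take_markers(sel)
    if matrix.n_markers < 2:
        raise LinkageError("a group needs at least 2 markers to order")
    r, _, lod, _ = pairwise_linkage_matrices(matrix)
    var_d = pairwise_distance_variance(matrix.codes, r)
    return _order_group(np.arange(matrix.n_markers), matrix.marker_ids, r,
                        lod, var_d, max_rf=max_rf, min_lod=min_lod,
                        jump_threshold=jump_threshold,
                        ripple_window=ripple_window, group_id=group_id)


# ---------------------------------------------------------------------------
# Map container and summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MapSummary:
    n_groups: int
    n_markers: int
    total_cm: float
    mean_spacing_cm: float
    max_gap_cm: float
    max_gap_group: str
    n_cosegregating: int
    pct_cosegregating: float


@dataclass
class GeneticMap:
    """An ordered collection of linkage groups."""

    groups: list[LinkageGroupResult]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_markers(self) -> int:
        return sum(g.n_markers for g in self.groups)

    @property
    def total_cm(self) -> float:
        return float(sum(g.length_cm for g in self.groups))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g.group_id, rank + 1, mid, round(float(pos), 2))
            for g in self.groups
            for rank, (mid, pos) in enumerate(zip(g.marker_ids, g.positions))
        ]
        return pd.DataFrame(rows, columns=["group", "rank", "marker_id",
                                           "position_cM"])

    def summary(self, coseg_tol: float = 1e-6) -> MapSummary:
        return map_summary(self, coseg_tol=coseg_tol)


def map_summary(gmap: GeneticMap, coseg_tol: float = 1e-6) -> MapSummary:
    """Whole-map statistics: size, spacing, largest gap, co-segregation.

    Mean spacing is ``total_cM / (n_markers - n_groups)`` (the number of
    inter-marker intervals).  A marker co-segregates when its distance to
    the preceding marker in map order is zero (within ``coseg_tol`` cM).
    """
    if not gmap.groups:
        raise ValueError("empty map")
    n_groups = gmap.n_groups
    n_markers = gmap.n_markers
    total = gmap.total_cm
    mean_spacing = (total / (n_markers - n_groups)
                    if n_markers > n_groups else float("nan"))
    max_gap, max_gap_group = 0.0, gmap.groups[0].group_id
    n_coseg = 0
    for g in gmap.groups:
        gaps = np.diff(g.positions)
        if len(gaps):
            gm = float(gaps.max())
            if gm > max_gap:
                max_gap, max_gap_group = gm, g.group_id
            n_coseg += int((gaps <= coseg_tol).sum())
    return MapSummary(
        n_groups=n_groups, n_markers=n_markers, total_cm=total,
        mean_spacing_cm=mean_spacing, max_gap_cm=max_gap,
        max_gap_group=max_gap_group, n_cosegregating=n_coseg,
        pct_cosegregating=100.0 * n_coseg / n_markers if n_markers else 0.0,
    )


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------

class LinkageMapModel:
    """Genetic-map construction model for an F2 genotype matrix.

    Parameters
    ----------
    matrix : GenotypeMatrix
        QC-filtered marker-by-individual genotypes.
    grouping_lod : float
        LOD threshold for single-linkage grouping (default 6.0).
    grouping_stat : {"linkage", "independence"}
        Grouping statistic; see :func:`pairwise_linkage_matrices`.
    max_rf, min_lod : float
        Pair-usability thresholds for the ordering fit (defaults 0.400, 1.0).
    jump_threshold : float
        Maximum tolerated increase of the normalised goodness of fit when a
        marker is inserted (default 5.00); offenders are retried in a second
        round and otherwise reported unplaced.
    ripple_window : int
        Window size of the permutation polish applied after each insertion.
    """

    def __init__(self, matrix: GenotypeMatrix, *, grouping_lod: float = 6.0,
                 grouping_stat: str = "linkage", max_rf: float = 0.400,
                 min_lod: float = 1.0, jump_threshold: float = 5.00,
                 ripple_window: int = 3):
        if grouping_stat not in ("linkage", "independence"):
            raise ValueError(f"unknown grouping statistic {grouping_stat!r}")
        self.matrix = matrix
        self.grouping_lod = grouping_lod
        self.grouping_stat = grouping_stat
        self.max_rf = max_rf
        self.min_lod = min_lod
        self.jump_threshold = jump_threshold
        self.ripple_window = ripple_window

    def fit(self) -> "LinkageMapResults":
        mat = self.matrix
        r, grouping, lod, n = pairwise_linkage_matrices(
            mat, stat=self.grouping_stat)
        partitions = group_markers(grouping, self.grouping_lod,
                                   marker_ids=mat.marker_ids)
        id_to_idx = {mid: i for i, mid in enumerate(mat.marker_ids)}
        ungrouped = [g[0] for g in partitions if len(g) == 1]
        results = []
        var_full = np.full_like(r, np.inf)
        for members in (g for g in partitions if len(g) > 1):
            idx = np.array([id_to_idx[mid] for mid in members])
            var_full[np.ix_(idx, idx)] = pairwise_distance_variance(
                mat.codes[idx], r[np.ix_(idx, idx)])
            try:
                res = _order_group(
                    idx, mat.marker_ids, r, lod, var_full,
                    max_rf=self.max_rf,
                    min_lod=self.min_lod, jump_threshold=self.jump_threshold,
                    ripple_window=self.ripple_window, group_id="?")
            except LinkageError:
                res = LinkageGroupResult("?", [], np.zeros(0),
                                         unplaced=sorted(members))
            results.append(res)
        # name groups by decreasing map length, then marker count
        results.sort(key=lambda g: (-g.length_cm, -g.n_markers,
                                    g.marker_ids[:1]))
        for i, g in enumerate(results, start=1):
            g.group_id = f"LG{i}"
        return LinkageMapResults(self, GeneticMap(results), ungrouped,
                                 pairwise=(r, lod, n))


class LinkageMapResults:
    """Fitted genetic map plus diagnostics.

    Attributes
    ----------
    map : GeneticMap
    ungrouped : list of markers not linked to any other at the grouping LOD
    pairwise : (r_hat, lod, n) square matrices over the input markers
    """

    def __init__(self, model: LinkageMapModel, genetic_map: GeneticMap,
                 ungrouped: list[str], pairwise=None):
        self.model = model
        self.map = genetic_map
        self.ungrouped = ungrouped
        self.pairwise = pairwise

    @property
    def n_unplaced(self) -> int:
        return sum(len(g.unplaced) for g in self.map.groups)

    def to_frame(self) -> pd.DataFrame:
        return self.map.to_frame()

    def pairwise_frame(self) -> pd.DataFrame:
        """Long-format pairwise linkage cache (upper triangle)."""
        r, lod, n = self.pairwise
        ids = self.model.matrix.marker_ids
        iu, ju = np.triu_indices(len(ids), 1)
        return pd.DataFrame({
            "marker_a": ids[iu], "marker_b": ids[ju],
            "r_hat": np.round(r[iu, ju], 6),
            "lod": np.round(lod[iu, ju], 4),
            "n_informative": n[iu, ju],
        })

    def summary(self) -> str:
        s = self.map.summary()
        lines = [
            "Linkage map (two-point regression mapping, Kosambi distances)",
            "=" * 62,
            f"grouping LOD threshold     {self.model.grouping_lod:>10.2f}"
            f"  ({self.model.grouping_stat})",
            f"ordering max rf / min LOD  {self.model.max_rf:>10.3f} /"
            f" {self.model.min_lod:.2f}",
            f"goodness-of-fit jump       "
            f"{self.model.jump_threshold:>10.2f}",
            "-" * 62,
            f"linkage groups             {s.n_groups:>10d}",
            f"mapped markers             {s.n_markers:>10d}",
            f"ungrouped / unplaced       {len(self.ungrouped):>10d} /"
            f" {self.n_unplaced}",
            f"total map length (cM)      {s.total_cm:>10.1f}",
            f"mean marker spacing (cM)   {s.mean_spacing_cm:>10.2f}",
            f"largest gap (cM)           {s.max_gap_cm:>10.1f}"
            f"  on {s.max_gap_group}",
            f"co-segregating markers     {s.n_cosegregating:>10d}"
            f"  ({s.pct_cosegregating:.1f}%)",
            "-" * 62,
        ]
        for g in self.map.groups:
            lines.append(f"{g.group_id:<6} {g.n_markers:>4d} markers "
                         f"{g.length_cm:>7.1f} cM"
                         + (f"  ({len(g.unplaced)} unplaced)"
                            if g.unplaced else ""))
        return "\n".join(lines)
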