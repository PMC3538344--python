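"""Genotype codes and the marker-by-individual genotype container.

An F2 intercross of two outbred-ish parental lines segregates, at a fully
codominant marker, into the three genotype classes ``a`` (homozygous for the
first parental allele), ``h`` (heterozygous) and ``b`` (homozygous for the
second parental allele) in the Mendelian 1:2:1 ratio.  Markers where only one
parent was heterozygous carry one-sided information: one homozygote class is
distinguishable from the union of the other two.  Following the common
locus-file convention, those collapsed observations are coded ``c``
("not a", i.e. h-or-b) and ``d`` ("not b", i.e. a-or-h).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# Integer genotype codes used throughout the package.
A, H, B = 0, 1, 2          # fully observed F2 genotypes
NOT_A, NOT_B = 3, 4        # collapsed classes {h,b} and {a,h}
MISSING = -1

#: genotype values (0,1,2 = count of the second parental allele) compatible
#: with each observed code
CODE_SETS: dict[int, tuple[int, ...]] = {
    A: (0,),
    H: (1,),
    B: (2,),
    NOT_A: (1, 2),
    NOT_B: (0, 1),
}

CODE_TO_CHAR = {A: "a", H: "h", B: "b", NOT_A: "c", NOT_B: "d", MISSING: "-"}
CHAR_TO_CODE = {v: k for k, v in CODE_TO_CHAR.items()}

#: the six informative parental segregation types plus the uninformative case
SEGREGATION_TYPES = ("aaxbb", "aaxab", "abxaa", "abxab", "abxac", "abxcc")

#: types whose F2 genotypes are fully distinguishable (codominant a/h/b)
CODOMINANT_TYPES = frozenset({"aaxbb", "abxab", "abxac", "abxcc"})
#: one-sided types and the collapsed code they produce
ONE_SIDED_TYPES = {"aaxab": NOT_A, "abxaa": NOT_B}


def classify_segregation_type(parent1: str, parent2: str) -> str:
    """Classify a marker's parental segregation type from two genotypes.

    Parameters are two-character allele strings such as ``"aa"``, ``"ab"``,
    ``"ac"``.  Returns one of :data:`SEGREGATION_TYPES` or ``"uninformative"``
    for markers that cannot segregate in the F2 (both parents homozygous for
    the same allele).  Hom-by-het configurations are canonicalised onto the
    listed het-first or hom-first form with the same information content.
    """
    for p in (parent1, parent2):
        if not isinstance(p, str) or len(p) != 2 or "-" in p:
            raise ValueError(f"missing or malformed parental genotype: {p!r}")
    a1, a2 = set(parent1), set(parent2)
    het1, het2 = len(a1) == 2, len(a2) == 2
    shared = a1 & a2
    if not het1 and not het2:
        return "uninformative" if a1 == a2 else "aaxbb"
    if het1 and not het2:
        return "abxaa" if shared else "abxcc"
    if not het1 and het2:
        return "aaxab" if shared else "abxcc"
    # both heterozygous
    if a1 == a2:
        return "abxab"
    if shared:
        return "abxac"
    return "abxcc"  # ab x cd carries the same F2 information as ab x cc


@dataclass
class GenotypeMatrix:
    """Marker-by-individual genotype codes with per-allele read depths.

    Attributes
    ----------
    marker_ids, individual_ids : object ndarrays of str
    seg_types : ndarray of str, one segregation type per marker
    codes : int8 ndarray (markers, individuals) of genotype codes
    depth_a, depth_b : int32 ndarrays, reads supporting each allele per call
    """

    marker_ids: np.ndarray
    individual_ids: np.ndarray
    seg_types: np.ndarray
    codes: np.ndarray
    depth_a: np.ndarray = field(default=None)  # type: ignore[assignment]
    depth_b: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.seg_types = np.asarray(self.seg_types, dtype=object)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        m, n = self.codes.shape
        if self.depth_a is None:
            self.depth_a = np.zeros((m, n), dtype=np.int32)
        if self.depth_b is None:
            self.depth_b = np.zeros((m, n), dtype=np.int32)
        self.depth_a = np.asarray(self.depth_a, dtype=np.int32)
        self.depth_b = np.asarray(self.depth_b, dtype=np.int32)
        if not (len(self.marker_ids) == len(self.seg_types) == m):
            raise ValueError("marker metadata length mismatch")
        if len(self.individual_ids) != n:
            raise ValueError("individual id length mismatch")
        for d in (self.depth_a, self.depth_b):
            if d.shape != (m, n):
                raise ValueError("depth array shape mismatch")
            if (d < 0).any():
                raise ValueError("negative read depths")

    # -- basic queries -----------------------------------------------------
    @property
    def n_markers(self) -> int:
        return self.codes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[1]

    @property
    def total_depth(self) -> np.ndarray:
        return self.depth_a + self.depth_b

    def n_genotyped(self) -> np.ndarray:
        """Number of non-missing calls per marker."""
        return (self.codes != MISSING).sum(axis=1)

    def genotype_counts(self) -> np.ndarray:
        """(markers, 3) counts of a/h/b calls (collapsed codes not counted)."""
        out = np.zeros((self.n_markers, 3), dtype=np.int64)
        for g in (A, H, B):
            out[:, g] = (self.codes == g).sum(axis=1)
        return out

    # -- subsetting --------------------------------------------------------
    def take_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.marker_ids[idx], self.individual_ids, self.seg_types[idx],
            self.codes[idx], self.depth_a[idx], self.depth_b[idx],
        )

    def take_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.marker_ids, self.individual_ids[idx], self.seg_types,
            self.codes[:, idx], self.depth_a[:, idx], self.depth_b[:, idx],
        )

    def marker_index(self, marker_id: str) -> int:
        pos = np.nonzero(self.marker_ids == marker_id)[0]
        if len(pos) == 0:
            raise KeyError(marker_id)
        return int(pos[0])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.marker_ids.copy(), self.individual_ids.copy(),
            self.seg_types.copy(), self.codes.copy(),
            self.depth_a.copy(), self.depth_b.copy(),
        )

    def __eq__(self, other) -> bool:  # value equality, used in round-trips
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.marker_ids, other.marker_ids)
            and np.array_equal(self.individual_ids, other.individual_ids)
            and np.array_equal(self.seg_types, other.seg_types)
            and np.array_equal(self.codes, other.codes)
            and np.array_equal(self.depth_a, other.depth_a)
            and np.array_equal(self.depth_b, other.depth_b)
        )
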