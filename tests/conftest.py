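import numpy as np
import pytest

from radmap.genotypes import GenotypeMatrix
from radmap.sim import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_clean_dataset():
    """Error-free, complete-data cross: 3 groups x 10 codominant markers."""
    cfg = SimConfig(
        n_groups=3, markers_per_group=[10, 10, 10],
        group_lengths_cm=[50.0, 50.0, 50.0], n_f2=200,
        fixed_diff_fraction=1.0, missing_rate=0.0,
        genotyping_error_rate=0.0, mutation_rate=0.0,
        distortion_blocks=[], marker_placement="even", seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def messy_dataset():
    """Small cross with one-sided markers, missingness and depth noise."""
    cfg = SimConfig(
        n_groups=2, markers_per_group=[8, 8],
        group_lengths_cm=[40.0, 40.0], n_f2=120,
        distortion_blocks=[], seed=7,
    )
    return simulate_dataset(cfg)


def simulate_marker_pair(r, n, rng, collapse=(None, None)):
    """Joint F2 genotypes of one marker pair at recombination fraction r.

    ``collapse`` optionally collapses a column to a one-sided code:
    "not_a" (a vs c) or "not_b" (b vs d).
    """
    from radmap.genotypes import NOT_A, NOT_B, A, H, B
    gm, gp = rng.random(n) < 0.5, rng.random(n) < 0.5
    rec_m, rec_p = rng.random(n) < r, rng.random(n) < r
    g1 = (gm.astype(np.int8) + gp.astype(np.int8))
    g2 = ((gm ^ rec_m).astype(np.int8) + (gp ^ rec_p).astype(np.int8))
    out = []
    for g, mode in ((g1, collapse[0]), (g2, collapse[1])):
        g = g.copy()
        if mode == "not_a":
            g[np.isin(g, (H, B))] = NOT_A
        elif mode == "not_b":
            g[np.isin(g, (A, H))] = NOT_B
        out.append(g)
    return out[0], out[1]
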