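"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from oligoscope.simulate import CommunityDesign, generate_community, generate_env_table


@pytest.fixture(scope="session")
def env13():
    """Default 13-site two-transect environmental table."""
    return generate_env_table(13, seed=11)


@pytest.fixture(scope="session")
def small_community(env13):
    """Five error-free OTUs, one per occurrence scenario, with ground truth."""
    design = CommunityDesign(
        n_otus=5,
        reads_per_otu=(300, 900),
        error_rate=0.0,
        missing_tail_fraction=0.0,
        seed=17,
    )
    return generate_community(design, env13)


def brute_force_ct(presence: np.ndarray) -> tuple[float, float]:
    """Mean C/T scores by exhaustive enumeration over site pairs.

    Independent oracle: for every unordered oligotype pair and site pair,
    a C unit is a 2×2 checkerboard sub-matrix and a T unit a
    joint-presence/joint-absence site pair.
    """
    presence = np.asarray(presence) > 0
    n, m = presence.shape
    c_tot = t_tot = 0
    pairs = list(combinations(range(n), 2))
    for i, j in pairs:
        for s, u in combinations(range(m), 2):
            quad = (presence[i, s], presence[j, s], presence[i, u], presence[j, u])
            if quad in ((True, False, False, True), (False, True, True, False)):
                c_tot += 1
            if quad[0] and quad[1] and not (quad[2] or quad[3]):
                t_tot += 1
            if quad[2] and quad[3] and not (quad[0] or quad[1]):
                t_tot += 1
    return c_tot / len(pairs), t_tot / len(pairs)


def reference_mcl(weights: np.ndarray, inflation: float = 2.5,
                  max_iter: int = 300) -> list[set[int]]:
    """Plain dense expansion/inflation iteration (no pruning): oracle MCL.

    Written independently of the package implementation: self-loops equal
    to each node's maximum incident weight, column normalisation, iterate
    M <- normalise((M @ M) ** inflation) to a fixed point, then group
    columns by their attractor support.
    """
    m = weights.astype(float).copy()
    np.fill_diagonal(m, 0.0)
    loops = m.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(m, loops)
    m = m / m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        nxt = np.linalg.matrix_power(m, 2) ** inflation
        nxt = nxt / nxt.sum(axis=0, keepdims=True)
        if np.abs(nxt - m).max() < 1e-10:
            m = nxt
            break
        m = nxt
    n = m.shape[0]
    # nodes sharing an attractor (row with mass) belong together
    clusters: list[set[int]] = []
    for col in range(n):
        support = frozenset(np.flatnonzero(m[:, col] > 1e-6).tolist())
        for cl in clusters:
            if cl & support:
                cl.update(support | {col})
                break
        else:
            clusters.append(set(support) | {col})
    # merge transitively
    merged: list[set[int]] = []
    for cl in clusters:
        hit = [i for i, m2 in enumerate(merged) if m2 & cl]
        for i in reversed(hit):
            cl |= merged.pop(i)
        merged.append(cl)
    return merged
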