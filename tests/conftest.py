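import numpy as np
import pytest


def brute_force_upstream_counts(receiver: np.ndarray) -> np.ndarray:
    """Independent oracle: a_i = #cells whose receiver chain passes through i.

    Follows every cell's receiver chain to its outlet, incrementing each
    visited cell. O(N * path length); for test-sized grids only.
    """
    n = receiver.shape[0]
    counts = np.zeros(n, dtype=np.int64)
    for c in range(n):
        cur = c
        counts[cur] += 1
        while receiver[cur] != cur:
            cur = receiver[cur]
            counts[cur] += 1
    return counts


def mfd_dense_oracle(g: np.ndarray, domain, absorb_at_end: bool) -> np.ndarray:
    """Independent oracle for partitioned accumulation: dense linear solve.

    Builds the full N x N slope-proportional transfer matrix W (row c ->
    fractions given to each downhill neighbour) and solves
    a = seed + W^T a. Independent of the kernel's ordering logic.
    """
    from itertools import product

    shape = g.shape
    n = g.size
    gf = g.ravel()
    W = np.zeros((n, n))
    for c in range(n):
        idx = np.unravel_index(c, shape)
        fi = idx[domain.axis_flow]
        nf = shape[domain.axis_flow]
        if (fi == nf - 1) if absorb_at_end else (fi == 0):
            continue
        nbrs = []
        for off in product((-1, 0, 1), repeat=len(shape)):
            if all(o == 0 for o in off):
                continue
            nb = tuple(i + o for i, o in zip(idx, off))
            if not all(0 <= v < s for v, s in zip(nb, shape)):
                continue
            j = np.ravel_multi_index(nb, shape)
            dist = domain.spacing * np.sqrt(sum(o * o for o in off))
            s = (gf[c] - gf[j]) / dist
            if s > 0:
                nbrs.append((j, s))
        wsum = sum(s for _, s in nbrs)
        if wsum <= 0:
            continue
        for j, s in nbrs:
            W[c, j] = s / wsum
    seed = np.full(n, domain.spacing)
    a = np.linalg.solve(np.eye(n) - W.T, seed)
    return a.reshape(shape)


@pytest.fixture(scope="session")
def oracle_counts():
    return brute_force_upstream_counts


@pytest.fixture(scope="session")
def oracle_mfd():
    return mfd_dense_oracle
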