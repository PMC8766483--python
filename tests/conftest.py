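"""Shared fixtures and independent oracles for the test suite."""

import itertools

import numpy as np
import pytest

from phagenet import InteractionMatrix


def set_partitions(n):
    """All set partitions of range(n) as restricted-growth label lists."""

    def rec(prefix, mx):
        if len(prefix) == n:
            yield prefix
            return
        for v in range(mx + 2):
            yield from rec(prefix + [v], max(mx, v))

    yield from rec([0], 0)


def brute_force_qb(m: InteractionMatrix) -> float:
    """Exhaustive maximum of Barber modularity over all joint partitions."""
    A = np.asarray(m.cells, dtype=float)
    I = A.sum()
    B = A - np.outer(A.sum(axis=1), A.sum(axis=0)) / I
    nh, np_ = A.shape
    best = -np.inf
    for labels in set_partitions(nh + np_):
        hl = np.array(labels[:nh])
        pl = np.array(labels[nh:])
        best = max(best, B[hl[:, None] == pl[None, :]].sum() / I)
    return float(best)


@pytest.fixture
def two_block_matrix():
    """Block-diagonal matrix of two fully connected 3x2 blocks."""
    cells = np.zeros((6, 4), dtype=int)
    cells[:3, :2] = 1
    cells[3:, 2:] = 1
    return InteractionMatrix(
        tuple(f"h{i}" for i in range(6)), tuple(f"p{j}" for j in range(4)), cells
    )


@pytest.fixture
def nested_triangle():
    """3x3 strictly nested triangle: row degrees 3, 2, 1."""
    cells = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]])
    return InteractionMatrix(("h0", "h1", "h2"), ("p0", "p1", "p2"), cells)


def block_partition(m, n_blocks, host_sizes, phage_sizes):
    """Ground-truth partition for contiguous block-diagonal matrices."""
    from phagenet import ModulePartition

    host_assignment, phage_assignment = {}, {}
    h = p = 0
    for b in range(n_blocks):
        for _ in range(host_sizes[b]):
            host_assignment[m.host_ids[h]] = b
            h += 1
        for _ in range(phage_sizes[b]):
            phage_assignment[m.phage_ids[p]] = b
            p += 1
    return ModulePartition(host_assignment, phage_assignment, n_blocks, 0.0, 0.0)
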