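"""Shared fixtures and random-graph builders for the test suite."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from gfsnet.graph_io import WeightedGraph


def make_graph(W: np.ndarray, labels=None) -> WeightedGraph:
    W = np.asarray(W, dtype=float)
    labels = labels or tuple(f"R{i + 1}" for i in range(W.shape[0]))
    return WeightedGraph(tuple(labels), W)


def random_graph(rng: np.random.Generator, n: int, p: float | None = None,
                 weighted: bool = True, connected: bool = False) -> WeightedGraph:
    """Random symmetric zero-diagonal graph; optionally resampled until connected."""
    for _ in range(1000):
        q = p if p is not None else rng.uniform(0.2, 0.9)
        upper = rng.random((n, n)) < q
        W = np.triu(upper, k=1).astype(float)
        if weighted:
            W *= rng.uniform(0.5, 10.0, size=(n, n))
        W = W + W.T
        if not connected or _is_connected(W > 0):
            return make_graph(W)
    raise RuntimeError("failed to draw a connected graph")


def _is_connected(A: np.ndarray) -> bool:
    n = A.shape[0]
    seen = np.zeros(n, dtype=bool)
    seen[0] = True
    frontier = [0]
    while frontier:
        nxt = []
        for i in frontier:
            for j in np.flatnonzero(A[i]):
                if not seen[j]:
                    seen[j] = True
                    nxt.append(j)
        frontier = nxt
    return bool(seen.all())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def path3() -> WeightedGraph:
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 2] = 1.0
    return make_graph(W + W.T, ("a", "b", "c"))


@pytest.fixture
def path4() -> WeightedGraph:
    W = np.zeros((4, 4))
    W[0, 1] = W[1, 2] = W[2, 3] = 1.0
    return make_graph(W + W.T, ("a", "b", "c", "d"))


@pytest.fixture
def k2() -> WeightedGraph:
    return make_graph([[0.0, 5.0], [5.0, 0.0]], ("a", "b"))


@pytest.fixture
def star4() -> WeightedGraph:
    """Star K1,3 with the hub first."""
    W = np.zeros((4, 4))
    W[0, 1:] = 1.0
    return make_graph(W + W.T, ("hub", "l1", "l2", "l3"))
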