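"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by first principles (geodesic counting
via adjacency-matrix powers, all-subsets clique enumeration, fixed-point
iteration of the classical restart walk, alternating maximization for the
first canonical pair) without touching the library code paths it checks.
"""

from __future__ import annotations

import numpy as np


def distance_matrix(A: np.ndarray) -> np.ndarray:
    """All-pairs unweighted geodesic distances by layered reachability.

    A is a boolean adjacency matrix; unreachable pairs get +inf.
    """
    n = A.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reach = np.eye(n, dtype=bool)
    step = np.eye(n, dtype=bool)
    for length in range(1, n):
        step = (step.astype(np.int64) @ A.astype(np.int64)) > 0
        new = step & ~reach
        if not new.any():
            break
        dist[new] = length
        reach |= new
    return dist


def geodesic_counts(A: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """sigma[s, t] = number of shortest s-t paths.

    Walks of exactly the geodesic length are necessarily simple paths, so
    sigma is the corresponding entry of the d-th adjacency power.
    """
    n = A.shape[0]
    powers = [np.eye(n, dtype=np.int64)]
    Ai = A.astype(np.int64)
    for _ in range(n):
        powers.append(powers[-1] @ Ai)
    sigma = np.zeros((n, n), dtype=np.int64)
    for s in range(n):
        for t in range(n):
            d = dist[s, t]
            if np.isfinite(d):
                sigma[s, t] = powers[int(d)][s, t]
    return sigma


def brute_betweenness(A: np.ndarray) -> np.ndarray:
    """Betweenness by explicit geodesic counting over unordered pairs."""
    n = A.shape[0]
    dist = distance_matrix(A)
    sigma = geodesic_counts(A, dist)
    cb = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(dist[s, t]) or sigma[s, t] == 0:
                continue
            for i in range(n):
                if i in (s, t):
                    continue
                if dist[s, i] + dist[i, t] == dist[s, t]:
                    cb[i] += sigma[s, i] * sigma[i, t] / sigma[s, t]
    return cb


def brute_closeness(A: np.ndarray) -> np.ndarray:
    """Closeness with reachable-set scaling: ((r-1)/sum d) * ((r-1)/(n-1))."""
    n = A.shape[0]
    dist = distance_matrix(A)
    cc = np.zeros(n)
    for i in range(n):
        finite = np.isfinite(dist[:, i])
        r = int(finite.sum())  # includes i itself
        if r <= 1:
            continue
        total = dist[finite, i].sum()
        cc[i] = ((r - 1) / total) * ((r - 1) / (n - 1))
    return cc


def brute_maximal_clique_counts(A: np.ndarray) -> np.ndarray:
    """Per-node maximal-clique membership by checking every vertex subset."""
    n = A.shape[0]
    adj = [int(sum(1 << j for j in range(n) if A[i, j])) for i in range(n)]
    counts = np.zeros(n)
    for S in range(1, 1 << n):
        members = [i for i in range(n) if S >> i & 1]
        if any((adj[i] & S) != S ^ (1 << i) for i in members):
            continue  # not complete
        if any((adj[v] & S) == S for v in range(n) if not S >> v & 1):
            continue  # extendable, not maximal
        counts[members] += 1
    return counts


def classical_rwr(P: np.ndarray, c: float, start: int, tol: float = 1e-15,
                  max_iter: int = 100_000) -> np.ndarray:
    """Fixed-point iteration of the 1-hop restart walk r <- c P^T r + (1-c) r0."""
    n = P.shape[0]
    r0 = np.zeros(n)
    r0[start] = 1.0
    r = r0.copy()
    for _ in range(max_iter):
        r_next = c * (P.T @ r) + (1 - c) * r0
        if np.abs(r_next - r).sum() < tol:
            return r_next
        r = r_next
    return r


def brute_first_cca(X: np.ndarray, Y: np.ndarray, n_iter: int = 2000) -> float:
    """Largest canonical correlation by alternating regression.

    Holding one composite fixed, the optimal coefficients of the other
    block are its least-squares regression on that composite; alternating
    converges to the first canonical pair. Independent of the whitened-SVD
    route used by the library.
    """
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    rng = np.random.default_rng(12345)
    best = 0.0
    for _ in range(5):  # multistart to dodge bad initializations
        a = rng.standard_normal(Xc.shape[1])
        b = rng.standard_normal(Yc.shape[1])
        for _ in range(n_iter):
            u = Xc @ a
            b, *_ = np.linalg.lstsq(Yc, u, rcond=None)
            nb = np.linalg.norm(b)
            if nb > 0:  # renormalize: regression shrinks the scale each pass
                b = b / nb
            v = Yc @ b
            a, *_ = np.linalg.lstsq(Xc, v, rcond=None)
            na = np.linalg.norm(a)
            if na > 0:
                a = a / na
        u, v = Xc @ a, Yc @ b
        denom = np.linalg.norm(u) * np.linalg.norm(v)
        if denom > 0:
            best = max(best, abs(float(u @ v) / denom))
    return best
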