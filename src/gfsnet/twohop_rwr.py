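"""2-hop random walk with restart (2hopRWR) and the 2hop-connectivity score.

A walker started at node v_i either restarts to v_i (probability ``1 - c``)
or takes a step (probability ``c``) drawn from a mixture of the 1-step
transition operator P — the weight-normalized adjacency, P = D^{-1} W — and
the 2-step operator P². The mixture fractions alpha1/alpha2 are, per node,
the share of 1-hop neighbors among all 1-hop plus exact-2-hop neighbors
(alpha1 + alpha2 = 1), so sparse neighborhoods lean on second-order
structure. The stationary distribution exists for every c < 1 because the
mixed step operator is row-stochastic (spectral radius of the damped
operator is at most c): it equals

    r_inf = (1 - c) (I - c (a1 P^T + a2 (P²)^T))^{-1} r_0,

which this module exposes both as a fixed-point iteration and as the exact
linear solve, their agreement being the executable form of the convergence
theorem. Stacking the stationary vectors of all starts gives the
steady-state probability matrix Pi; 2hop-connectivity aggregates Pi into a
per-node importance score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from gfsnet.graph_io import WeightedGraph
from gfsnet.local_features import FeatureVector

__all__ = [
    "TransitionModel",
    "WalkConfig",
    "SteadyStateMatrix",
    "ConvergenceError",
    "build_transition_model",
    "iterate_2hoprwr",
    "closed_form_steady_state",
    "steady_state_matrix",
    "s2hop_scores",
]

AlphaMode = Literal["per_node", "scalar"]
ScoreMode = Literal["column_sum", "row_sum"]


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to reach tolerance within the cap."""

    def __init__(self, iterations: int, residual: float, tol: float) -> None:
        self.iterations = iterations
        self.residual = residual
        super().__init__(
            f"2hopRWR did not converge in {iterations} iterations "
            f"(L1 residual {residual:.3e}, tolerance {tol:.3e})"
        )


@dataclass(frozen=True)
class WalkConfig:
    """Parameters of the 2hopRWR.

    c
        Continuation probability in [0, 1); ``1 - c`` is the restart
        probability. Default 0.85 (the common restart convention).
    tol
        L1 convergence tolerance of the fixed-point iteration.
    max_iter
        Iteration cap; the geometric bound ``residual <= 2 c^t`` makes 1000
        ample for any c bounded away from 1.
    alpha_mode
        ``per_node`` derives alpha1 from each node's 1-hop/2-hop neighbor
        counts; ``scalar`` uses one global ``scalar_alpha1``.
    """

    c: float = 0.85
    tol: float = 1e-10
    max_iter: int = 1000
    alpha_mode: AlphaMode = "per_node"
    scalar_alpha1: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.c < 1.0):
            raise ValueError(f"continuation probability c must be in [0, 1), got {self.c}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.alpha_mode not in ("per_node", "scalar"):
            raise ValueError(f"unknown alpha_mode {self.alpha_mode!r}")
        if self.alpha_mode == "scalar":
            if self.scalar_alpha1 is None:
                raise ValueError("scalar alpha mode requires scalar_alpha1")
            if not (0.0 <= self.scalar_alpha1 <= 1.0):
                raise ValueError("scalar_alpha1 must be in [0, 1]")


@dataclass(frozen=True)
class TransitionModel:
    """Row-stochastic 1-step and 2-step operators with hop-mixing fractions.

    ``P`` row-normalizes the weight matrix by weighted degree (isolated
    nodes get a self-loop row so P stays stochastic); ``P2 = P @ P``;
    ``alpha1[i] + alpha2[i] = 1`` for every node.
    """

    labels: tuple[str, ...]
    P: np.ndarray
    P2: np.ndarray
    alpha1: np.ndarray
    alpha2: np.ndarray

    def __post_init__(self) -> None:
        for name, M in (("P", self.P), ("P2", self.P2)):
            if np.any(M < -1e-15):
                raise ValueError(f"{name} has negative entries")
            if np.max(np.abs(M.sum(axis=1) - 1.0)) > 1e-12:
                raise ValueError(f"rows of {name} do not sum to 1")
        if np.max(np.abs(self.alpha1 + self.alpha2 - 1.0)) > 1e-12:
            raise ValueError("alpha1 + alpha2 must equal 1 per node")

    @property
    def n_nodes(self) -> int:
        return self.P.shape[0]

    def mixed_operator(self, cfg: WalkConfig) -> np.ndarray:
        """The row-stochastic one-step mixture A = diag(a1) P + diag(a2) P²
        (scalar mode: a1 P + a2 P²)."""
        if cfg.alpha_mode == "scalar":
            a1 = float(cfg.scalar_alpha1)  # validated non-None by WalkConfig
            return a1 * self.P + (1.0 - a1) * self.P2
        return self.alpha1[:, None] * self.P + self.alpha2[:, None] * self.P2


@dataclass(frozen=True)
class SteadyStateMatrix:
    """Pi[i, j] = stationary probability of finding at v_j a walk started at v_i."""

    labels: tuple[str, ...]
    Pi: np.ndarray

    def __post_init__(self) -> None:
        Pi = np.asarray(self.Pi, dtype=float)
        object.__setattr__(self, "Pi", Pi)
        if np.any(Pi < -1e-12) or np.any(Pi > 1 + 1e-12):
            raise ValueError("steady-state probabilities outside [0, 1]")
        if np.max(np.abs(Pi.sum(axis=1) - 1.0)) > 1e-8:
            raise ValueError("rows of Pi must sum to 1")


def _two_hop_alphas(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-node alpha1 = |N1| / (|N1| + |N2|), N2 the exact-distance-2 set."""
    A = (W > 0)
    np.fill_diagonal(A, False)
    n1 = A.sum(axis=1)
    # reachable in exactly two adjacency steps, excluding self and 1-hop set
    two_step = (A.astype(np.int64) @ A.astype(np.int64)) > 0
    np.fill_diagonal(two_step, False)
    n2 = (two_step & ~A).sum(axis=1)
    total = n1 + n2
    alpha1 = np.ones(W.shape[0])
    mask = total > 0
    alpha1[mask] = n1[mask] / total[mask]
    return alpha1, 1.0 - alpha1


def build_transition_model(
    g: WeightedGraph,
    alpha_mode: AlphaMode = "per_node",
    scalar_alpha1: float | None = None,
) -> TransitionModel:
    """Build P = D^{-1} W, its square, and the per-node hop fractions.

    Weighted degrees d_i = sum_j w_ij normalize each row; a node with no
    edges keeps all its step mass on itself. The hop fractions count
    topological neighbors only (weights set proportions within a row, not
    between hops). ``alpha_mode``/``scalar_alpha1`` are validated here for
    early failure but consumed from the :class:`WalkConfig` at solve time.
    """
    if alpha_mode == "scalar" and scalar_alpha1 is None:
        raise ValueError("scalar alpha mode requires scalar_alpha1")
    W = np.asarray(g.W, dtype=float)
    d = W.sum(axis=1)
    P = np.zeros_like(W)
    nz = d > 0
    P[nz] = W[nz] / d[nz, None]
    iso = np.flatnonzero(~nz)
    P[iso, iso] = 1.0
    alpha1, alpha2 = _two_hop_alphas(W)
    return TransitionModel(g.labels, P, P @ P, alpha1, alpha2)


def _restart_vector(n: int, start: int) -> np.ndarray:
    if not (0 <= start < n):
        raise IndexError(f"start node index {start} out of range for n={n}")
    r0 = np.zeros(n)
    r0[start] = 1.0
    return r0


def iterate_2hoprwr(
    model: TransitionModel,
    cfg: WalkConfig,
    start: int,
) -> tuple[np.ndarray, int]:
    """Run the fixed-point iteration r <- c A^T r + (1-c) r0 to stationarity.

    Returns the stationary probability vector and the number of iterations
    performed. Raises :class:`ConvergenceError` if the L1 residual is still
    above ``cfg.tol`` after ``cfg.max_iter`` steps.
    """
    A_T = model.mixed_operator(cfg).T
    r0 = _restart_vector(model.n_nodes, start)
    r = r0.copy()
    restart = (1.0 - cfg.c) * r0
    for t in range(1, cfg.max_iter + 1):
        r_next = cfg.c * (A_T @ r) + restart
        residual = float(np.abs(r_next - r).sum())
        r = r_next
        if residual < cfg.tol:
            return r, t
    raise ConvergenceError(cfg.max_iter, residual, cfg.tol)


def closed_form_steady_state(
    model: TransitionModel,
    cfg: WalkConfig,
    start: int,
) -> np.ndarray:
    """Exact stationary vector (1-c)(I - c A^T)^{-1} r0 by linear solve.

    Valid for every c < 1: the damped operator has spectral radius <= c, so
    the system is nonsingular. Serves as the oracle the iteration is checked
    against.
    """
    A_T = model.mixed_operator(cfg).T
    n = model.n_nodes
    r0 = _restart_vector(n, start)
    try:
        r = np.linalg.solve(np.eye(n) - cfg.c * A_T, (1.0 - cfg.c) * r0)
    except np.linalg.LinAlgError as exc:  # defensive: cannot occur for c < 1
        raise np.linalg.LinAlgError(
            f"singular 2hopRWR system at c={cfg.c}: {exc}"
        ) from exc
    return r


def steady_state_matrix(model: TransitionModel, cfg: WalkConfig) -> SteadyStateMatrix:
    """All stationary distributions at once: row i is the walk started at v_i.

    A single matrix solve replaces n vector solves: Pi^T = (1-c)(I - c A^T)^{-1},
    equivalently Pi = (1-c)(I - c A)^{-1}.
    """
    A = model.mixed_operator(cfg)
    n = model.n_nodes
    Pi = np.linalg.solve(np.eye(n) - cfg.c * A, (1.0 - cfg.c) * np.eye(n))
    # clip solver dust so probabilities stay in [0, 1]
    Pi = np.clip(Pi, 0.0, 1.0)
    return SteadyStateMatrix(model.labels, Pi)


def s2hop_scores(Pi: SteadyStateMatrix, mode: ScoreMode = "column_sum") -> FeatureVector:
    """2hop-connectivity per node, aggregated from the steady-state matrix.

    ``column_sum`` (default) scores node i by the total stationary mass it
    receives across all start nodes, sum_j Pi[j, i] — the standard
    restart-walk relevance aggregate, matching the semantics that a larger
    score marks a more important node. ``row_sum`` sums each start's own
    stationary vector instead; each row of Pi is a probability vector, so
    this mode is identically 1 and cannot rank nodes — it is kept to
    document that degeneracy. Both modes total exactly n over all nodes.
    """
    if mode == "column_sum":
        values = Pi.Pi.sum(axis=0)
    elif mode == "row_sum":
        warnings.warn(
            "row_sum 2hop-connectivity is the row total of a stationary "
            "probability vector and is identically 1 for every node",
            stacklevel=2,
        )
        values = Pi.Pi.sum(axis=1)
    else:
        raise ValueError(f"unknown score mode {mode!r}")
    return FeatureVector("S_2hop", Pi.labels, values)
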