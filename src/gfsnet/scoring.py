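"""Feature normalization, the Global Feature Score, and group comparison.

The Global Feature Score (GFS) of a node is a convex combination of the
five min-max-normalized local features

    GFS(v) = w1*NC_D + w2*NC_B + w3*NC_C + w4*NN_MC + w5*NS_2hop,

with equal weights 1/5 by default; weights may instead be fitted by
nonnegative least squares against an external per-node score (e.g., a
cognitive scale). Two group-average networks are compared by the per-node
difference Delta GFS = GFS_A - GFS_B, ranked descending; the block-level
association between GFS profiles and clinical scale scores is summarized by
the first canonical correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize

from gfsnet.graph_io import WeightedGraph
from gfsnet.local_features import (
    FEATURE_NAMES,
    FeatureVector,
    betweenness_centrality,
    closeness_centrality,
    degree_centrality,
    maximal_clique_counts,
)
from gfsnet.twohop_rwr import (
    WalkConfig,
    build_transition_model,
    s2hop_scores,
    steady_state_matrix,
)

__all__ = [
    "FeatureTable",
    "GFSWeights",
    "DifferentialRanking",
    "CCAResult",
    "normalize_minmax",
    "compute_feature_table",
    "gfs",
    "fit_gfs_weights",
    "differential_ranking",
    "rank_group_difference",
    "first_canonical_correlation",
]


def normalize_minmax(v: FeatureVector) -> FeatureVector:
    """Affinely rescale a feature to [0, 1]: (x - min) / (max - min).

    A constant feature carries no ranking information; it maps to all zeros
    (with a warning) so it contributes nothing to downstream combinations.
    Constancy is judged to a relative tolerance so that solver round-off at
    machine precision (e.g., on vertex-transitive graphs) is not inflated
    into a spurious [0, 1] spread.
    """
    x = v.values
    lo, hi = float(x.min()), float(x.max())
    if hi - lo <= 1e-12 * max(abs(lo), abs(hi), 1.0):
        warnings.warn(
            f"feature '{v.name}' is constant; normalized to zeros", stacklevel=2
        )
        return FeatureVector(f"N{v.name}", v.labels, np.zeros_like(x))
    return FeatureVector(f"N{v.name}", v.labels, (x - lo) / (hi - lo))


@dataclass(frozen=True)
class FeatureTable:
    """Raw and min-max normalized values of the five local features.

    Column order is fixed: C_D, c_B, C_c, N_MC, S_2hop.
    """

    labels: tuple[str, ...]
    raw: tuple[FeatureVector, ...]
    normalized: tuple[FeatureVector, ...]

    def __post_init__(self) -> None:
        if tuple(f.name for f in self.raw) != FEATURE_NAMES:
            raise ValueError(f"raw features must be {FEATURE_NAMES} in order")
        for f in list(self.raw) + list(self.normalized):
            if f.labels != tuple(self.labels):
                raise ValueError(f"feature '{f.name}' labels misaligned with table")

    @property
    def normalized_matrix(self) -> np.ndarray:
        """n_nodes x 5 matrix of normalized features in canonical order."""
        return np.column_stack([f.values for f in self.normalized])

    def to_records(self) -> list[dict[str, object]]:
        rows: list[dict[str, object]] = []
        for i, label in enumerate(self.labels):
            row: dict[str, object] = {"node": label}
            for f in self.raw:
                row[f.name] = f.values[i]
            for f in self.normalized:
                row[f.name] = f.values[i]
            rows.append(row)
        return rows


@dataclass(frozen=True)
class GFSWeights:
    """Convex-combination weights over the five normalized features."""

    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if w.shape != (5,):
            raise ValueError(f"expected 5 weights, got shape {w.shape}")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if abs(float(w.sum()) - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")

    @classmethod
    def equal(cls) -> "GFSWeights":
        """The default: each feature weighted 1/5."""
        return cls(np.full(5, 0.2))


def compute_feature_table(g: WeightedGraph, cfg: WalkConfig | None = None) -> FeatureTable:
    """All five features (raw and normalized) of one cleaned network."""
    cfg = cfg or WalkConfig()
    model = build_transition_model(g)
    Pi = steady_state_matrix(model, cfg)
    raw = (
        degree_centrality(g),
        betweenness_centrality(g),
        closeness_centrality(g),
        maximal_clique_counts(g),
        s2hop_scores(Pi),
    )
    with warnings.catch_warnings():
        # constant columns (e.g., on vertex-transitive graphs) are expected
        warnings.simplefilter("ignore")
        normalized = tuple(normalize_minmax(f) for f in raw)
    return FeatureTable(g.labels, raw, normalized)


def gfs(table: FeatureTable, weights: GFSWeights | None = None) -> FeatureVector:
    """Global Feature Score: weighted sum of the normalized features."""
    weights = weights or GFSWeights.equal()
    values = table.normalized_matrix @ weights.w
    return FeatureVector("GFS", table.labels, values)


def fit_gfs_weights(table: FeatureTable, scores: np.ndarray) -> GFSWeights:
    """Fit feature weights by nonnegative least squares against external scores.

    Regresses ``scores`` (one value per node, e.g., a scale score attributed
    to each region) on the five normalized features without intercept,
    constraining coefficients to be nonnegative, then rescales them to sum
    to 1 so GFS remains a convex combination. An all-zero solution falls
    back to equal weights with a warning.
    """
    y = np.asarray(scores, dtype=float)
    X = table.normalized_matrix
    if y.shape != (X.shape[0],):
        raise ValueError(
            f"scores shape {y.shape} does not match {X.shape[0]} nodes"
        )
    if len(y) < 6:
        raise ValueError("weight fitting needs at least 6 observations")
    coef, _ = scipy.optimize.nnls(X, y)
    total = coef.sum()
    if total <= 0:
        warnings.warn(
            "nonnegative regression returned all-zero weights; "
            "falling back to equal weights",
            stacklevel=2,
        )
        return GFSWeights.equal()
    return GFSWeights(coef / total)


@dataclass(frozen=True)
class DifferentialRanking:
    """Per-node GFS difference between two groups, ranked descending.

    ``delta[i] = GFS_A(v_i) - GFS_B(v_i)``; ``rank`` is 1-based with ties
    broken by input label order, and ``order`` lists node indices from
    largest to smallest delta.
    """

    labels: tuple[str, ...]
    delta: np.ndarray
    rank: np.ndarray
    order: np.ndarray

    def top(self, k: int) -> list[tuple[str, float]]:
        """The k nodes with the largest positive group difference."""
        if not (1 <= k <= len(self.labels)):
            raise ValueError(f"top-k must be in 1..{len(self.labels)}, got {k}")
        return [(self.labels[i], float(self.delta[i])) for i in self.order[:k]]

    def to_records(self) -> list[dict[str, object]]:
        return [
            {
                "node": self.labels[i],
                "delta_gfs": float(self.delta[i]),
                "rank": int(self.rank[i]),
            }
            for i in self.order
        ]


def differential_ranking(
    gfs_a: FeatureVector, gfs_b: FeatureVector
) -> DifferentialRanking:
    """Rank nodes by GFS(group A) - GFS(group B), descending, stable in label order."""
    if gfs_a.labels != gfs_b.labels:
        raise ValueError("group GFS vectors have mismatched node labels")
    delta = gfs_a.values - gfs_b.values
    # stable sort on -delta keeps label order among ties
    order = np.argsort(-delta, kind="stable")
    rank = np.empty(len(delta), dtype=int)
    rank[order] = np.arange(1, len(delta) + 1)
    return DifferentialRanking(gfs_a.labels, delta, rank, order)


def rank_group_difference(
    avg_a: WeightedGraph,
    avg_b: WeightedGraph,
    cfg: WalkConfig | None = None,
    weights: GFSWeights | None = None,
) -> tuple[DifferentialRanking, FeatureTable, FeatureTable]:
    """Full comparison of two group-average networks.

    Computes both feature tables and GFS vectors and returns the descending
    Delta-GFS ranking together with the tables (for reporting).
    """
    if avg_a.labels != avg_b.labels:
        raise ValueError("group-average networks have mismatched node labels")
    table_a = compute_feature_table(avg_a, cfg)
    table_b = compute_feature_table(avg_b, cfg)
    ranking = differential_ranking(gfs(table_a, weights), gfs(table_b, weights))
    return ranking, table_a, table_b


@dataclass(frozen=True)
class CCAResult:
    """First canonical pair of two observation blocks.

    ``rho`` is the largest canonical correlation; ``x_loadings`` and
    ``y_loadings`` are the coefficient vectors of the composite variables
    U = X a and V = Y b, normalized to unit variance of the composites.
    """

    rho: float
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_columns: tuple[str, ...] = ()
    y_columns: tuple[str, ...] = ()


def _drop_constant_columns(M: np.ndarray, names: list[str], block: str):
    keep = M.std(axis=0) > 0
    if not keep.all():
        dropped = [names[j] for j in np.flatnonzero(~keep)]
        warnings.warn(
            f"dropping zero-variance column(s) {dropped} from {block} block",
            stacklevel=3,
        )
    return M[:, keep], [names[j] for j in np.flatnonzero(keep)]


def first_canonical_correlation(
    X: np.ndarray,
    Y: np.ndarray,
    x_columns: list[str] | None = None,
    y_columns: list[str] | None = None,
    rcond: float = 1e-10,
) -> CCAResult:
    """Largest canonical correlation between two observation-by-variable blocks.

    Both blocks are centered; within-block covariances are whitened through
    symmetric inverse square roots (eigenvalues below ``rcond`` times the
    largest are treated as null directions, making rank-deficient blocks
    well defined); the first singular value of the whitened cross-covariance
    is the canonical correlation, invariant to invertible affine transforms
    of either block.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.ndim != 2 or Y.ndim != 2:
        raise ValueError("X and Y must be 2-D observation-by-variable arrays")
    if X.shape[0] != Y.shape[0]:
        raise ValueError(
            f"blocks have different observation counts: {X.shape[0]} vs {Y.shape[0]}"
        )
    n = X.shape[0]
    if n < 3:
        raise ValueError("canonical correlation needs at least 3 observations")
    x_names = x_columns or [f"x{j + 1}" for j in range(X.shape[1])]
    y_names = y_columns or [f"y{j + 1}" for j in range(Y.shape[1])]
    X, x_names = _drop_constant_columns(X, list(x_names), "X")
    Y, y_names = _drop_constant_columns(Y, list(y_names), "Y")
    if X.shape[1] == 0 or Y.shape[1] == 0:
        raise ValueError("a block has no non-constant columns")

    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)

    def inv_sqrt(S: np.ndarray) -> np.ndarray:
        vals, vecs = scipy.linalg.eigh(S)
        cutoff = rcond * vals.max()
        inv = np.where(vals > cutoff, 1.0 / np.sqrt(np.maximum(vals, cutoff)), 0.0)
        return (vecs * inv) @ vecs.T

    Kx, Ky = inv_sqrt(Sxx), inv_sqrt(Syy)
    U, s, Vt = np.linalg.svd(Kx @ Sxy @ Ky)
    rho = float(np.clip(s[0], 0.0, 1.0))
    a = Kx @ U[:, 0]
    b = Ky @ Vt[0]
    # canonical metric: composites U = X a, V = Y b have unit variance
    va = float(a @ Sxx @ a)
    vb = float(b @ Syy @ b)
    if va > 0:
        a = a / np.sqrt(va)
    if vb > 0:
        b = b / np.sqrt(vb)
    return CCAResult(rho, a, b, tuple(x_names), tuple(y_names))
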