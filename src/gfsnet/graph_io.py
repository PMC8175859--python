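"""Reading, validating, cleaning and group-averaging weighted network matrices.

A network is a square nonnegative symmetric matrix with zero diagonal — for
brain structural connectomes, the fiber-number (FN) matrix whose entry
(i, j) counts the tracked fibers between regions i and j. Node order is the
file order and is preserved by every downstream vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GraphValidationError",
    "WeightedGraph",
    "SubjectGroup",
    "read_weight_matrix",
    "read_group_dir",
    "clean_graph",
    "average_group",
    "write_table",
    "write_matrix",
]


class GraphValidationError(ValueError):
    """Raised when an input matrix violates the weighted-graph contract."""


def _default_labels(n: int) -> list[str]:
    return [f"R{i + 1}" for i in range(n)]


@dataclass(frozen=True)
class WeightedGraph:
    """An undirected node-labeled weighted graph G(V, E, W).

    Parameters
    ----------
    labels
        Ordered unique node identifiers (e.g., AAL region names).
    W
        Square symmetric nonnegative weight matrix with zero diagonal;
        ``W[i, j]`` is the edge weight (fiber count) between nodes i and j.

    Construction enforces the hard invariants (square, finite, nonnegative,
    matching unique labels). Exact symmetry and a zero diagonal are
    established by :func:`clean_graph`, which tolerates the slight
    asymmetry real tractography exports exhibit.
    """

    labels: tuple[str, ...]
    W: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise GraphValidationError(f"weight matrix is non-square: shape {W.shape}")
        n = W.shape[0]
        if len(self.labels) != n:
            raise GraphValidationError(
                f"label count mismatch: {len(self.labels)} labels for {n}x{n} matrix"
            )
        if len(set(self.labels)) != n:
            raise GraphValidationError("node labels are not unique")
        if not np.all(np.isfinite(W)):
            i, j = np.argwhere(~np.isfinite(W))[0]
            raise GraphValidationError(f"non-finite entry at row {i}, column {j}")
        if np.any(W < 0):
            i, j = np.argwhere(W < 0)[0]
            raise GraphValidationError(
                f"negative entry {W[i, j]} at row {i}, column {j}"
            )
    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    def with_matrix(self, W: np.ndarray) -> "WeightedGraph":
        """Return a new graph with the same labels and a replaced matrix."""
        return WeightedGraph(self.labels, W)


@dataclass(frozen=True)
class SubjectGroup:
    """A nonempty collection of subject networks sharing one node set."""

    members: tuple[WeightedGraph, ...]

    def __post_init__(self) -> None:
        members = tuple(self.members)
        object.__setattr__(self, "members", members)
        if not members:
            raise GraphValidationError("subject group is empty")
        ref = members[0].labels
        for k, g in enumerate(members):
            if g.labels != ref:
                raise GraphValidationError(
                    f"member {k} labels differ from member 0"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return self.members[0].labels

    def __len__(self) -> int:
        return len(self.members)


def _read_square_table(path: Path) -> tuple[np.ndarray, list[str] | None]:
    """Parse a TSV/CSV numeric matrix, detecting an optional label header."""
    sep = "," if path.suffix.lower() == ".csv" else None
    try:
        raw = pd.read_csv(path, sep=sep, header=None, engine="python", comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise GraphValidationError(f"cannot parse {path}: {exc}") from exc
    labels: list[str] | None = None

    def _all_floats(series: pd.Series) -> bool:
        # float("nan") succeeds, so a NaN cell is data (reported later), not a header
        for x in series:
            try:
                float(x)
            except (TypeError, ValueError):
                return False
        return True

    if not _all_floats(raw.iloc[0]):
        # header row of labels; a leading corner cell may label the index column
        header = [str(x) for x in raw.iloc[0]]
        body = raw.iloc[1:].reset_index(drop=True)
        if not _all_floats(body.iloc[:, 0]):
            labels = [str(x) for x in body.iloc[:, 0]]
            body = body.iloc[:, 1:]
        else:
            labels = header
        values = body
    else:
        values = raw
    numeric = values.apply(pd.to_numeric, errors="coerce")
    arr = numeric.to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise GraphValidationError(
            f"non-square matrix in {path}: {arr.shape[0]} rows x {arr.shape[1]} columns"
        )
    if np.isnan(arr).any():
        i, j = np.argwhere(np.isnan(arr))[0]
        raise GraphValidationError(f"NaN or non-numeric entry at row {i}, column {j} in {path}")
    return arr, labels


def read_weight_matrix(path: str | Path, labels_path: str | Path | None = None) -> WeightedGraph:
    """Read a square weight matrix from a TSV/CSV file.

    The file may carry a header row (and optionally a leading label column);
    otherwise nodes are named ``R1..Rn``. An explicit ``labels_path`` (one
    label per line) overrides any header.
    """
    path = Path(path)
    W, header_labels = _read_square_table(path)
    n = W.shape[0]
    if labels_path is not None:
        labels = [
            line.strip()
            for line in Path(labels_path).read_text().splitlines()
            if line.strip()
        ]
        if len(labels) != n:
            raise GraphValidationError(
                f"label file has {len(labels)} labels but matrix has {n} rows"
            )
    elif header_labels is not None:
        labels = header_labels
    else:
        labels = _default_labels(n)
    return WeightedGraph(tuple(labels), W)


def read_group_dir(directory: str | Path, labels_path: str | Path | None = None) -> SubjectGroup:
    """Read every ``*.tsv``/``*.csv``/``*.txt`` matrix in a directory (sorted by name)."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in {".tsv", ".csv", ".txt"}
    )
    if not paths:
        raise GraphValidationError(f"no matrix files found in {directory}")
    return SubjectGroup(tuple(read_weight_matrix(p, labels_path) for p in paths))


def clean_graph(
    g: WeightedGraph,
    min_weight: float = 1.0,
    symmetrize_tol: float = 1e-8,
) -> WeightedGraph:
    """Denoise a graph: threshold weak edges, zero the diagonal, symmetrize.

    Entries below ``min_weight`` are set to zero (fiber counts below the
    denoising threshold are treated as noise). Near-symmetric matrices —
    ``max|W - W.T| <= symmetrize_tol * max(W)`` — are symmetrized by
    averaging; worse asymmetry raises :class:`GraphValidationError`.
    Idempotent at a fixed threshold.
    """
    if min_weight < 0:
        raise ValueError("min_weight must be nonnegative")
    W = np.array(g.W, dtype=float)
    scale = float(W.max(initial=0.0))
    asym = float(np.abs(W - W.T).max(initial=0.0))
    if asym > symmetrize_tol * max(scale, 1e-300):
        raise GraphValidationError(
            f"asymmetry {asym:g} exceeds tolerance {symmetrize_tol:g} x max weight"
        )
    W = (W + W.T) / 2.0
    W[W < min_weight] = 0.0
    np.fill_diagonal(W, 0.0)
    return WeightedGraph(g.labels, W)


def average_group(group: SubjectGroup) -> WeightedGraph:
    """Elementwise mean of a group's matrices (the group-average FN matrix)."""
    stack = np.stack([g.W for g in group.members])
    return WeightedGraph(group.labels, stack.mean(axis=0))


def write_table(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write per-node records as a TSV with a header, preserving row order."""
    path = Path(path)
    df = pd.DataFrame(list(rows), columns=list(columns) if columns else None)
    df.to_csv(path, sep="\t", index=False)


def write_matrix(g_or_matrix: WeightedGraph | np.ndarray, path: str | Path,
                 labels: Sequence[str] | None = None) -> None:
    """Write a matrix as TSV with a label header row (round-trips through
    :func:`read_weight_matrix`)."""
    if isinstance(g_or_matrix, WeightedGraph):
        M, labels = g_or_matrix.W, g_or_matrix.labels
    else:
        M = np.asarray(g_or_matrix, dtype=float)
        if labels is None:
            labels = _default_labels(M.shape[0])
    pd.DataFrame(M, columns=list(labels)).to_csv(Path(path), sep="\t", index=False)
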