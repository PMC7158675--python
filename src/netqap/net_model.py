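"""Core containers and file I/O for dyadic friendship-network analysis.

The data model follows the classic sociometric design of school-based
health-behavior studies: each pupil in an enrolled roster answers an
attribute questionnaire (class, gender, ethnicity, Likert-scale perceived
relevance of vaccination for pupil and parent, parent age, medical-visit
frequency category, and a binary post-intervention vaccination response)
and nominates schoolmates, yielding directed binary sociomatrices for two
contexts (school hours and after-school hours).

Four containers are shared across the package:

``NodeTable``
    one validated row per pupil; the atoms of every dyadic covariate.
``Network``
    a directed, binary, hollow sociomatrix over the same node ordering.
``DyadicMatrix``
    a square real-valued dyad-level variable whose diagonal is ignored by
    convention ("pseudo-network" data).
``DyadDesign``
    the stacked off-diagonal cells — one row per ordered dyad (i, j),
    i != j — ready for network regression.

All matrices of one study share a single node ordering; operations that
combine containers assert this and fail loudly on mismatch.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CONTEXTS",
    "NODE_TABLE_COLUMNS",
    "SchemaError",
    "ValidationError",
    "NodeTable",
    "Network",
    "DyadicMatrix",
    "DyadDesign",
    "dyad_index",
    "offdiag_mask",
    "vectorize",
    "devectorize",
    "read_node_table",
    "read_network",
    "write_edge_list",
    "write_adjacency",
    "write_graphml",
]

#: Recognised network contexts (when the nominations were active).
CONTEXTS = ("school", "after_school")

#: Required node-table columns, in canonical order.
NODE_TABLE_COLUMNS = (
    "node_id",
    "class_label",
    "gender",
    "ethnicity",
    "pupil_relevance",
    "parent_relevance",
    "parent_age",
    "medical_visits",
    "positive_response",
)

_LIKERT_COLUMNS = ("pupil_relevance", "parent_relevance")


class SchemaError(ValueError):
    """A file or frame does not have the expected columns/shape."""


class ValidationError(ValueError):
    """Values violate a domain invariant (range, uniqueness, binarity)."""


# ---------------------------------------------------------------------------
# dyad ordering helpers
# ---------------------------------------------------------------------------


def offdiag_mask(n: int) -> np.ndarray:
    """Boolean mask selecting the n(n-1) off-diagonal cells of an n x n matrix."""
    if n < 2:
        raise ValidationError(f"dyadic operations need n >= 2 nodes, got n={n}")
    return ~np.eye(n, dtype=bool)


def dyad_index(n: int) -> np.ndarray:
    """Canonical (sender, receiver) ordering of the n(n-1) ordered dyads.

    Row-major over (i, j) with the diagonal skipped — the one fixed
    ordering used by every module, so that vectorized dyad data are
    comparable across operations.
    """
    i, j = np.nonzero(offdiag_mask(n))
    return np.column_stack([i, j])


def vectorize(matrix: "DyadicMatrix | np.ndarray") -> np.ndarray:
    """Off-diagonal cells of a square matrix in canonical dyad order."""
    values = matrix.values if isinstance(matrix, DyadicMatrix) else np.asarray(matrix)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError(f"expected a square matrix, got shape {values.shape}")
    n = values.shape[0]
    return values[offdiag_mask(n)].astype(float)


def devectorize(vec: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`vectorize`: fold a dyad vector back to a hollow matrix."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (n * (n - 1),):
        raise ValidationError(
            f"dyad vector has length {vec.size}, expected n(n-1) = {n * (n - 1)}"
        )
    out = np.zeros((n, n))
    out[offdiag_mask(n)] = vec
    return out


# ---------------------------------------------------------------------------
# NodeTable
# ---------------------------------------------------------------------------


@dataclass
class NodeTable:
    """Validated per-pupil attribute table.

    Parameters
    ----------
    data
        One row per pupil with the columns of :data:`NODE_TABLE_COLUMNS`.
        ``positive_response`` may be wholly missing (NaN) for a cohort whose
        outcomes have not yet been observed/generated; all other columns
        must be complete.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in NODE_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"node table is missing column(s): {', '.join(missing)}")
        df = df.loc[:, list(NODE_TABLE_COLUMNS)].reset_index(drop=True).copy()
        df["node_id"] = df["node_id"].astype(str)
        if (df["node_id"].str.len() == 0).any():
            raise ValidationError("empty node_id")
        dupes = df["node_id"][df["node_id"].duplicated()].unique()
        if dupes.size:
            raise ValidationError(f"duplicate node_id(s): {', '.join(dupes)}")

        for col in (
            "class_label",
            "gender",
            "ethnicity",
            "pupil_relevance",
            "parent_relevance",
            "parent_age",
            "medical_visits",
        ):
            bad = df.index[df[col].isna()]
            if len(bad):
                raise ValidationError(
                    f"missing value in column {col!r} at row {int(bad[0])}"
                )
        for col in _LIKERT_COLUMNS:
            vals = df[col].to_numpy()
            bad = np.nonzero((vals < 1) | (vals > 7) | (vals != np.round(vals)))[0]
            if bad.size:
                raise ValidationError(
                    f"{col} must be an integer in [1, 7]; row {int(bad[0])} has "
                    f"{vals[bad[0]]!r}"
                )
        mv = df["medical_visits"].to_numpy()
        bad = np.nonzero(~np.isin(mv, [1, 2, 3, 4, 5]))[0]
        if bad.size:
            raise ValidationError(
                f"medical_visits must be in {{1..5}}; row {int(bad[0])} has {mv[bad[0]]!r}"
            )
        if (df["parent_age"].to_numpy() <= 0).any():
            row = int(np.nonzero(df["parent_age"].to_numpy() <= 0)[0][0])
            raise ValidationError(f"parent_age must be > 0; offending row {row}")
        pr = df["positive_response"]
        observed = pr.dropna()
        if not observed.isin([0, 1]).all():
            row = int(observed.index[~observed.isin([0, 1])][0])
            raise ValidationError(
                f"positive_response must be 0/1; offending row {row}"
            )
        self.data = df

    # -- convenience accessors ------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(self.data["node_id"])

    def attribute(self, name: str) -> np.ndarray:
        if name not in NODE_TABLE_COLUMNS:
            raise SchemaError(f"unknown attribute {name!r}")
        return self.data[name].to_numpy()

    def outcome(self) -> np.ndarray:
        """The binary positive-response vector; errors if any value is missing."""
        pr = self.data["positive_response"]
        if pr.isna().any():
            raise ValidationError(
                "positive_response contains missing values; outcomes not yet observed"
            )
        return pr.to_numpy().astype(int)

    def with_outcome(self, outcome: np.ndarray) -> "NodeTable":
        out = self.data.copy()
        out["positive_response"] = np.asarray(outcome, dtype=float)
        return NodeTable(out)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        # keep integer display for a binary column that may pass through float NaN
        if out["positive_response"].notna().all():
            out["positive_response"] = out["positive_response"].astype(int)
        out.to_csv(path, index=False)


def read_node_table(path) -> NodeTable:
    """Read and validate a per-pupil attribute CSV (header row mandatory)."""
    df = pd.read_csv(path, dtype={"node_id": str})
    missing = [c for c in NODE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    if df[list(NODE_TABLE_COLUMNS)].isna().any().any():
        # survey files are analysed complete-case; reject partial records
        bad_rows = df.index[df[list(NODE_TABLE_COLUMNS)].isna().any(axis=1)]
        raise ValidationError(
            f"{path}: missing value(s) in row(s) {list(map(int, bad_rows[:5]))}"
        )
    return NodeTable(df)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


@dataclass
class Network:
    """Directed binary sociomatrix with a context tag.

    ``adjacency[i, j] == 1`` records a nomination from ``nodes[i]`` to
    ``nodes[j]``. The matrix is hollow (no self-nomination).
    """

    nodes: tuple[str, ...]
    adjacency: np.ndarray
    context: str

    def __post_init__(self) -> None:
        self.nodes = tuple(str(v) for v in self.nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValidationError("duplicate node ids in network roster")
        adj = np.asarray(self.adjacency)
        n = len(self.nodes)
        if adj.shape != (n, n):
            raise SchemaError(
                f"adjacency shape {adj.shape} does not match {n} nodes"
            )
        if not np.isin(adj, [0, 1]).all():
            raise ValidationError("adjacency entries must be 0/1")
        if np.diagonal(adj).any():
            raise ValidationError("adjacency diagonal must be zero (no self-ties)")
        if self.context not in CONTEXTS:
            raise ValidationError(
                f"context must be one of {CONTEXTS}, got {self.context!r}"
            )
        self.adjacency = adj.astype(np.int8)

    @property
    def n(self) -> int:
        return len(self.nodes)

    def out_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def in_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0)

    def as_dyadic(self, label: str | None = None) -> "DyadicMatrix":
        return DyadicMatrix(
            values=self.adjacency.astype(float),
            label=label or self.context,
            symmetric=False,
        )


def read_network(path, nodes: Sequence[str], context: str) -> Network:
    """Read a directed binary network from edge-list or adjacency CSV.

    The dialect is sniffed from the header: a two-column
    ``sender,receiver`` file is an edge list; otherwise the file must be a
    square adjacency CSV whose first column holds node ids and whose header
    matches ``nodes`` in order. Self-loops are dropped with a warning and
    duplicate edges collapse to a single tie.
    """
    nodes = tuple(str(v) for v in nodes)
    header = pd.read_csv(path, nrows=0)
    cols = [c.strip() for c in header.columns]
    if cols[:2] == ["sender", "receiver"] and len(cols) == 2:
        edges = pd.read_csv(path, dtype=str)
        index = {v: i for i, v in enumerate(nodes)}
        adj = np.zeros((len(nodes), len(nodes)), dtype=np.int8)
        for row, (s, r) in enumerate(zip(edges["sender"], edges["receiver"])):
            for v in (s, r):
                if v not in index:
                    raise ValidationError(
                        f"{path}: unknown node_id {v!r} in edge-list row {row}"
                    )
            if s == r:
                warnings.warn(
                    f"{path}: dropping self-nomination {s!r} -> {r!r}",
                    stacklevel=2,
                )
                continue
            adj[index[s], index[r]] = 1
        return Network(nodes=nodes, adjacency=adj, context=context)

    frame = pd.read_csv(path, index_col=0)
    if frame.shape[0] != frame.shape[1]:
        raise SchemaError(
            f"{path}: adjacency must be square, got shape {frame.shape}"
        )
    file_nodes = tuple(str(v) for v in frame.columns)
    if file_nodes != nodes:
        raise ValidationError(
            f"{path}: adjacency header order does not match the study roster"
        )
    adj = frame.to_numpy()
    if np.diagonal(adj).any():
        warnings.warn(f"{path}: dropping self-nominations on the diagonal", stacklevel=2)
        adj = adj.copy()
        np.fill_diagonal(adj, 0)
    return Network(nodes=nodes, adjacency=adj, context=context)


def write_edge_list(network: Network, path) -> None:
    senders, receivers = np.nonzero(network.adjacency)
    pd.DataFrame(
        {
            "sender": [network.nodes[i] for i in senders],
            "receiver": [network.nodes[j] for j in receivers],
        }
    ).to_csv(path, index=False)


def write_adjacency(network: Network, path) -> None:
    pd.DataFrame(
        network.adjacency, index=list(network.nodes), columns=list(network.nodes)
    ).to_csv(path)


def write_graphml(network: Network, attrs: NodeTable, path) -> None:
    """Export a network with node attributes attached, for external drawing.

    Gender, perceived relevance, class and ethnicity are attached to every
    node element so sociogram tools can size/colour nodes by attribute.
    """
    if network.nodes != attrs.node_ids:
        raise ValidationError("network and node-table rosters differ")
    g = nx.DiGraph()
    table = attrs.data.set_index("node_id")
    for node in network.nodes:
        row = table.loc[node]
        g.add_node(
            node,
            gender=str(row["gender"]),
            pupil_relevance=int(row["pupil_relevance"]),
            class_label=str(row["class_label"]),
            ethnicity=str(row["ethnicity"]),
        )
    for i, j in zip(*np.nonzero(network.adjacency)):
        g.add_edge(network.nodes[i], network.nodes[j])
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# DyadicMatrix and DyadDesign
# ---------------------------------------------------------------------------


@dataclass
class DyadicMatrix:
    """Square real-valued dyad-level variable; the diagonal is ignored.

    Attribute covariates expressed at the dyad level ("pseudo-network"
    data) and network terms both live in this container. Construction
    zeroes the diagonal so no statistic can accidentally include it.
    """

    values: np.ndarray
    label: str
    symmetric: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise SchemaError(f"dyadic matrix must be square, got {values.shape}")
        if values.shape[0] < 2:
            raise ValidationError("dyadic matrix needs at least 2 nodes")
        values = values.copy()
        np.fill_diagonal(values, 0.0)
        if self.symmetric and not np.array_equal(values, values.T):
            raise ValidationError(
                f"matrix {self.label!r} declared symmetric but is not"
            )
        self.values = values

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def vector(self) -> np.ndarray:
        return vectorize(self.values)


@dataclass
class DyadDesign:
    """Stacked ordered-dyad design: response plus named predictor vectors.

    Every vector has length n(n-1); row k corresponds to the ordered dyad
    ``dyad_index[k] = (sender, receiver)`` in canonical row-major order.
    """

    response: np.ndarray
    predictors: dict[str, np.ndarray]
    dyad_index: np.ndarray
    node_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        n = self.n_nodes
        expected = n * (n - 1)
        if self.response.shape != (expected,):
            raise ValidationError(
                f"response has length {self.response.size}, expected {expected}"
            )
        if self.dyad_index.shape != (expected, 2):
            raise ValidationError("dyad_index must have shape (n(n-1), 2)")
        pairs = {tuple(p) for p in self.dyad_index.tolist()}
        if len(pairs) != expected or any(i == j for i, j in pairs):
            raise ValidationError(
                "dyad_index must list every ordered pair i != j exactly once"
            )
        self.predictors = {
            name: np.asarray(vec, dtype=float) for name, vec in self.predictors.items()
        }
        for name, vec in self.predictors.items():
            if vec.shape != (expected,):
                raise ValidationError(
                    f"predictor {name!r} has length {vec.size}, expected {expected}"
                )

    @property
    def n_nodes(self) -> int:
        return int(self.dyad_index.max()) + 1 if self.dyad_index.size else 0

    @property
    def n_obs(self) -> int:
        return self.response.size

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return tuple(self.predictors)

    def matrix(self) -> np.ndarray:
        """Predictors stacked column-wise, in declaration order (no intercept)."""
        return np.column_stack([self.predictors[k] for k in self.predictors])

    def as_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "sender": self.dyad_index[:, 0],
                "receiver": self.dyad_index[:, 1],
                "response": self.response,
            }
        )
        for name, vec in self.predictors.items():
            frame[name] = vec
        return frame
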