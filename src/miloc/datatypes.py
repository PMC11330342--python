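"""Core domain containers shared by every pipeline stage.

The pipeline manipulates a small set of typed matrices whose rows/columns are
keyed by ordered entity indices (miRNAs, diseases, drugs, mRNAs).  Keeping the
index attached to the values — rather than passing bare arrays — lets every
stage check alignment instead of silently mixing entity orders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

ENTITY_KINDS = ("mirna", "disease", "drug", "mrna")

#: Fixed localization vocabularies.  Order is part of the data contract: every
#: label matrix, score matrix and report uses exactly this column order.
MIRNA_LOCALIZATIONS = (
    "cytoplasm",
    "exosome",
    "nucleolus",
    "nucleus",
    "extracellular vesicle",
    "microvesicle",
    "mitochondrion",
)
MRNA_LOCALIZATIONS = ("cytoplasm", "exosome", "nucleolus", "nucleus")


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


@dataclass(frozen=True)
class EntityIndex:
    """Ordered, unique identifiers for one entity kind."""

    ids: tuple[str, ...]
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ENTITY_KINDS:
            raise ValidationError(f"unknown entity kind {self.kind!r}")
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            for e in self.ids:
                if e in seen:
                    raise ValidationError(f"duplicate entity id {e!r}")
                seen.add(e)
        object.__setattr__(self, "_pos", {e: i for i, e in enumerate(self.ids)})

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, entity: str) -> bool:
        return entity in self._pos

    def position(self, entity: str) -> int:
        try:
            return self._pos[entity]
        except KeyError:
            raise KeyError(f"unknown {self.kind} id {entity!r}") from None

    def positions(self, entities: Iterable[str]) -> np.ndarray:
        return np.array([self.position(e) for e in entities], dtype=np.intp)

    @classmethod
    def from_ids(cls, ids: Sequence[str], kind: str) -> "EntityIndex":
        return cls(tuple(ids), kind)


@dataclass
class AssociationMatrix:
    """Binary miRNA-vs-partner incidence matrix."""

    rows: EntityIndex
    cols: EntityIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.validate()

    def validate(self) -> None:
        if self.values.shape != (len(self.rows), len(self.cols)):
            raise ValidationError(
                f"association shape {self.values.shape} does not match index "
                f"lengths ({len(self.rows)}, {len(self.cols)})"
            )
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            raise ValidationError("association entries must be 0 or 1")

    def row_counts(self) -> np.ndarray:
        """Number of associated partners per miRNA."""
        return self.values.sum(axis=1)

    def partners_of(self, mirna: str) -> set[str]:
        i = self.rows.position(mirna)
        return {self.cols.ids[j] for j in np.flatnonzero(self.values[i])}


@dataclass
class SimilarityMatrix:
    """Symmetric miRNA x miRNA similarity with unit diagonal, values in [0, 1]."""

    index: EntityIndex
    values: np.ndarray

    SYMMETRY_TOL = 1e-9

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.index)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"similarity shape {self.values.shape} does not match index "
                f"length {n}"
            )
        if not np.allclose(self.values, self.values.T, atol=self.SYMMETRY_TOL, rtol=0):
            raise ValidationError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=self.SYMMETRY_TOL):
            raise ValidationError("similarity diagonal must be 1")
        if self.values.min() < -self.SYMMETRY_TOL or self.values.max() > 1 + self.SYMMETRY_TOL:
            raise ValidationError("similarity entries must lie in [0, 1]")


@dataclass
class DiseaseDAG:
    """Acyclic parent -> child disease ontology with decay factor delta.

    ``delta`` is the per-edge decay applied when a disease's semantic
    contribution is propagated to its parents (default 0.5).
    """

    graph: nx.DiGraph
    delta: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.delta < 1:
            raise ValidationError(f"delta must be in (0, 1), got {self.delta}")
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValidationError(f"disease graph contains a cycle: {cycle}")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
        delta: float = 0.5,
    ) -> "DiseaseDAG":
        g = nx.DiGraph()
        g.add_edges_from(edges)
        g.add_nodes_from(extra_nodes)
        return cls(g, delta)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def parents(self, disease: str) -> set[str]:
        return set(self.graph.predecessors(disease))

    def children(self, disease: str) -> set[str]:
        return set(self.graph.successors(disease))

    def ancestor_closure(self, disease: str) -> set[str]:
        """The disease itself plus all its ancestors."""
        if disease not in self.graph:
            raise KeyError(f"unknown disease {disease!r}")
        return nx.ancestors(self.graph, disease) | {disease}


@dataclass
class WeightedGraph:
    """Undirected weighted graph over an ordered node list.

    Backed by a symmetric CSR adjacency so random-walk code can fetch neighbor
    arrays without python-level dict traversal.
    """

    node_ids: tuple[str, ...]
    adjacency: sp.csr_matrix

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        if self.adjacency.shape != (n, n):
            raise ValidationError("adjacency shape does not match node count")
        if (self.adjacency != self.adjacency.T).nnz:
            raise ValidationError("adjacency must be symmetric")
        if self.adjacency.nnz and self.adjacency.data.min() <= 0:
            raise ValidationError("edge weights must be positive")
        self._pos = {v: i for i, v in enumerate(self.node_ids)}

    @classmethod
    def from_edges(
        cls,
        nodes: Sequence[str],
        edges: Iterable[tuple[str, str]] | Iterable[tuple[str, str, float]],
    ) -> "WeightedGraph":
        pos = {v: i for i, v in enumerate(nodes)}
        rows, cols, data = [], [], []
        for e in edges:
            u, v, w = e if len(e) == 3 else (*e, 1.0)
            if u == v:
                continue  # self-loops are added explicitly where needed
            rows += [pos[u], pos[v]]
            cols += [pos[v], pos[u]]
            data += [w, w]
        adj = sp.csr_matrix((data, (rows, cols)), shape=(len(nodes), len(nodes)))
        adj.sum_duplicates()
        return cls(tuple(nodes), adj)

    @classmethod
    def from_dense(cls, nodes: Sequence[str], weights: np.ndarray) -> "WeightedGraph":
        w = np.asarray(weights, dtype=float).copy()
        np.fill_diagonal(w, 0.0)
        return cls(tuple(nodes), sp.csr_matrix(w))

    def __len__(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    def position(self, node: str) -> int:
        return self._pos[node]

    def neighbors(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(neighbor indices, edge weights) of node ``i``."""
        a = self.adjacency
        sl = slice(a.indptr[i], a.indptr[i + 1])
        return a.indices[sl], a.data[sl]

    def has_edge(self, u: str, v: str) -> bool:
        i, j = self._pos[u], self._pos[v]
        return bool(self.adjacency[i, j])

    def edge_list(self) -> list[tuple[str, str, float]]:
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return [
            (self.node_ids[i], self.node_ids[j], float(w))
            for i, j, w in zip(coo.row, coo.col, coo.data)
        ]


@dataclass
class LabelMatrix:
    """Binary localization labels with a fixed label-name order."""

    index: EntityIndex
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.validate()

    def validate(self) -> None:
        if self.values.shape != (len(self.index), len(self.labels)):
            raise ValidationError(
                f"label shape {self.values.shape} does not match "
                f"({len(self.index)}, {len(self.labels)})"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("label entries must be 0 or 1")
        expected = (
            MIRNA_LOCALIZATIONS if self.index.kind == "mirna" else MRNA_LOCALIZATIONS
        )
        if self.labels != expected:
            raise ValidationError(
                f"label order for {self.index.kind} must be {expected}, "
                f"got {self.labels}"
            )

    def label_sets(self) -> list[set[str]]:
        return [
            {self.labels[j] for j in np.flatnonzero(row)} for row in self.values
        ]


@dataclass
class FeatureBundle:
    """The five named per-miRNA feature blocks.

    Default widths: sequence 64, disease 128, drug 128, mrna_network 128,
    coloc 4 — 452 columns in total.
    """

    index: EntityIndex
    blocks: dict[str, np.ndarray] = field(default_factory=dict)

    BLOCK_ORDER = ("sequence", "disease", "drug", "mrna_network", "coloc")

    def __post_init__(self) -> None:
        for name, block in self.blocks.items():
            if name not in self.BLOCK_ORDER:
                raise ValidationError(f"unknown feature block {name!r}")
            if block.shape[0] != len(self.index):
                raise ValidationError(
                    f"block {name!r} has {block.shape[0]} rows, expected "
                    f"{len(self.index)}"
                )
        if "coloc" in self.blocks:
            c = self.blocks["coloc"]
            if c.min() < 0 or c.max() > 1:
                raise ValidationError("coloc features must lie in [0, 1]")

    def widths(self) -> dict[str, int]:
        return {k: v.shape[1] for k, v in self.blocks.items()}

    def concat(self, subset: Sequence[str] | None = None) -> np.ndarray:
        """Horizontally concatenate blocks in canonical order.

        ``subset`` selects a feature-type combination (ablation mode); by
        default all present blocks are used.
        """
        names = [b for b in self.BLOCK_ORDER if b in (subset or self.blocks)]
        missing = [b for b in (subset or ()) if b not in self.blocks]
        if missing:
            raise ValidationError(f"missing feature block(s): {missing}")
        if not names:
            raise ValidationError("no feature blocks selected")
        return np.hstack([self.blocks[b] for b in names])

    def block_dims(self, subset: Sequence[str] | None = None) -> tuple[int, ...]:
        names = [b for b in self.BLOCK_ORDER if b in (subset or self.blocks)]
        return tuple(self.blocks[b].shape[1] for b in names)


def validate_container(obj) -> None:
    """Re-run the structural invariants of any domain container."""
    obj.validate() if hasattr(obj, "validate") else obj.__post_init__()
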