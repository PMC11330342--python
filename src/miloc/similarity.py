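"""miRNA similarity measures and the networks derived from them.

Five similarity matrices feed the pipeline:

* ``GM`` — Gaussian interaction profile (GIP) kernel on binary
  miRNA-disease association profiles,
  ``GM(i,j) = exp(-lam * ||A_i - A_j||^2)`` with the bandwidth
  ``lam = n / sum_k ||A_k||^2`` normalized by the mean profile norm.
* ``SW`` — normalized Smith-Waterman local-alignment similarity,
  ``SW(i,j) = sp(i,j) / sqrt(sp(i,i) * sp(j,j))``.
* ``mFS`` — Wang-style functional similarity between the disease sets of two
  miRNAs, built on semantic similarity over the disease ontology with decay
  factor delta.
* ``SW_GM`` / ``mFS_GM`` — the above with zero entries back-filled by the GIP
  kernel, which otherwise leaves many pairs at exactly 0.

The fused functional similarity, thresholded at ``T``, yields the miRNA
functional network consumed by the graph attention auto-encoder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from .datatypes import (
    AssociationMatrix,
    DiseaseDAG,
    EntityIndex,
    SimilarityMatrix,
    ValidationError,
    WeightedGraph,
)

logger = logging.getLogger("miloc")


@dataclass(frozen=True)
class AlignmentScoring:
    """Linear-gap local alignment parameters."""

    match: float = 2.0
    mismatch: float = -1.0
    gap: float = -2.0

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap > 0:
            raise ValueError("mismatch and gap penalties must be <= 0")


def gip_kernel(assoc: AssociationMatrix) -> SimilarityMatrix:
    """GIP kernel similarity between miRNA association profiles."""
    A = assoc.values.astype(float)
    sq_norms = (A * A).sum(axis=1)
    total = sq_norms.sum()
    if total == 0:
        raise ValidationError("GIP bandwidth undefined: association matrix is all zero")
    lam = len(A) / total
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2 * A @ A.T
    np.maximum(sq_dist, 0.0, out=sq_dist)
    values = np.exp(-lam * sq_dist)
    values = (values + values.T) / 2  # exact symmetry against float jitter
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(assoc.rows, values)


def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap
    aligner.extend_gap_score = scoring.gap
    return aligner


def smith_waterman_score(
    a: str, b: str, scoring: AlignmentScoring = AlignmentScoring()
) -> float:
    """Best local-alignment score of two RNA sequences (linear gaps)."""
    if not a or not b:
        return 0.0
    return float(_aligner(scoring).score(a, b))


def alignment_score_matrix(
    sequences: Mapping[str, str],
    index: EntityIndex,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> np.ndarray:
    """All-vs-all local alignment scores sp(i, j) in index order."""
    missing = [m for m in index.ids if m not in sequences]
    if missing:
        raise ValidationError(f"missing sequence(s) for {missing[:5]}")
    aligner = _aligner(scoring)
    n = len(index)
    seqs = [sequences[m] for m in index.ids]
    sp = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if seqs[i] and seqs[j]:
                sp[i, j] = sp[j, i] = aligner.score(seqs[i], seqs[j])
    return sp


def sequence_similarity(sp: np.ndarray, index: EntityIndex) -> SimilarityMatrix:
    """Normalize alignment scores: SW(i,j) = sp(i,j)/sqrt(sp(i,i)*sp(j,j))."""
    sp = np.asarray(sp, dtype=float)
    diag = np.diag(sp)
    bad = np.flatnonzero(diag <= 0)
    if bad.size:
        raise ValidationError(
            f"non-positive self-alignment score for {index.ids[bad[0]]!r}"
        )
    values = sp / np.sqrt(np.outer(diag, diag))
    values = np.clip((values + values.T) / 2, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(index, values)


def fuse_with_gip(S: SimilarityMatrix, G: SimilarityMatrix) -> SimilarityMatrix:
    """Back-fill zero similarities with the GIP kernel (SW_GM / mFS_GM)."""
    if S.index.ids != G.index.ids:
        raise ValidationError("similarity matrices are over different miRNA indices")
    values = np.where(S.values > 0, S.values, G.values)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(S.index, values)


@dataclass
class SemanticCache:
    """Per-disease semantic contributions over the ancestor closure."""

    disease: str
    contributions: dict[str, float]  # dt -> D_di(dt), support = A(di)
    semantic_value: float            # DS(di) = sum of contributions


def semantic_values(dag: DiseaseDAG, disease: str) -> SemanticCache:
    """Decay-weighted contribution of each ancestor to ``disease``.

    The disease itself contributes 1; an ancestor contributes delta times the
    largest contribution among its children inside the closure.
    """
    closure = dag.ancestor_closure(disease)
    contributions: dict[str, float] = {}

    def contribution(dt: str) -> float:
        if dt in contributions:
            return contributions[dt]
        if dt == disease:
            val = 1.0
        else:
            val = max(
                dag.delta * contribution(c)
                for c in dag.children(dt)
                if c in closure
            )
        contributions[dt] = val
        return val

    for dt in closure:
        contribution(dt)
    return SemanticCache(disease, contributions, sum(contributions.values()))


def disease_semantic_similarity(dag: DiseaseDAG, di: str, dj: str) -> float:
    """Semantic similarity of two diseases over shared ancestors, in [0, 1]."""
    ci, cj = semantic_values(dag, di), semantic_values(dag, dj)
    shared = ci.contributions.keys() & cj.contributions.keys()
    if not shared:
        return 0.0
    num = sum(ci.contributions[t] + cj.contributions[t] for t in shared)
    return num / (ci.semantic_value + cj.semantic_value)


def semantic_similarity_matrix(
    dag: DiseaseDAG, diseases: Sequence[str]
) -> np.ndarray:
    """Pairwise semantic similarity for a disease list (vectorized)."""
    order = {d: i for i, d in enumerate(diseases)}
    all_nodes = sorted(dag.nodes)
    node_pos = {d: i for i, d in enumerate(all_nodes)}
    n, m = len(diseases), len(all_nodes)
    D = np.zeros((n, m))       # D[i, t] = contribution of node t to disease i
    ds = np.zeros(n)
    for d in diseases:
        cache = semantic_values(dag, d)
        i = order[d]
        for t, v in cache.contributions.items():
            D[i, node_pos[t]] = v
        ds[i] = cache.semantic_value
    support = D > 0
    # sum over shared ancestors of (D_i + D_j) = D_i . 1_j + D_j . 1_i
    cross = D @ support.T.astype(float)
    ss = (cross + cross.T) / (ds[:, None] + ds[None, :])
    np.fill_diagonal(ss, 1.0)
    return ss


def mirna_functional_similarity(
    disease_sets: Mapping[str, set[str]],
    dag: DiseaseDAG,
    index: EntityIndex | None = None,
) -> SimilarityMatrix:
    """Wang-style functional similarity between miRNA disease sets.

    For each disease of one miRNA the best semantic match in the other's set
    is taken; the two directed sums are averaged over the total set size.
    Pairs where both sets are empty get 0 off-diagonal (no evidence), and the
    diagonal is fixed at 1.
    """
    if index is None:
        index = EntityIndex(tuple(disease_sets), "mirna")
    diseases = sorted({d for s in disease_sets.values() for d in s})
    unknown = [d for d in diseases if d not in dag.nodes]
    if unknown:
        raise ValidationError(f"disease(s) absent from the ontology: {unknown[:5]}")
    n = len(index)
    if not diseases:
        values = np.zeros((n, n))
        np.fill_diagonal(values, 1.0)
        return SimilarityMatrix(index, values)
    dpos = {d: i for i, d in enumerate(diseases)}
    ss = semantic_similarity_matrix(dag, diseases)
    # membership Z (miRNA x disease) and best-match B[d, j] = max SS(d, DD_j)
    Z = np.zeros((n, len(diseases)))
    for i, m in enumerate(index.ids):
        for d in disease_sets.get(m, ()):
            Z[i, dpos[d]] = 1.0
    sizes = Z.sum(axis=1)
    B = np.zeros((len(diseases), n))
    for j in range(n):
        members = np.flatnonzero(Z[j])
        if members.size:
            B[:, j] = ss[:, members].max(axis=1)
    directed = Z @ B  # directed[i, j] = sum_{d in DD_i} max SS(d, DD_j)
    denom = sizes[:, None] + sizes[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, (directed + directed.T) / np.where(denom > 0, denom, 1), 0.0)
    values = np.clip((values + values.T) / 2, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(index, values)


def binarize_network(S: SimilarityMatrix, threshold: float | str) -> WeightedGraph:
    """Unweighted graph with an edge wherever similarity strictly exceeds T.

    ``threshold="auto"`` picks the 90th percentile of the off-diagonal
    similarities, targeting ~10% edge density regardless of how the
    similarity values are distributed.
    """
    if threshold == "auto":
        n = len(S.index)
        off = S.values[np.triu_indices(n, 1)] if n > 1 else np.array([0.0])
        threshold = float(np.quantile(off, 0.9))
    if not 0 <= threshold <= 1:
        raise ValidationError("binarization threshold must be in [0, 1]")
    mask = (S.values > threshold).astype(float)
    np.fill_diagonal(mask, 0.0)
    return WeightedGraph.from_dense(S.index.ids, mask)


def similarity_network(S: SimilarityMatrix) -> WeightedGraph:
    """Weighted graph connecting pairs with positive similarity.

    Used for the sequence-similarity network: the similarity score itself is
    the edge weight.
    """
    return WeightedGraph.from_dense(S.index.ids, S.values)
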