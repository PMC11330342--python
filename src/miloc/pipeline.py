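"""End-to-end feature construction: similarities -> networks -> embeddings ->
auto-encoder refinement -> co-localization ratios -> 452-D feature matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .coloc import assemble_features, coloc_feature_matrix
from .config import PipelineConfig
from .datatypes import (
    AssociationMatrix,
    DiseaseDAG,
    EntityIndex,
    FeatureBundle,
    LabelMatrix,
    SimilarityMatrix,
    WeightedGraph,
)
from .embed import embed_network
from .gate import gate_fit
from .similarity import (
    alignment_score_matrix,
    binarize_network,
    fuse_with_gip,
    gip_kernel,
    mirna_functional_similarity,
    sequence_similarity,
    similarity_network,
)

logger = logging.getLogger("miloc")


@dataclass
class FeaturizeResult:
    """Output of :func:`featurize`."""

    bundle: FeatureBundle
    features: np.ndarray                     # n x 452 under default dims
    similarities: "SimilarityStack"
    raw_association_blocks: dict[str, np.ndarray]  # pre-auto-encoder 128-D

    def __iter__(self):
        # backward-friendly unpacking: bundle, features, similarities
        return iter((self.bundle, self.features, self.similarities))


@dataclass
class SimilarityStack:
    """All similarity matrices and derived networks."""

    gm: SimilarityMatrix        # GIP kernel on disease associations
    sw: SimilarityMatrix        # normalized local-alignment similarity
    sw_gm: SimilarityMatrix     # SW back-filled with GIP
    mfs: SimilarityMatrix       # functional similarity
    mfs_gm: SimilarityMatrix    # functional similarity back-filled with GIP
    sequence_network: WeightedGraph    # weighted by SW_GM
    functional_network: WeightedGraph  # mFS_GM thresholded at T


def build_similarities(
    disease_assoc: AssociationMatrix,
    sequences: dict[str, str],
    dag: DiseaseDAG,
    config: PipelineConfig | None = None,
    sp_matrix: np.ndarray | None = None,
) -> SimilarityStack:
    """Compute GM, SW(_GM), mFS(_GM) and the two miRNA networks.

    ``sp_matrix`` optionally supplies precomputed pairwise local-alignment
    scores (index order must match the miRNA index).
    """
    config = config or PipelineConfig()
    index = disease_assoc.rows
    gm = gip_kernel(disease_assoc)
    if sp_matrix is None:
        sp_matrix = alignment_score_matrix(sequences, index)
    sw = sequence_similarity(sp_matrix, index)
    sw_gm = fuse_with_gip(sw, gm)
    disease_sets = {m: disease_assoc.partners_of(m) for m in index.ids}
    mfs = mirna_functional_similarity(disease_sets, dag, index)
    mfs_gm = fuse_with_gip(mfs, gm)
    return SimilarityStack(
        gm=gm, sw=sw, sw_gm=sw_gm, mfs=mfs, mfs_gm=mfs_gm,
        sequence_network=similarity_network(sw_gm),
        functional_network=binarize_network(mfs_gm, config.functional_threshold),
    )


def _bipartite_graph(assoc: AssociationMatrix) -> WeightedGraph:
    """Unweighted miRNA + partner graph from an association matrix."""
    nodes = list(assoc.rows.ids) + [f"{assoc.cols.kind}::{c}" for c in assoc.cols.ids]
    edges = [
        (assoc.rows.ids[i], f"{assoc.cols.kind}::{assoc.cols.ids[j]}")
        for i, j in zip(*np.nonzero(assoc.values))
    ]
    return WeightedGraph.from_edges(nodes, edges)


def featurize(
    dataset,
    config: PipelineConfig | None = None,
    similarities: SimilarityStack | None = None,
) -> FeaturizeResult:
    """Build the five feature blocks for every miRNA in the dataset.

    ``dataset`` is any object exposing ``mirna_index``, ``sequences``,
    ``disease_assoc``, ``drug_assoc``, ``mrna_assoc``, ``disease_dag`` and
    ``mrna_labels`` (see :class:`miloc.synthetic.SyntheticDataset`).
    Returns a :class:`FeaturizeResult`; unpacking it yields
    (bundle, flat n x 452 matrix, similarity stack).
    """
    config = config or PipelineConfig()
    index: EntityIndex = dataset.mirna_index
    if similarities is None:
        logger.info("computing similarity matrices")
        similarities = build_similarities(
            dataset.disease_assoc, dataset.sequences, dataset.disease_dag, config
        )

    nv = config.node2vec
    common = dict(p=nv.p, q=nv.q, walks_per_node=nv.walks_per_node,
                  walk_length=nv.walk_length, window=nv.window,
                  epochs=nv.epochs, negative=nv.negative)
    logger.info("embedding sequence-similarity network (%d-D)", config.sequence_dim)
    seq_block = embed_network(
        similarities.sequence_network, index, config.sequence_dim,
        seed=config.stage_seed("node2vec:sequence"), **common,
    )
    assoc_blocks = {}
    raw_blocks = {}
    for name, assoc in (("disease", dataset.disease_assoc),
                        ("drug", dataset.drug_assoc),
                        ("mrna_network", dataset.mrna_assoc)):
        logger.info("embedding %s association network (%d-D)",
                    name, config.association_dim)
        raw = embed_network(
            _bipartite_graph(assoc), index, config.association_dim,
            seed=config.stage_seed(f"node2vec:{name}"), **common,
        )
        raw_blocks[name] = raw
        if config.use_gate:
            logger.info("refining %s embedding with the graph auto-encoder", name)
            _, refined = gate_fit(
                raw, similarities.functional_network, config.gate,
                seed=config.stage_seed(f"gate:{name}"),
            )
            assoc_blocks[name] = refined
        else:
            assoc_blocks[name] = raw

    coloc_block = coloc_feature_matrix(dataset.mrna_assoc, dataset.mrna_labels)
    bundle, flat = assemble_features(
        index,
        sequence=seq_block,
        disease=assoc_blocks["disease"],
        drug=assoc_blocks["drug"],
        mrna_network=assoc_blocks["mrna_network"],
        coloc=coloc_block,
    )
    return FeaturizeResult(bundle, flat, similarities, raw_blocks)
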