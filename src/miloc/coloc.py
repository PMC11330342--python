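"""mRNA co-localization ratio features and final feature assembly.

For a miRNA m with target set M(m) (its neighbors in the miRNA-mRNA
association network), the co-localization feature for compartment c is the
fraction of targets annotated to c:

    R_c(m) = |M_c(m)| / |M(m)|,   c in {cytoplasm, exosome, nucleolus, nucleus}

The four ratios lie in [0, 1] and need not sum to 1 (mRNAs multi-localize).
A miRNA with no targets gets the zero vector (logged): an empty target set
carries no localization evidence.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import (
    AssociationMatrix,
    FeatureBundle,
    EntityIndex,
    LabelMatrix,
    MRNA_LOCALIZATIONS,
    ValidationError,
)

logger = logging.getLogger("miloc")


def target_set(mirna: str, net: AssociationMatrix) -> set[str]:
    """mRNAs associated with ``mirna`` in the miRNA-mRNA network."""
    return net.partners_of(mirna)


def coloc_features(
    mirna: str, net: AssociationMatrix, mrna_labels: LabelMatrix
) -> np.ndarray:
    """Four co-localization ratios for one miRNA."""
    return coloc_feature_matrix(net, mrna_labels)[net.rows.position(mirna)]


def coloc_feature_matrix(
    net: AssociationMatrix, mrna_labels: LabelMatrix
) -> np.ndarray:
    """Co-localization ratios for every miRNA (n x 4, canonical order)."""
    if mrna_labels.labels != MRNA_LOCALIZATIONS:
        raise ValidationError("mRNA labels must use the four-compartment order")
    missing = [g for g in net.cols.ids if g not in mrna_labels.index]
    if missing:
        raise ValidationError(
            f"mRNA(s) without localization labels: {missing[:5]}"
        )
    order = mrna_labels.index.positions(net.cols.ids)
    L = mrna_labels.values[order].astype(float)      # n_mrna x 4, net col order
    A = net.values.astype(float)                     # n_mirna x n_mrna
    counts = A @ L
    totals = A.sum(axis=1)
    empty = np.flatnonzero(totals == 0)
    if empty.size:
        logger.warning(
            "%d miRNA(s) have no mRNA targets; zero co-localization features",
            empty.size,
        )
    out = np.divide(
        counts, totals[:, None], out=np.zeros_like(counts), where=totals[:, None] > 0
    )
    return out


def assemble_features(
    index: EntityIndex,
    sequence: np.ndarray | None = None,
    disease: np.ndarray | None = None,
    drug: np.ndarray | None = None,
    mrna_network: np.ndarray | None = None,
    coloc: np.ndarray | None = None,
) -> tuple[FeatureBundle, np.ndarray]:
    """Bundle the five blocks and concatenate them in canonical order.

    Any subset of blocks may be supplied (ablation mode); at least one is
    required.  All present blocks must share the miRNA index length.
    """
    blocks = {
        name: np.asarray(b, dtype=float)
        for name, b in zip(
            FeatureBundle.BLOCK_ORDER,
            (sequence, disease, drug, mrna_network, coloc),
        )
        if b is not None
    }
    if not blocks:
        raise ValidationError("no feature blocks supplied")
    if len(index) == 0:
        raise ValidationError("empty miRNA index")
    bundle = FeatureBundle(index, blocks)
    return bundle, bundle.concat()
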