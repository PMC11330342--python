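"""Synthetic dataset generator with planted localization signal.

Emulates the structure of the real inputs — a seven-label miRNA localization
table, three bipartite association networks (disease / drug / mRNA), a disease
ontology, miRNA sequences and a four-label mRNA localization table — with a
tunable dependence between a miRNA's localizations and its association
partners.

The signal is planted indirectly: each partner entity carries a latent
localization affinity; with probability ``signal`` an association is drawn
from partners whose affinity matches one of the miRNA's localizations, else
uniformly.  mRNA labels correlate with the mRNA's affinity, and sequences
receive localization-specific motifs with probability ``signal``.  Features
are therefore informative only after the embedding / auto-encoder /
co-localization stages actually extract the shared-partner structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as mio
from .datatypes import (
    AssociationMatrix,
    DiseaseDAG,
    EntityIndex,
    LabelMatrix,
    MIRNA_LOCALIZATIONS,
    MRNA_LOCALIZATIONS,
    ValidationError,
)

#: one 6-mer seed motif per localization, planted into sequences
_MOTIFS = (
    "ACGACG",  # cytoplasm
    "UGGUGG",  # exosome
    "CCAUCC",  # nucleolus
    "GAUGAU",  # nucleus
    "AGCAGC",  # extracellular vesicle
    "UCCUCC",  # microvesicle
    "GGAGGA",  # mitochondrion
)


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_mirna: int = 300
    n_disease: int = 120
    n_drug: int = 40
    n_mrna: int = 400
    prevalences: tuple[float, ...] = (0.5, 0.85, 0.07, 0.3, 0.12, 0.6, 0.1)
    signal: float = 0.8
    mean_disease_assoc: float = 15.0
    mean_drug_assoc: float = 3.0
    mean_mrna_assoc: float = 8.0
    dag_extra_parent_prob: float = 0.1
    sequence_length: int = 22
    label_coupling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.prevalences) != 7:
            raise ValidationError("need 7 label prevalences")
        if not all(0 < p < 1 for p in self.prevalences):
            raise ValidationError("prevalences must lie in (0, 1)")
        if not 0 <= self.signal <= 1:
            raise ValidationError("signal must lie in [0, 1]")
        for name in ("n_mirna", "n_disease", "n_drug", "n_mrna"):
            if getattr(self, name) < 2:
                raise ValidationError(f"{name} must be >= 2")
        for name in ("mean_disease_assoc", "mean_drug_assoc", "mean_mrna_assoc"):
            if getattr(self, name) > min(self.n_disease, self.n_drug, self.n_mrna) * 4:
                raise ValidationError(f"{name} infeasible for partner pool size")


@dataclass
class SyntheticDataset:
    """Complete in-memory input bundle."""

    spec: SyntheticSpec
    mirna_index: EntityIndex
    labels: LabelMatrix
    sequences: dict[str, str]
    disease_assoc: AssociationMatrix
    drug_assoc: AssociationMatrix
    mrna_assoc: AssociationMatrix
    disease_dag: DiseaseDAG
    mrna_labels: LabelMatrix
    affinities: dict[str, np.ndarray] = field(default_factory=dict)

    def write(self, directory: str | Path) -> None:
        """Write every input in its on-disk format (deterministic bytes)."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        mio.write_label_matrix(d / "mirna_labels.tsv", self.labels)
        mio.write_label_matrix(d / "mrna_labels.tsv", self.mrna_labels)
        mio.write_fasta(d / "mirna_sequences.fasta", self.sequences)
        mio.write_association_table(d / "mirna_disease.tsv", self.disease_assoc)
        mio.write_association_table(d / "mirna_drug.tsv", self.drug_assoc)
        mio.write_association_table(d / "mirna_mrna.tsv", self.mrna_assoc)
        mio.write_disease_dag(d / "disease_dag.tsv", self.disease_dag)
        # ordered entity lists so column order survives a round-trip even for
        # partners that happen to have no association
        (d / "diseases.txt").write_text(
            "".join(f"{x}\n" for x in self.disease_assoc.cols.ids)
        )
        (d / "drugs.txt").write_text(
            "".join(f"{x}\n" for x in self.drug_assoc.cols.ids)
        )

    @classmethod
    def read(cls, directory: str | Path) -> "SyntheticDataset":
        """Load a bundle previously written by :meth:`write`."""
        d = Path(directory)
        labels = mio.read_label_matrix(d / "mirna_labels.tsv", "mirna")
        mrna_labels = mio.read_label_matrix(d / "mrna_labels.tsv", "mrna")
        sequences = mio.read_fasta(d / "mirna_sequences.fasta")
        idx = labels.index
        disease_idx = EntityIndex(
            tuple((d / "diseases.txt").read_text().split()), "disease"
        )
        drug_idx = EntityIndex(tuple((d / "drugs.txt").read_text().split()), "drug")
        disease_assoc = mio.read_association_table(
            d / "mirna_disease.tsv", rows=idx, cols=disease_idx
        )
        drug_assoc = mio.read_association_table(
            d / "mirna_drug.tsv", rows=idx, cols=drug_idx
        )
        mrna_assoc = mio.read_association_table(
            d / "mirna_mrna.tsv", rows=idx, cols=mrna_labels.index
        )
        dag = mio.read_disease_dag(
            d / "disease_dag.tsv", extra_nodes=disease_assoc.cols.ids
        )
        return cls(
            SyntheticSpec(), idx, labels, sequences, disease_assoc,
            drug_assoc, mrna_assoc, dag, mrna_labels,
        )


def _sample_labels(rng: np.random.Generator, n: int,
                   prevalences: tuple[float, ...]) -> np.ndarray:
    p = np.asarray(prevalences)
    Y = np.zeros((n, len(p)), dtype=np.int8)
    for i in range(n):
        while True:  # rejection-sample: every miRNA carries >= 1 label
            row = (rng.random(len(p)) < p).astype(np.int8)
            if row.any():
                Y[i] = row
                break
    return Y


def _sample_associations(
    rng: np.random.Generator,
    Y: np.ndarray,
    n_partners: int,
    mean_assoc: float,
    signal: float,
    affinity: np.ndarray,
    shared_only: bool = False,
    label_coupling: float = 0.0,
) -> np.ndarray:
    """Draw partner associations with localization-matched bias.

    ``affinity[j]`` is partner j's latent localization.  With probability
    ``signal`` a draw picks one of the miRNA's localizations uniformly and
    then a partner from the matching pool; otherwise a uniform partner.  When
    the matching pool is empty the draw falls back to uniform.
    """
    n = len(Y)
    A = np.zeros((n, n_partners), dtype=np.int8)
    pools = [np.flatnonzero(affinity == c) for c in range(7)]
    label_counts = Y.sum(axis=1)
    mean_labels = label_counts.mean()
    for i in range(n):
        mean_i = mean_assoc
        if label_coupling > 0:
            # miRNAs with more localizations get proportionally more partners
            mean_i *= 1 + label_coupling * (label_counts[i] / mean_labels - 1)
        k = max(1, rng.poisson(max(mean_i, 0.1)))
        own = np.flatnonzero(Y[i])
        if shared_only:
            own = own[own < 4]
        for _ in range(k):
            partner = -1
            if own.size and rng.random() < signal:
                c = int(rng.choice(own))
                if pools[c].size:
                    partner = int(rng.choice(pools[c]))
            if partner < 0:
                partner = int(rng.integers(n_partners))
            A[i, partner] = 1
    return A


def _random_dag(rng: np.random.Generator, ids: tuple[str, ...],
                extra_parent_prob: float) -> DiseaseDAG:
    """Random rooted tree plus occasional extra parent edges."""
    edges = []
    for i in range(1, len(ids)):
        parent = int(rng.integers(i))
        edges.append((ids[parent], ids[i]))
        if i > 1 and rng.random() < extra_parent_prob:
            second = int(rng.integers(i))
            if second != parent:
                edges.append((ids[second], ids[i]))
    return DiseaseDAG.from_edges(edges, extra_nodes=ids)


def _sequences(rng: np.random.Generator, ids: tuple[str, ...],
               Y: np.ndarray, length: int, signal: float) -> dict[str, str]:
    alphabet = np.array(list("ACGU"))
    seqs = {}
    for i, name in enumerate(ids):
        seq = list(rng.choice(alphabet, size=length))
        for c in np.flatnonzero(Y[i]):
            if rng.random() < signal:
                motif = _MOTIFS[c]
                start = int(rng.integers(length - len(motif) + 1))
                seq[start:start + len(motif)] = list(motif)
        seqs[name] = "".join(seq)
    return seqs


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a complete synthetic input bundle (deterministic in seed)."""
    rng = np.random.default_rng(spec.seed)
    mirna_ids = tuple(f"mir{i:04d}" for i in range(spec.n_mirna))
    disease_ids = tuple(f"dis{i:04d}" for i in range(spec.n_disease))
    drug_ids = tuple(f"drug{i:03d}" for i in range(spec.n_drug))
    mrna_ids = tuple(f"gene{i:04d}" for i in range(spec.n_mrna))

    index = EntityIndex(mirna_ids, "mirna")
    Y = _sample_labels(rng, spec.n_mirna, spec.prevalences)
    labels = LabelMatrix(index, MIRNA_LOCALIZATIONS, Y)

    aff_disease = rng.integers(7, size=spec.n_disease)
    aff_drug = rng.integers(7, size=spec.n_drug)
    # mRNA affinities live in the four shared compartments so co-localization
    # ratios can carry signal about them
    aff_mrna = rng.integers(4, size=spec.n_mrna)

    disease_assoc = AssociationMatrix(
        index, EntityIndex(disease_ids, "disease"),
        _sample_associations(rng, Y, spec.n_disease, spec.mean_disease_assoc,
                             spec.signal, aff_disease,
                             label_coupling=spec.label_coupling),
    )
    drug_assoc = AssociationMatrix(
        index, EntityIndex(drug_ids, "drug"),
        _sample_associations(rng, Y, spec.n_drug, spec.mean_drug_assoc,
                             spec.signal, aff_drug,
                             label_coupling=spec.label_coupling),
    )
    mrna_assoc = AssociationMatrix(
        index, EntityIndex(mrna_ids, "mrna"),
        _sample_associations(rng, Y, spec.n_mrna, spec.mean_mrna_assoc,
                             spec.signal, aff_mrna, shared_only=True,
                             label_coupling=spec.label_coupling),
    )

    # mRNA labels: the affinity compartment is present with probability
    # max(signal, base); other compartments at a background prevalence.
    base = np.array([0.45, 0.8, 0.1, 0.35])
    My = np.zeros((spec.n_mrna, 4), dtype=np.int8)
    for j in range(spec.n_mrna):
        row = (rng.random(4) < base).astype(np.int8)
        if spec.signal >= 1.0:
            row[:] = 0
        if rng.random() < max(spec.signal, base[aff_mrna[j]]):
            row[aff_mrna[j]] = 1
        if not row.any():
            row[aff_mrna[j]] = 1
        My[j] = row
    mrna_labels = LabelMatrix(EntityIndex(mrna_ids, "mrna"), MRNA_LOCALIZATIONS, My)

    dag = _random_dag(rng, disease_ids, spec.dag_extra_parent_prob)
    sequences = _sequences(rng, mirna_ids, Y, spec.sequence_length, spec.signal)

    return SyntheticDataset(
        spec, index, labels, sequences, disease_assoc, drug_assoc,
        mrna_assoc, dag, mrna_labels,
        affinities={"disease": aff_disease, "drug": aff_drug, "mrna": aff_mrna},
    )


def benchmark_instance(seed: int = 7) -> SyntheticDataset:
    """The canonical seeded benchmark dataset.

    300 miRNAs, 120 diseases, 40 drugs, 400 mRNAs, signal 0.8, with a label
    prevalence skew mimicking real localization data (an exosome-like label
    most frequent, a nucleolus-like label least).
    """
    return generate_dataset(SyntheticSpec(
        n_mirna=300, n_disease=120, n_drug=40, n_mrna=400,
        prevalences=(0.5, 0.85, 0.07, 0.3, 0.12, 0.6, 0.1),
        signal=0.8, seed=seed,
    ))
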