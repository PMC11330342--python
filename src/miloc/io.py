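"""Readers and writers for the pipeline's plain-text formats.

Associations and the disease ontology are TSV edge lists; similarity,
embedding, feature and label matrices are TSV tables with a header row of
column IDs and a leading column of row IDs; sequences are FASTA.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .datatypes import (
    AssociationMatrix,
    DiseaseDAG,
    EntityIndex,
    LabelMatrix,
    MIRNA_LOCALIZATIONS,
    MRNA_LOCALIZATIONS,
    ValidationError,
)

logger = logging.getLogger("miloc")


def _read_pairs(path: str | Path) -> list[tuple[str, str]]:
    pairs = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValidationError(
                f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        a, b = (f.strip() for f in fields)
        if not a or not b:
            raise ValidationError(f"{path}:{lineno}: empty identifier")
        pairs.append((a, b))
    return pairs


def _first_appearance_order(items: Sequence[str]) -> tuple[str, ...]:
    return tuple(dict.fromkeys(items))


def read_association_table(
    path: str | Path,
    rows: EntityIndex | None = None,
    cols: EntityIndex | None = None,
    row_kind: str = "mirna",
    col_kind: str = "disease",
) -> AssociationMatrix:
    """Read a two-column (row entity, column entity) TSV edge list.

    Lines beginning with ``#`` are comments.  When an index is not supplied it
    is inferred from the file in order of first appearance.  Duplicate pairs
    collapse to a single association (logged).
    """
    pairs = _read_pairs(path)
    if rows is None:
        rows = EntityIndex(_first_appearance_order([a for a, _ in pairs]), row_kind)
    if cols is None:
        cols = EntityIndex(_first_appearance_order([b for _, b in pairs]), col_kind)
    values = np.zeros((len(rows), len(cols)), dtype=np.int8)
    n_dup = 0
    for a, b in pairs:
        if a not in rows:
            raise ValidationError(f"{path}: unknown {rows.kind} id {a!r}")
        if b not in cols:
            raise ValidationError(f"{path}: unknown {cols.kind} id {b!r}")
        i, j = rows.position(a), cols.position(b)
        if values[i, j]:
            n_dup += 1
        values[i, j] = 1
    if n_dup:
        logger.warning("%s: collapsed %d duplicate association pair(s)", path, n_dup)
    return AssociationMatrix(rows, cols, values)


def write_association_table(path: str | Path, assoc: AssociationMatrix) -> None:
    with open(path, "w") as fh:
        for i, j in zip(*np.nonzero(assoc.values)):
            fh.write(f"{assoc.rows.ids[i]}\t{assoc.cols.ids[j]}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences keyed by the first header token; T is normalized to U."""
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in seqs:
            raise ValidationError(f"{path}: duplicate sequence id {name!r}")
        seq = str(record.seq).upper().replace("T", "U")
        if not seq:
            raise ValidationError(f"{path}: empty sequence for {name!r}")
        bad = set(seq) - set("ACGUN")
        if bad:
            raise ValidationError(
                f"{path}: sequence {name!r} has non-RNA characters {sorted(bad)}"
            )
        seqs[name] = seq
    return seqs


def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def read_disease_dag(
    path: str | Path,
    extra_nodes: Sequence[str] = (),
    delta: float = 0.5,
) -> DiseaseDAG:
    """Read a (parent, child) TSV edge list into an acyclic disease graph.

    ``extra_nodes`` adds isolated diseases (e.g. those present only in the
    association table).
    """
    return DiseaseDAG.from_edges(_read_pairs(path), extra_nodes=extra_nodes, delta=delta)


def write_disease_dag(path: str | Path, dag: DiseaseDAG) -> None:
    with open(path, "w") as fh:
        for u, v in dag.graph.edges:
            fh.write(f"{u}\t{v}\n")
        isolated = [n for n in dag.graph.nodes if dag.graph.degree(n) == 0]
        for n in isolated:
            fh.write(f"# isolated\t{n}\n")


def read_matrix(path: str | Path) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    """Read a TSV matrix with a column-ID header and row-ID first column."""
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype={0: str})
    if df.isna().any().any():
        raise ValidationError(f"{path}: ragged or missing values in matrix")
    return (
        tuple(str(r) for r in df.index),
        tuple(str(c) for c in df.columns),
        df.to_numpy(dtype=float),
    )


def write_matrix(
    path: str | Path,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    values: np.ndarray,
) -> None:
    values = np.asarray(values)
    if values.shape != (len(row_ids), len(col_ids)):
        raise ValidationError(
            f"matrix shape {values.shape} does not match ids "
            f"({len(row_ids)}, {len(col_ids)})"
        )
    df = pd.DataFrame(values, index=list(row_ids), columns=list(col_ids))
    # repr-precision floats so a write -> read round-trip is exact
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_label_matrix(path: str | Path, kind: str = "mirna") -> LabelMatrix:
    """Read a localization label table (entities x localization names).

    Columns outside the fixed vocabulary are dropped with a warning; missing
    localization columns are an error.
    """
    row_ids, col_ids, values = read_matrix(path)
    expected = MIRNA_LOCALIZATIONS if kind == "mirna" else MRNA_LOCALIZATIONS
    extra = [c for c in col_ids if c not in expected]
    if extra:
        logger.warning("%s: ignoring unsupported localization column(s) %s", path, extra)
    missing = [c for c in expected if c not in col_ids]
    if missing:
        raise ValidationError(f"{path}: missing localization column(s) {missing}")
    order = [col_ids.index(c) for c in expected]
    return LabelMatrix(
        EntityIndex(row_ids, kind), expected, values[:, order].astype(np.int8)
    )


def write_label_matrix(path: str | Path, labels: LabelMatrix) -> None:
    write_matrix(path, labels.index.ids, labels.labels, labels.values)
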