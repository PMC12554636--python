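"""Reading, validating and writing the three input kinds.

The pipeline consumes (a) a binary drug-disease association matrix,
(b) dense per-entity embedding tables produced upstream by pretrained
language models (or synthetic stand-ins), and (c) optional predefined
drug-drug / disease-disease similarity matrices (Tanimoto coefficients,
ontology-based semantic scores). Tabular formats are TSV/CSV with an ID
header row and ID index column; a MATLAB-style ``.mat`` container is also
accepted because public copies of the benchmark matrices circulate in both
forms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io

__all__ = [
    "AssociationTable",
    "SimilarityTable",
    "EmbeddingMatrix",
    "load_association_table",
    "write_association_table",
    "load_similarity_table",
    "write_similarity_table",
    "load_embedding_matrix",
    "write_embedding_matrix",
    "dataset_summary",
]

MODALITIES = ("small_molecule", "protein", "disease_text", "synthetic")

#: key aliases commonly used for the association matrix in .mat benchmark files
MAT_ASSOC_KEYS = ("didr", "drug_disease", "association", "A")


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what} identifiers: {dupes[:5]}")
    return ids


@dataclass
class AssociationTable:
    """Binary drug-disease association matrix with row/column identities.

    ``matrix[i, j] == 1`` records a validated association between drug
    ``drug_ids[i]`` and disease ``disease_ids[j]``; 0 means unknown (not a
    verified negative).
    """

    drug_ids: list[str]
    disease_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        self.matrix = np.asarray(self.matrix)
        bad = ~np.isin(self.matrix, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary association entry {self.matrix[i, j]!r} at "
                f"row {self.drug_ids[i]!r}, column {self.disease_ids[j]!r}"
            )
        self.matrix = self.matrix.astype(np.int8)
        if self.matrix.shape != (len(self.drug_ids), len(self.disease_ids)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.disease_ids)} diseases"
            )
        if self.matrix.sum() < 1:
            raise ValueError("association table has no positive entries")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_positives(self) -> int:
        return int(self.matrix.sum())


@dataclass
class SimilarityTable:
    """Square symmetric similarity matrix over one entity type, values in [0, 1]."""

    entity_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.entity_ids = _check_unique(self.entity_ids, "entity")
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"similarity matrix must be square, got shape {m.shape}")
        if m.shape[0] != len(self.entity_ids):
            raise ValueError("entity_ids length does not match matrix size")
        asym = float(np.abs(m - m.T).max()) if m.size else 0.0
        if asym > 1e-6:
            raise ValueError(f"similarity matrix asymmetry {asym:.3g} exceeds 1e-6")
        m = (m + m.T) / 2.0
        if m.min() < -1e-12 or m.max() > 1.0 + 1e-12:
            raise ValueError(
                f"similarity values must lie in [0, 1], got range "
                f"[{m.min():.3g}, {m.max():.3g}]"
            )
        self.matrix = np.clip(m, 0.0, 1.0)


@dataclass
class EmbeddingMatrix:
    """Dense entity-by-feature table with an explicit modality tag."""

    entity_ids: list[str]
    matrix: np.ndarray
    modality: str = "synthetic"

    def __post_init__(self) -> None:
        self.entity_ids = _check_unique(self.entity_ids, "entity")
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.matrix.shape[0] != len(self.entity_ids):
            raise ValueError(
                f"{len(self.entity_ids)} ids but {self.matrix.shape[0]} embedding rows"
            )
        if not np.isfinite(self.matrix).all():
            raise ValueError("embedding matrix contains non-finite values")

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


# ---------------------------------------------------------------------------
# loaders / writers
# ---------------------------------------------------------------------------


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower()
    if suffix == ".tsv":
        return "tsv"
    if suffix == ".csv":
        return "csv"
    if suffix == ".mat":
        return "mat_container"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format=")


def _read_frame(path: Path, fmt: str) -> pd.DataFrame:
    sep = "\t" if fmt == "tsv" else ","
    # round_trip parsing keeps write->load exact to the bit
    return pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")


def load_association_table(
    path,
    format: str | None = None,
    *,
    transpose: bool = False,
    mat_key: str | None = None,
) -> AssociationTable:
    """Load a drug-major (rows = drugs) binary association matrix.

    ``transpose=True`` accepts a disease-major source. For ``.mat``
    containers the matrix key is auto-detected among common aliases unless
    ``mat_key`` is given; IDs absent from the container are synthesized as
    ``drug_0 ...`` / ``disease_0 ...`` preserving stored order.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt in ("tsv", "csv"):
        frame = _read_frame(path, fmt)
        matrix = frame.to_numpy()
        drug_ids, disease_ids = list(frame.index), list(frame.columns)
    elif fmt == "mat_container":
        content = scipy.io.loadmat(path)
        keys = [mat_key] if mat_key else [k for k in MAT_ASSOC_KEYS if k in content]
        if not keys or keys[0] not in content:
            raise ValueError(
                f"no association key found in {path.name}; tried {MAT_ASSOC_KEYS}"
            )
        matrix = np.asarray(content[keys[0]])
        drug_ids = [f"drug_{i}" for i in range(matrix.shape[0])]
        disease_ids = [f"disease_{j}" for j in range(matrix.shape[1])]
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if transpose:
        matrix = matrix.T
        if fmt in ("tsv", "csv"):
            drug_ids, disease_ids = disease_ids, drug_ids
        else:
            drug_ids = [f"drug_{i}" for i in range(matrix.shape[0])]
            disease_ids = [f"disease_{j}" for j in range(matrix.shape[1])]
    return AssociationTable(drug_ids, disease_ids, matrix)


def write_association_table(table: AssociationTable, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt not in ("tsv", "csv"):
        raise ValueError("association tables are written as tsv or csv")
    frame = pd.DataFrame(table.matrix, index=table.drug_ids, columns=table.disease_ids)
    frame.to_csv(path, sep="\t" if fmt == "tsv" else ",")


def load_similarity_table(path, format: str | None = None) -> SimilarityTable:
    """Load a square similarity matrix; small asymmetry (<= 1e-6) is averaged out."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt not in ("tsv", "csv"):
        raise ValueError("similarity tables are read from tsv or csv")
    frame = _read_frame(path, fmt)
    return SimilarityTable(list(frame.index), frame.to_numpy())


def write_similarity_table(table: SimilarityTable, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    frame = pd.DataFrame(table.matrix, index=table.entity_ids, columns=table.entity_ids)
    frame.to_csv(path, sep="\t" if fmt == "tsv" else ",")


def load_embedding_matrix(path, format: str | None = None, modality: str = "synthetic") -> EmbeddingMatrix:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt not in ("tsv", "csv"):
        raise ValueError("embedding matrices are read from tsv or csv")
    frame = _read_frame(path, fmt)
    return EmbeddingMatrix(list(frame.index), frame.to_numpy(), modality=modality)


def write_embedding_matrix(emb: EmbeddingMatrix, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    frame = pd.DataFrame(emb.matrix, index=emb.entity_ids)
    frame.to_csv(path, sep="\t" if fmt == "tsv" else ",")


def dataset_summary(assoc: AssociationTable) -> dict:
    """Entity counts, positive count and matrix density for a dataset."""
    return {
        "n_drugs": assoc.n_drugs,
        "n_diseases": assoc.n_diseases,
        "n_positives": assoc.n_positives,
        "density": assoc.n_positives / (assoc.n_drugs * assoc.n_diseases),
    }
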