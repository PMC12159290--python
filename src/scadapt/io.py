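"""Reading, writing and validating the matrices the pipeline touches.

The on-disk formats are deliberately plain: dense delimited matrices
(first row = feature ids, first column = sample ids), Matrix Market
coordinate files with companion row/column id files, and CSV label /
survival / prediction tables.  Everything is validated into a
:class:`FeatureMatrix` before any modelling code sees it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread

Domain = Literal["bulk", "single_cell", "reference"]
Kind = Literal["embedding", "expression"]

__all__ = [
    "FeatureMatrix",
    "LabelTable",
    "GeneVocabulary",
    "VocabularyCoverage",
    "read_feature_matrix",
    "write_feature_matrix",
    "map_to_vocabulary",
    "read_label_table",
    "write_predictions",
]


class ValidationError(ValueError):
    """Raised when an input matrix or table violates its invariants."""


@dataclass
class FeatureMatrix:
    """An N x F real matrix with axis metadata and a domain tag.

    ``kind='embedding'`` holds model-derived features (any sign);
    ``kind='expression'`` holds raw expression and must be nonnegative.
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    domain: Domain = "bulk"
    kind: Kind = "embedding"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_ids = [str(c) for c in self.col_ids]
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n, f = self.values.shape
        if len(self.row_ids) != n:
            raise ValidationError(f"{len(self.row_ids)} row ids for {n} rows")
        if len(self.col_ids) != f:
            raise ValidationError(f"{len(self.col_ids)} col ids for {f} columns")
        if len(set(self.row_ids)) != n:
            raise ValidationError("duplicate row ids")
        if len(set(self.col_ids)) != f:
            raise ValidationError("duplicate col ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite values (NaN/Inf) present")
        if self.kind == "expression" and np.any(self.values < 0):
            raise ValidationError("expression matrices must be nonnegative")
        if self.domain not in ("bulk", "single_cell", "reference"):
            raise ValidationError(f"unknown domain {self.domain!r}")
        if self.kind not in ("embedding", "expression"):
            raise ValidationError(f"unknown kind {self.kind!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)


@dataclass
class LabelTable:
    """Binary drug-response labels: 0 = sensitive, 1 = resistant."""

    sample_ids: list[str]
    response: np.ndarray
    drug: str = ""
    cancer_type: str = ""

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.response = np.asarray(self.response, dtype=int)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in label table")
        if len(self.sample_ids) != self.response.shape[0]:
            raise ValidationError("label table length mismatch")
        if not np.isin(self.response, (0, 1)).all():
            raise ValidationError("responses must be 0 (sensitive) or 1 (resistant)")

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass
class GeneVocabulary:
    """A fixed, ordered gene-symbol vocabulary (e.g. the 19,264-gene set
    used by transcriptome foundation models)."""

    genes: list[str]

    def __post_init__(self) -> None:
        self.genes = [g.strip() for g in self.genes]
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("vocabulary genes must be unique")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class VocabularyCoverage:
    matched: int
    missing: int  # vocab genes absent from the input (zero-filled)
    dropped: int  # input genes absent from the vocabulary


def read_feature_matrix(
    path: str | Path,
    format: Literal["delimited", "matrix_market"] = "delimited",
    kind: Kind = "embedding",
    domain: Domain = "bulk",
    row_ids_path: str | Path | None = None,
    col_ids_path: str | Path | None = None,
    sep: str = ",",
) -> FeatureMatrix:
    """Read a matrix from disk into a validated :class:`FeatureMatrix`.

    Matrix Market inputs are coordinate (triplet) files with 1-based
    indices and must come with plain-text row/column id files, one id
    per line.  Sparse inputs are densified.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(set(header)) != len(header):
            raise ValidationError(f"duplicate feature ids in header of {path}")
        try:
            df = pd.read_csv(path, sep=sep, index_col=0,
                             float_precision="round_trip")
        except Exception as exc:  # surface the offending line when pandas knows it
            raise ValidationError(f"malformed delimited file {path}: {exc}") from exc
        values = df.to_numpy(dtype=float)
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in df.columns]
    elif format == "matrix_market":
        if row_ids_path is None or col_ids_path is None:
            raise ValidationError("matrix_market input requires row_ids_path and col_ids_path")
        raw = mmread(path)
        values = np.asarray(raw.todense() if sparse.issparse(raw) else raw, dtype=float)
        row_ids = _read_id_file(row_ids_path)
        col_ids = _read_id_file(col_ids_path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return FeatureMatrix(values=values, row_ids=row_ids, col_ids=col_ids, domain=domain, kind=kind)


def _read_id_file(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_feature_matrix(m: FeatureMatrix, path: str | Path, sep: str = ",") -> Path:
    """Write a FeatureMatrix as a delimited file (full float precision)."""
    path = Path(path)
    m.to_frame().to_csv(path, sep=sep)  # pandas repr round-trips float64
    return path


def map_to_vocabulary(
    m: FeatureMatrix, vocab: GeneVocabulary
) -> tuple[FeatureMatrix, VocabularyCoverage]:
    """Project an expression matrix onto a fixed gene vocabulary.

    Output columns are exactly ``vocab.genes`` in vocabulary order;
    vocabulary genes absent from the input are zero-filled and input
    genes outside the vocabulary are dropped.  Matching is exact on
    whitespace-stripped symbols (case-sensitive).
    """
    if m.kind != "expression":
        raise ValidationError("vocabulary mapping applies to expression matrices")
    stripped = [c.strip() for c in m.col_ids]
    col_index = {g: i for i, g in enumerate(stripped)}
    matched_positions = [(j, col_index[g]) for j, g in enumerate(vocab.genes) if g in col_index]
    if not matched_positions:
        raise ValidationError(
            "no genes matched the vocabulary — wrong identifier namespace?"
        )
    out = np.zeros((m.n_samples, vocab.size), dtype=float)
    dst = np.array([j for j, _ in matched_positions])
    src = np.array([i for _, i in matched_positions])
    out[:, dst] = m.values[:, src]
    coverage = VocabularyCoverage(
        matched=len(matched_positions),
        missing=vocab.size - len(matched_positions),
        dropped=m.n_features - len(matched_positions),
    )
    mapped = FeatureMatrix(
        values=out, row_ids=list(m.row_ids), col_ids=list(vocab.genes),
        domain=m.domain, kind=m.kind,
    )
    return mapped, coverage


def read_label_table(path: str | Path) -> LabelTable:
    df = pd.read_csv(path)
    required = {"sample_id", "response"}
    if not required.issubset(df.columns):
        raise ValidationError(f"label table must have columns {sorted(required)}")
    return LabelTable(
        sample_ids=[str(s) for s in df["sample_id"]],
        response=df["response"].to_numpy(),
        drug=str(df["drug"].iloc[0]) if "drug" in df.columns and len(df) else "",
        cancer_type=str(df["cancer_type"].iloc[0]) if "cancer_type" in df.columns and len(df) else "",
    )


def write_predictions(
    table: Sequence[tuple[str, float, float, str]], path: str | Path
) -> Path:
    """Write per-sample prediction rows ``(sample_id, p_sensitive,
    p_resistant, call)`` as CSV, preserving input order."""
    for row in table:
        sid, p_s, p_r, call = row
        if not (0.0 <= p_s <= 1.0 and 0.0 <= p_r <= 1.0):
            raise ValidationError(f"probabilities out of [0,1] for sample {sid}")
    path = Path(path)
    df = pd.DataFrame(table, columns=["sample_id", "p_sensitive", "p_resistant", "call"])
    df.to_csv(path, index=False, float_format="%.10g")
    return path
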