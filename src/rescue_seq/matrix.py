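"""Gene-by-sample expression container and its file formats.

The :class:`ExpressionMatrix` is the substrate every expression stage of the
pipeline operates on: a genes x samples table of nonnegative values (counts or
TPM), a class label per sample (e.g. ``control`` / ``disease`` / ``treated``),
and a flag recording whether values are raw linear measurements or have been
pedestal-log2 transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

LINEAR = "linear"
LOG2 = "log2"


class StateError(RuntimeError):
    """An operation was applied to a matrix in the wrong value space."""


@dataclass
class ExpressionMatrix:
    """Expression values plus per-sample class labels.

    Parameters
    ----------
    values
        DataFrame, rows indexed by gene id, columns by sample id.
    classes
        Series mapping sample id -> class label; must cover every column.
    space
        ``"linear"`` (raw nonnegative values) or ``"log2"``
        (pedestal-log2-transformed).
    """

    values: pd.DataFrame
    classes: pd.Series
    space: str = LINEAR

    def __post_init__(self) -> None:
        if self.space not in (LINEAR, LOG2):
            raise ValueError(f"unknown value space {self.space!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.classes = self.classes.reindex(self.values.columns)
        if self.classes.isna().any():
            missing = list(self.classes.index[self.classes.isna()])
            raise ValueError(f"samples without a class label: {missing}")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if self.space == LINEAR and arr.size and arr.min() < 0:
            raise ValueError("linear expression values must be nonnegative")

    # -- convenience -------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def class_names(self) -> list[str]:
        """Class labels in order of first appearance across samples."""
        return list(dict.fromkeys(self.classes))

    def samples_of(self, cls: str) -> list[str]:
        return list(self.classes.index[self.classes == cls])

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[list(genes)])

    def with_values(self, values: pd.DataFrame, space: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.classes, space or self.space)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @staticmethod
    def from_tsv(matrix_path, sample_sheet_path, space: str = LINEAR) -> "ExpressionMatrix":
        """Read a gene x sample TSV (first column gene id) plus a sample sheet.

        The sample sheet is a CSV with columns ``sample_id,class``.
        """
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        classes = read_sample_sheet(sample_sheet_path)
        return ExpressionMatrix(values, classes, space)

    @staticmethod
    def from_mtx(mtx_path, gene_ids_path, sample_ids_path, sample_sheet_path,
                 space: str = LINEAR) -> "ExpressionMatrix":
        """Read MatrixMarket values with one-id-per-line row/column files."""
        from scipy.io import mmread

        mat = mmread(str(mtx_path))
        if hasattr(mat, "todense"):
            mat = mat.todense()
        mat = np.asarray(mat)
        genes = _read_id_list(gene_ids_path)
        samples = _read_id_list(sample_ids_path)
        values = pd.DataFrame(mat, index=genes, columns=samples)
        return ExpressionMatrix(values, read_sample_sheet(sample_sheet_path), space)


def read_sample_sheet(path) -> pd.Series:
    sheet = pd.read_csv(path)
    required = {"sample_id", "class"}
    if not required.issubset(sheet.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    return pd.Series(sheet["class"].values, index=sheet["sample_id"].values, name="class")


def write_sample_sheet(classes: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": classes.index, "class": classes.values}).to_csv(path, index=False)


def _read_id_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
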