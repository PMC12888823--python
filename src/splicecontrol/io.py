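"""Matrix / phenotype I/O and the three preprocessing filters.

All expression matrices are feature-by-sample: rows are AS events, RBPs or
TFs, columns are samples.  Files are plain TSV/CSV with a header row of
sample IDs and the feature ID in the first column.  Empty cells, ``NA`` and
``NaN`` parse as missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

EPITHELIAL = 1
MESENCHYMAL = 2

_LABEL_ALIASES = {
    "1": EPITHELIAL,
    "2": MESENCHYMAL,
    "epithelial": EPITHELIAL,
    "mesenchymal": MESENCHYMAL,
}

_NA_VALUES = ["", "NA", "NaN"]


class FormatError(ValueError):
    """Raised for malformed matrix or phenotype files."""


@dataclass
class OmicsPanel:
    """Three feature-by-sample layers sharing one sample axis.

    ``as_matrix`` holds alternative-splicing event quantifications (e.g. PSI),
    ``rbp_matrix`` RNA-binding-protein expression and ``tf_matrix``
    transcription-factor expression.  ``labels`` maps every sample to
    epithelial (1) or mesenchymal (2).
    """

    as_matrix: pd.DataFrame
    rbp_matrix: pd.DataFrame
    tf_matrix: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        cols = list(self.as_matrix.columns)
        for name, mat in (("rbp", self.rbp_matrix), ("tf", self.tf_matrix)):
            if list(mat.columns) != cols:
                raise ValueError(f"{name} matrix sample axis differs from AS matrix")
        if len(set(cols)) != len(cols):
            raise ValueError("duplicate sample IDs")
        if list(self.labels.index) != cols:
            self.labels = self.labels.reindex(cols)
        if self.labels.isna().any():
            missing = list(self.labels.index[self.labels.isna()])
            raise ValueError(f"samples without phenotype label: {missing[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.as_matrix.columns)

    @property
    def n_samples(self) -> int:
        return self.as_matrix.shape[1]

    def layers(self) -> dict[str, pd.DataFrame]:
        return {"AS": self.as_matrix, "RBP": self.rbp_matrix, "TF": self.tf_matrix}

    def reorder(self, sample_order: list[str]) -> "OmicsPanel":
        """Apply one column permutation to all three layers and the labels."""
        if sorted(sample_order) != sorted(self.sample_ids):
            raise ValueError("sample_order is not a permutation of panel samples")
        return OmicsPanel(
            as_matrix=self.as_matrix[sample_order],
            rbp_matrix=self.rbp_matrix[sample_order],
            tf_matrix=self.tf_matrix[sample_order],
            labels=self.labels.reindex(sample_order),
        )

    def is_finite(self) -> bool:
        return all(np.isfinite(m.to_numpy()).all() for m in self.layers().values())


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature-by-sample matrix from TSV (or CSV by extension).

    The header row carries sample IDs, the first column feature IDs.  Missing
    markers (empty, ``NA``, ``NaN``) become NaN.  Duplicate feature IDs,
    ragged rows and zero-sample files are rejected.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0,
        na_values=_NA_VALUES,
        keep_default_na=False,
    )
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate feature IDs {dups[:5]}")
    try:
        df = df.astype(float)
    except ValueError as exc:  # non-numeric cell that is not a missing marker
        raise FormatError(f"{path}: non-numeric cell ({exc})") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    matrix.to_csv(path, sep=_sep_for(path), na_rep="NA", index_label="feature_id")


def read_phenotype(path: str | Path) -> pd.Series:
    """Read a phenotype table (columns sample_id, label) into sample -> {1,2}."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if not {"sample_id", "label"}.issubset(df.columns):
        raise FormatError(f"{path}: need columns sample_id and label")
    labels = {}
    for sid, raw in zip(df["sample_id"], df["label"]):
        key = str(raw).strip().lower()
        if key not in _LABEL_ALIASES:
            raise FormatError(f"{path}: unknown label {raw!r} for sample {sid}")
        if sid in labels:
            raise FormatError(f"{path}: duplicate sample {sid}")
        labels[sid] = _LABEL_ALIASES[key]
    return pd.Series(labels, name="label", dtype=int)


def write_phenotype(labels: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": labels.index, "label": labels.to_numpy()}).to_csv(
        path, sep=_sep_for(Path(path)), index=False
    )


def filter_missing_rows(matrix: pd.DataFrame, max_missing: int = 100) -> pd.DataFrame:
    """Drop rows with ``max_missing`` or more missing cells (order preserved)."""
    if max_missing < 0:
        raise ValueError("max_missing must be >= 0")
    keep = matrix.isna().sum(axis=1) < max_missing
    return matrix.loc[keep]


def knn_impute(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Fill missing cells from the k nearest feature rows.

    Distance between rows is nan-aware Euclidean over co-observed columns;
    a missing cell becomes the mean of that column over the k nearest rows
    that observe it.  Observed cells are untouched.
    """
    from sklearn.impute import KNNImputer

    if matrix.isna().all(axis=1).any():
        bad = matrix.index[matrix.isna().all(axis=1)].tolist()
        raise ValueError(f"rows with all cells missing cannot be imputed: {bad[:5]}")
    if not matrix.isna().any().any():
        return matrix.copy()
    k = min(k, matrix.shape[0] - 1)
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    values = imputer.fit_transform(matrix.to_numpy())
    return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)


def drop_zero_variance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Remove rows whose values are all identical (variance exactly zero)."""
    vals = matrix.to_numpy()
    keep = np.nanmax(vals, axis=1) != np.nanmin(vals, axis=1)
    return matrix.loc[keep]


def preprocess(matrix: pd.DataFrame, max_missing: int = 100, k: int = 10) -> pd.DataFrame:
    """The standard filter chain: missing-row filter, kNN imputation, zero-variance drop."""
    out = filter_missing_rows(matrix, max_missing=max_missing)
    if out.shape[0] == 0:
        return out
    out = knn_impute(out, k=k)
    return drop_zero_variance(out)


@dataclass
class PanelPaths:
    """File locations for one panel on disk."""

    as_matrix: Path
    rbp_matrix: Path
    tf_matrix: Path
    phenotype: Path

    @classmethod
    def in_dir(cls, directory: str | Path) -> "PanelPaths":
        d = Path(directory)
        return cls(
            as_matrix=d / "as_matrix.tsv",
            rbp_matrix=d / "rbp_matrix.tsv",
            tf_matrix=d / "tf_matrix.tsv",
            phenotype=d / "phenotype.tsv",
        )


def read_panel(directory: str | Path) -> OmicsPanel:
    p = PanelPaths.in_dir(directory)
    return OmicsPanel(
        as_matrix=read_matrix(p.as_matrix),
        rbp_matrix=read_matrix(p.rbp_matrix),
        tf_matrix=read_matrix(p.tf_matrix),
        labels=read_phenotype(p.phenotype),
    )


def write_panel(panel: OmicsPanel, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    p = PanelPaths.in_dir(d)
    write_matrix(panel.as_matrix, p.as_matrix)
    write_matrix(panel.rbp_matrix, p.rbp_matrix)
    write_matrix(panel.tf_matrix, p.tf_matrix)
    write_phenotype(panel.labels, p.phenotype)
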