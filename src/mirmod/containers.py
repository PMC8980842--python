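"""Core in-memory containers shared across the pipeline.

All matrices are features-by-samples pandas DataFrames with unique string
indices.  Expression values are on log2 scale once normalized; miRNA
abundances start life as raw integer counts and are converted to cpm
(counts per million) downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CountMatrix",
    "NormalizedMatrix",
    "SampleAnnotation",
    "MatrixError",
]


class MatrixError(ValueError):
    """Raised when a matrix container violates its invariants."""


def _check_frame(data: pd.DataFrame) -> None:
    if data.index.duplicated().any():
        dups = data.index[data.index.duplicated()].unique().tolist()
        raise MatrixError(f"duplicate feature ids: {dups}")
    if data.columns.duplicated().any():
        dups = data.columns[data.columns.duplicated()].unique().tolist()
        raise MatrixError(f"duplicate sample ids: {dups}")
    if data.isna().to_numpy().any():
        raise MatrixError("matrix contains missing values")


@dataclass
class ExpressionMatrix:
    """Features x samples matrix of (typically log2) expression values.

    Parameters
    ----------
    data:
        DataFrame indexed by feature id with sample ids as columns.
    kind:
        ``"gene"`` or ``"mir"``.
    """

    data: pd.DataFrame
    kind: str = "gene"

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "mir"):
            raise MatrixError(f"unknown feature kind {self.kind!r}")
        self.data = self.data.astype(float)
        _check_frame(self.data)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_features(self, features) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(features)], kind=self.kind)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)], kind=self.kind)


@dataclass
class CountMatrix:
    """Features x samples matrix of non-negative integer read counts."""

    data: pd.DataFrame
    kind: str = "mir"

    def __post_init__(self) -> None:
        _check_frame(self.data)
        values = self.data.to_numpy()
        if not np.allclose(values, np.round(values)):
            bad = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise MatrixError(
                "non-integer count at feature "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )
        if (values < 0).any():
            raise MatrixError("negative counts present")
        self.data = self.data.round().astype(np.int64)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.data.sum(axis=0)


NORMALIZATION_TAGS = ("cpm", "log2cpm", "quantile-log2")


@dataclass
class NormalizedMatrix(ExpressionMatrix):
    """Expression matrix carrying a normalization tag."""

    norm: str = "cpm"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.norm not in NORMALIZATION_TAGS:
            raise MatrixError(
                f"unknown normalization tag {self.norm!r}; expected one of {NORMALIZATION_TAGS}"
            )


@dataclass
class SampleAnnotation:
    """Per-sample metadata: group label, optional covariates and response label.

    ``table`` is indexed by sample id; ``group`` holds a two-level label set
    (e.g. case/control) and ``response`` holds responder/nonresponder or NA.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise MatrixError("duplicate sample ids in annotation")
        if "group" not in self.table.columns:
            raise MatrixError("annotation requires a 'group' column")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def group(self) -> pd.Series:
        return self.table["group"]

    def samples_in_group(self, label: str) -> list[str]:
        return list(self.table.index[self.table["group"] == label])

    def group_levels(self) -> list[str]:
        return sorted(self.table["group"].unique())
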