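"""The labeled-dataset container used throughout the package.

A dataset is an ``n x p`` numeric matrix (observations in rows, ``p >> n``
allowed) plus binary class labels coded 0/1. Missing values are represented
as NaN and are only meaningful to steps that handle them (imputation).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class LabeledDataset:
    """An i.i.d. two-class sample: predictor matrix, labels, variable names.

    Parameters
    ----------
    X : ndarray, shape (n, p)
        Numeric predictor matrix; NaN marks a missing entry.
    y : ndarray, shape (n,)
        Binary class labels in {0, 1}; both classes must be present.
    variable_names : tuple of str
        Length-p identifiers; generated as ``V1..Vp`` if not supplied.
    dataset_id : str
        Identifier used in reports.
    """

    X: np.ndarray
    y: np.ndarray
    variable_names: tuple[str, ...] = field(default=())
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix (observations in rows)")
        if y.shape != (X.shape[0],):
            raise ValueError(
                f"label length {y.shape} does not match {X.shape[0]} observations"
            )
        if np.any(~np.isfinite(y.astype(float))):
            raise ValueError("every observation needs a defined label")
        labels = np.unique(y)
        if not np.array_equal(labels, [0, 1]):
            raise ValueError(
                f"labels must be binary 0/1 with both classes present, got {labels!r}"
            )
        names = self.variable_names or tuple(f"V{j + 1}" for j in range(X.shape[1]))
        if len(names) != X.shape[1]:
            raise ValueError("variable_names length must equal the number of columns")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y.astype(int))
        object.__setattr__(self, "variable_names", tuple(names))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def class_counts(self) -> tuple[int, int]:
        return int(np.sum(self.y == 0)), int(np.sum(self.y == 1))

    @property
    def minority_proportion(self) -> float:
        c0, c1 = self.class_counts
        return min(c0, c1) / self.n
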