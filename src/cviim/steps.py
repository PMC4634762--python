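"""Preparation steps with fit-on-training and addon-transform halves.

An *addon procedure* prepares a test observation exactly as a corresponding
training observation would have been prepared, using information estimated
from the training data alone. Every step here therefore splits into
``fit`` (estimate the step's parameters on the training matrix and store
them) and the fitted step's ``transform`` (apply those frozen parameters to
any matrix — the training data itself, a held-out fold, or a single new
observation). Transforming the training data through the addon path *is*
its fit-time preparation; there is no second code path to drift.

Unsupervised steps (quantile normalization, global VSN, PCA, variance
filtering, imputation) expose ``fit(X)`` only — the interface itself keeps
the labels out of reach. Supervised steps (t-test variable selection,
tuning) take ``fit(X, y, seed)``.
"""
from __future__ import annotations

import abc
from typing import Any, Mapping

import numpy as np
import scipy.stats

from .classifiers import ClassifierSpec
from .exceptions import FitFailureError, PipelineCompositionError

__all__ = [
    "PrepStep",
    "FittedStep",
    "QuantileNormalization",
    "GlobalVSN",
    "PCAStep",
    "TTestSelection",
    "VarianceFilter",
    "MeanImputation",
    "TuningStep",
    "STEP_REGISTRY",
    "step_from_dict",
]


class PrepStep(abc.ABC):
    """A preparation procedure; ``fit`` returns its frozen, applicable state."""

    kind: str = "step"
    supervised: bool = False


class FittedStep(abc.ABC):
    """Fitted state of a step plus its addon transform.

    ``transform`` must accept matrices with any number of rows, down to a
    single observation (patients arriving one at a time are the extreme
    case an addon procedure exists for). ``param_override`` is non-None
    only for steps whose output is a tuning-parameter choice rather than a
    data transform.
    """

    kind: str = "step"
    param_override: Mapping[str, Any] | None = None

    @abc.abstractmethod
    def transform(self, X: np.ndarray) -> np.ndarray: ...

    def state(self) -> dict[str, Any]:
        """JSON-serializable fitted parameters, for audit logs."""
        return {}

    def _check_width(self, X: np.ndarray, p: int) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != p:
            raise PipelineCompositionError(
                f"step {self.kind!r}: expected {p} variables, got {X.shape[1]}"
            )
        return X


# --------------------------------------------------------------------------
# quantile normalization


def _map_rows_to_reference(X: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Replace each row's sorted values by the reference quantiles.

    Values are reassigned by each row's ranks; tied raw values receive the
    mean of the reference values at the tied ranks, so the output does not
    depend on how a sort happens to order ties.
    """
    n, p = X.shape
    order = np.argsort(X, axis=1, kind="stable")
    sorted_vals = np.take_along_axis(X, order, axis=1)
    out_sorted = np.broadcast_to(reference, (n, p)).copy()
    flat = sorted_vals.ravel()
    run_start = np.ones(n * p, dtype=bool)
    run_start[1:] = flat[1:] != flat[:-1]
    run_start[::p] = True  # a new row always starts a new tie-run
    starts = np.flatnonzero(run_start)
    counts = np.diff(np.append(starts, n * p))
    means = np.add.reduceat(out_sorted.ravel(), starts) / counts
    out_sorted = np.repeat(means, counts).reshape(n, p)
    out = np.empty_like(out_sorted)
    np.put_along_axis(out, order, out_sorted, axis=1)
    return out


class FittedQuantileNorm(FittedStep):
    kind = "quantile_norm"

    def __init__(self, reference: np.ndarray) -> None:
        self.reference = reference

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = self._check_width(X, self.reference.size)
        return _map_rows_to_reference(X, self.reference)

    def state(self) -> dict[str, Any]:
        return {"reference_quantiles": self.reference.tolist()}


class QuantileNormalization(PrepStep):
    """Quantile normalization with a training-derived reference distribution.

    Fitting averages the sorted value vectors of the training observations
    into a length-p reference; normalizing any observation replaces its
    sorted values by that reference, reassigned by the observation's own
    ranks. Applied to held-out data this is the addon scheme of Kostka and
    Spang: the test observation's quantiles are replaced by the training
    quantiles.
    """

    kind = "quantile_norm"

    def fit(self, X: np.ndarray) -> FittedQuantileNorm:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 1:
            raise ValueError("training matrix must be 2-D with p >= 1 variables")
        if not np.all(np.isfinite(X)):
            raise ValueError("quantile normalization requires finite values")
        reference = np.sort(X, axis=1).mean(axis=0)
        return FittedQuantileNorm(reference)


# --------------------------------------------------------------------------
# global variance stabilization (generalized-log transform)


class FittedGlobalVSN(FittedStep):
    kind = "global_vsn"

    def __init__(self, offset: float, scale: float, p: int) -> None:
        self.offset = offset
        self.scale = scale
        self.p = p

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = self._check_width(X, self.p)
        return np.arcsinh((X - self.offset) / self.scale)

    def state(self) -> dict[str, Any]:
        return {"offset": self.offset, "scale": self.scale}


class GlobalVSN(PrepStep):
    """Dataset-level variance-stabilizing glog transform.

    Applies ``arsinh((x - a) / b)``, which behaves like a log for large
    intensities (taming multiplicative noise, where the SD grows with the
    mean) and linearly near the offset. Only the two global parameters
    (a, b) are estimated — no observation-specific calibration — so the
    addon is simply reusing the training-estimated (a, b) on test data.
    Estimation here is a simple robust scheme: ``a`` is a low quantile of
    all training intensities and ``b`` a robust scale (scaled MAD) of the
    low-intensity stratum.
    """

    kind = "global_vsn"

    def __init__(self, offset_quantile: float = 0.05, low_quantile: float = 0.25) -> None:
        if not (0.0 <= offset_quantile < low_quantile <= 1.0):
            raise ValueError("need 0 <= offset_quantile < low_quantile <= 1")
        self.offset_quantile = offset_quantile
        self.low_quantile = low_quantile

    def fit(self, X: np.ndarray) -> FittedGlobalVSN:
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("variance stabilization requires finite values")
        values = X.ravel()
        a = float(np.quantile(values, self.offset_quantile))
        low = values[values <= np.quantile(values, self.low_quantile)]
        b = float(1.4826 * np.median(np.abs(low - np.median(low))))
        if b <= 0:
            raise FitFailureError(
                "degenerate scale estimate (b <= 0); intensities have no spread "
                "in the low stratum"
            )
        return FittedGlobalVSN(offset=a, scale=b, p=X.shape[1])


# --------------------------------------------------------------------------
# PCA


class FittedPCA(FittedStep):
    kind = "pca"

    def __init__(self, means: np.ndarray, loadings: np.ndarray) -> None:
        self.means = means
        self.loadings = loadings  # p x n_comp, orthonormal columns

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = self._check_width(X, self.means.size)
        return (X - self.means) @ self.loadings

    def state(self) -> dict[str, Any]:
        return {"means": self.means.tolist(), "loadings": self.loadings.tolist()}


class PCAStep(PrepStep):
    """Dimension reduction onto the leading principal components.

    Fitting runs an SVD of the column-centered training matrix and stores
    the training means together with the first ``n_comp`` loading vectors
    (orthonormal, ordered by decreasing singular value; each column's
    largest-magnitude entry is made positive, since the SVD sign is
    arbitrary). The addon centers new data by the *training* means and
    projects onto the stored loadings.
    """

    kind = "pca"

    def __init__(self, n_comp: int) -> None:
        if int(n_comp) < 1:
            raise ValueError(f"n_comp must be >= 1, got {n_comp!r}")
        self.n_comp = int(n_comp)

    def fit(self, X: np.ndarray) -> FittedPCA:
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if self.n_comp > min(n - 1, p):
            raise ValueError(
                f"n_comp={self.n_comp} exceeds min(n_train - 1, p) = {min(n - 1, p)}"
            )
        means = X.mean(axis=0)
        _, _, vt = np.linalg.svd(X - means, full_matrices=False)
        loadings = vt[: self.n_comp].T
        # sign convention: largest-|entry| of each loading made positive
        anchor = np.argmax(np.abs(loadings), axis=0)
        signs = np.sign(loadings[anchor, np.arange(loadings.shape[1])])
        signs[signs == 0] = 1.0
        return FittedPCA(means=means, loadings=loadings * signs)


# --------------------------------------------------------------------------
# variable selection / filtering


class FittedColumnSelection(FittedStep):
    def __init__(self, kind: str, indices: np.ndarray, p: int) -> None:
        self.kind = kind
        self.indices = indices
        self.p = p

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = self._check_width(X, self.p)
        return X[:, self.indices]

    def state(self) -> dict[str, Any]:
        return {"selected_indices": self.indices.tolist()}


class TTestSelection(PrepStep):
    """Supervised selection of the variables with smallest t-test p-values.

    A pooled-variance two-sample t-test per variable compares class means;
    the ``psel`` smallest p-values win. Zero-pooled-variance variables are
    uninformative and get p-value 1; p-value ties break toward the lower
    column index. The addon selects exactly the training-chosen columns in
    the test data.
    """

    kind = "ttest_select"
    supervised = True

    def __init__(self, psel: int, welch: bool = False) -> None:
        if int(psel) < 1:
            raise ValueError(f"psel must be >= 1, got {psel!r}")
        self.psel = int(psel)
        self.welch = bool(welch)

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int = 0) -> FittedColumnSelection:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if set(np.unique(y)) != {0, 1}:
            raise ValueError("t-test selection needs both classes present")
        if self.psel > X.shape[1]:
            raise ValueError(f"psel={self.psel} exceeds p={X.shape[1]}")
        with np.errstate(all="ignore"):
            result = scipy.stats.ttest_ind(
                X[y == 0], X[y == 1], axis=0, equal_var=not self.welch
            )
        pvalues = np.where(np.isfinite(result.pvalue), result.pvalue, 1.0)
        ranked = np.argsort(pvalues, kind="stable")  # stable => lower index on ties
        indices = np.sort(ranked[: self.psel])
        return FittedColumnSelection(self.kind, indices, X.shape[1])


class VarianceFilter(PrepStep):
    """Unsupervised retention of the ``m`` highest-variance variables."""

    kind = "variance_filter"

    def __init__(self, m: int) -> None:
        if int(m) < 1:
            raise ValueError(f"m must be >= 1, got {m!r}")
        self.m = int(m)

    def fit(self, X: np.ndarray) -> FittedColumnSelection:
        X = np.asarray(X, dtype=float)
        if self.m > X.shape[1]:
            raise ValueError(f"m={self.m} exceeds p={X.shape[1]}")
        variances = X.var(axis=0, ddof=1)
        ranked = np.argsort(-variances, kind="stable")  # ties -> lower index first
        indices = np.sort(ranked[: self.m])
        return FittedColumnSelection(self.kind, indices, X.shape[1])


# --------------------------------------------------------------------------
# imputation


class FittedImputation(FittedStep):
    kind = "mean_impute"

    def __init__(self, means: np.ndarray) -> None:
        self.means = means

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = self._check_width(X, self.means.size).copy()
        missing = np.isnan(X)
        if missing.any():
            X[missing] = np.broadcast_to(self.means, X.shape)[missing]
        return X

    def state(self) -> dict[str, Any]:
        return {"means": self.means.tolist()}


class MeanImputation(PrepStep):
    """Replace missing entries by per-variable training means.

    A representative, deliberately simple imputation scheme: the stored
    state is the vector of training column means, and the addon fills test
    missingness from the same vector.
    """

    kind = "mean_impute"

    def fit(self, X: np.ndarray) -> FittedImputation:
        X = np.asarray(X, dtype=float)
        all_missing = np.all(np.isnan(X), axis=0)
        if all_missing.any():
            raise FitFailureError(
                f"variable(s) {np.flatnonzero(all_missing).tolist()} entirely missing "
                "in the training data"
            )
        return FittedImputation(np.nanmean(X, axis=0))


# --------------------------------------------------------------------------
# tuning as a chain step


class FittedTuning(FittedStep):
    kind = "tune"

    def __init__(self, param: str, value: Any, p: int) -> None:
        self.param_override = {param: value}
        self.p = p

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self._check_width(X, self.p)

    def state(self) -> dict[str, Any]:
        return dict(self.param_override)


class TuningStep(PrepStep):
    """Tuning-parameter optimization modeled as a preparation step.

    Fitting runs internal 3-fold CV over the classifier's candidate grid
    on whatever data this step sees, and pins the winning value for the
    downstream classifier fit. Placed before the incompleteness boundary
    this reproduces the leaky practice of tuning once on the whole
    dataset; after the boundary, the parameter is re-chosen inside every
    CV training set.
    """

    kind = "tune"
    supervised = True

    def __init__(self, spec: ClassifierSpec, n_folds: int = 3) -> None:
        if spec.tune_param is None:
            raise ValueError("TuningStep needs a ClassifierSpec with tune_param set")
        self.spec = spec
        self.n_folds = int(n_folds)

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int = 0) -> FittedTuning:
        from .cv import tune_parameter

        X = np.asarray(X, dtype=float)
        value = tune_parameter(X, np.asarray(y), self.spec, seed=seed,
                               n_folds=self.n_folds)
        return FittedTuning(self.spec.tune_param, value, X.shape[1])


# --------------------------------------------------------------------------
# registry (for YAML configs)

STEP_REGISTRY: dict[str, type[PrepStep]] = {
    cls.kind: cls
    for cls in (
        QuantileNormalization,
        GlobalVSN,
        PCAStep,
        TTestSelection,
        VarianceFilter,
        MeanImputation,
        TuningStep,
    )
}


def step_from_dict(spec: Mapping[str, Any],
                   classifier: ClassifierSpec | None = None) -> PrepStep:
    """Build a step from a config mapping like ``{"kind": "pca", "n_comp": 5}``.

    A ``{"kind": "tune"}`` entry takes its grid from the study's classifier
    spec unless one is given inline.
    """
    params = dict(spec)
    kind = params.pop("kind", None)
    if kind not in STEP_REGISTRY:
        raise ValueError(f"unknown step kind {kind!r}; known: {sorted(STEP_REGISTRY)}")
    if kind == "tune":
        if classifier is None:
            raise ValueError("a 'tune' step needs the study's classifier spec")
        return TuningStep(classifier, **params)
    return STEP_REGISTRY[kind](**params)
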