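"""Two-class classifiers behind a uniform fit/predict contract.

Implemented natively: nearest shrunken centroids (NSC), linear discriminant
analysis (LDA), diagonal LDA (DLDA, usable when p >> n), LDA on partial
least squares components (PLS-LDA), and a majority-class baseline. Any
external method can participate through :func:`register_classifier` with
the same ``fit(X, y) -> fitted; predict(X) -> labels`` contract; a random
forest plug-in backed by scikit-learn is registered by default.

All native classifiers use empirical class priors by default (configurable
to uniform) and deterministic predictions given the fitted model; score
ties break toward class 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Mapping

import numpy as np
import scipy.linalg

from .exceptions import FitFailureError

__all__ = [
    "NearestShrunkenCentroids",
    "LinearDiscriminant",
    "DiagonalLinearDiscriminant",
    "PLSLinearDiscriminant",
    "MajorityClass",
    "ClassifierSpec",
    "register_classifier",
    "make_classifier",
    "classifier_entry",
]

# Relative floor applied to per-variable variances so DLDA/NSC stay defined
# on degenerate (constant) columns.
_VAR_FLOOR = 1e-12


def _validate_two_class(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be n x p and y length n")
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("training data must contain both classes 0 and 1")
    return X, y


def _log_priors(y: np.ndarray, priors: str) -> np.ndarray:
    if priors == "empirical":
        pi = np.array([np.mean(y == 0), np.mean(y == 1)])
    elif priors == "uniform":
        pi = np.array([0.5, 0.5])
    else:
        raise ValueError(f"priors must be 'empirical' or 'uniform', got {priors!r}")
    return np.log(pi)


def _pooled_variances(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    v = np.zeros(X.shape[1])
    for k in (0, 1):
        Xk = X[y == k]
        v += np.sum((Xk - Xk.mean(axis=0)) ** 2, axis=0)
    v /= max(n - 2, 1)
    floor = _VAR_FLOOR * max(float(v.mean()), 1.0)
    return np.maximum(v, floor)


class NearestShrunkenCentroids:
    """Nearest shrunken centroids with shrinkage intensity ``delta``.

    Class centroids are shrunk toward the overall centroid by
    soft-thresholding the standardized centroid deviations
    ``d_kj = (xbar_kj - xbar_j) / (m_k (s_j + s0))`` at ``delta``, where
    ``s_j`` is the pooled within-class standard deviation, ``s0`` its
    median (a stabilizing offset) and ``m_k = sqrt(1/n_k - 1/n)``.
    Prediction minimizes the standardized squared distance to the shrunken
    centroids minus twice the log prior. ``delta = 0`` leaves the centroids
    unshrunk; a very large ``delta`` collapses both centroids onto the
    overall centroid, so predictions are driven by the priors alone.
    """

    def __init__(self, delta: float = 0.5, priors: str = "empirical") -> None:
        if not (np.isfinite(delta) and delta >= 0):
            raise ValueError(f"delta must be finite and >= 0, got {delta!r}")
        self.delta = float(delta)
        self.priors = priors

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NearestShrunkenCentroids":
        X, y = _validate_two_class(X, y)
        n = X.shape[0]
        overall = X.mean(axis=0)
        s = np.sqrt(_pooled_variances(X, y))
        s0 = float(np.median(s))
        scale = s + s0
        centroids = np.empty((2, X.shape[1]))
        for k in (0, 1):
            nk = int(np.sum(y == k))
            mk = np.sqrt(max(1.0 / nk - 1.0 / n, 0.0))
            d = (X[y == k].mean(axis=0) - overall) / np.maximum(mk * scale, _VAR_FLOOR)
            d_shrunk = np.sign(d) * np.maximum(np.abs(d) - self.delta, 0.0)
            centroids[k] = overall + mk * scale * d_shrunk
        self.centroids_ = centroids
        self.scale_ = scale
        self.log_priors_ = _log_priors(y, self.priors)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        scores = np.stack(
            [
                np.sum(((X - self.centroids_[k]) / self.scale_) ** 2, axis=1)
                - 2.0 * self.log_priors_[k]
                for k in (0, 1)
            ],
            axis=1,
        )
        return (scores[:, 1] < scores[:, 0]).astype(int)


class LinearDiscriminant:
    """Two-class LDA with pooled within-class covariance.

    Requires more training observations than variables (apply only after
    dimension reduction or variable selection); an exactly or numerically
    singular pooled covariance raises :class:`FitFailureError` with a hint
    to reduce the dimension first.
    """

    def __init__(self, priors: str = "empirical") -> None:
        self.priors = priors

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearDiscriminant":
        X, y = _validate_two_class(X, y)
        n, p = X.shape
        if n <= p + 1:
            raise FitFailureError(
                f"LDA needs n > p + 1 for a well-conditioned pooled covariance "
                f"(got n={n}, p={p}); reduce the dimension first"
            )
        mu = np.stack([X[y == k].mean(axis=0) for k in (0, 1)])
        S = np.zeros((p, p))
        for k in (0, 1):
            Xc = X[y == k] - mu[k]
            S += Xc.T @ Xc
        S /= n - 2
        try:
            cho = scipy.linalg.cho_factor(S)
            w = scipy.linalg.cho_solve(cho, mu[1] - mu[0])
        except scipy.linalg.LinAlgError as exc:
            raise FitFailureError(
                "singular pooled covariance; reduce the dimension "
                "(PCA or variable selection) before LDA"
            ) from exc
        if not np.all(np.isfinite(w)):
            raise FitFailureError("pooled covariance is numerically singular")
        log_pi = _log_priors(y, self.priors)
        self.coef_ = w
        self.intercept_ = float(-0.5 * (mu[0] + mu[1]) @ w + (log_pi[1] - log_pi[0]))
        self.means_ = mu
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X @ self.coef_ + self.intercept_ > 0).astype(int)


class DiagonalLinearDiscriminant:
    """LDA under within-class independence of the variables (DLDA).

    The pooled covariance is replaced by its diagonal, so the fit is
    defined for any p, including p >> n. Equivalent to LDA when p = 1.
    """

    def __init__(self, priors: str = "empirical") -> None:
        self.priors = priors

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DiagonalLinearDiscriminant":
        X, y = _validate_two_class(X, y)
        self.means_ = np.stack([X[y == k].mean(axis=0) for k in (0, 1)])
        self.variances_ = _pooled_variances(X, y)
        self.log_priors_ = _log_priors(y, self.priors)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        scores = np.stack(
            [
                np.sum((X - self.means_[k]) ** 2 / self.variances_, axis=1)
                - 2.0 * self.log_priors_[k]
                for k in (0, 1)
            ],
            axis=1,
        )
        return (scores[:, 1] < scores[:, 0]).astype(int)


class PLSLinearDiscriminant:
    """LDA on ``n_comp`` partial least squares components (PLS-LDA).

    Components are extracted against the centered binary response with the
    NIPALS algorithm (X-deflation) as provided by scikit-learn's
    ``PLSRegression`` (``scale=False``); the first weight vector is
    therefore proportional to the per-variable covariances with the
    response. New observations are mapped through the training-derived
    centering and rotation (the addon-consistency contract for the
    embedded projection) before LDA scoring.
    """

    def __init__(self, n_comp: int = 2, priors: str = "empirical") -> None:
        if int(n_comp) < 1:
            raise ValueError(f"n_comp must be >= 1, got {n_comp!r}")
        self.n_comp = int(n_comp)
        self.priors = priors

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PLSLinearDiscriminant":
        from sklearn.cross_decomposition import PLSRegression

        X, y = _validate_two_class(X, y)
        n, p = X.shape
        if self.n_comp > min(n - 1, p):
            raise ValueError(
                f"n_comp={self.n_comp} exceeds min(n - 1, p) = {min(n - 1, p)}"
            )
        with np.errstate(all="ignore"):
            pls = PLSRegression(n_components=self.n_comp, scale=False)
            try:
                pls.fit(X, y.astype(float))
                scores = pls.transform(X)
            except Exception as exc:  # component extraction collapse
                raise FitFailureError(f"PLS component extraction failed: {exc}") from exc
        if not np.all(np.isfinite(scores)):
            raise FitFailureError(
                "PLS component extraction collapsed (zero covariance with the response)"
            )
        self._pls = pls
        self._lda = LinearDiscriminant(priors=self.priors).fit(scores, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._lda.predict(self._pls.transform(np.asarray(X, dtype=float)))


class MajorityClass:
    """Baseline predicting the most frequent training class (tie -> 0)."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MajorityClass":
        y = np.asarray(y, dtype=int)
        self.label_ = int(np.sum(y == 1) > np.sum(y == 0))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(np.asarray(X).shape[0], self.label_, dtype=int)


def _make_random_forest(
    mtry: int | None = None, n_estimators: int = 300, random_state: int = 0, **kw: Any
):
    """Plug-in around scikit-learn's random forest; ``mtry`` is the number
    of candidate variables per split."""
    from sklearn.ensemble import RandomForestClassifier

    return RandomForestClassifier(
        n_estimators=n_estimators,
        max_features=mtry if mtry is not None else "sqrt",
        random_state=random_state,
        **kw,
    )


@dataclass(frozen=True)
class _Entry:
    factory: Callable[..., Any]
    needs_seed: bool = False
    # per-parameter tie-break direction for internal-CV tuning:
    # "largest" = larger value is the simpler model (NSC delta),
    # "smallest" = smaller value is simpler (PLS n_comp, RF mtry).
    simpler: Mapping[str, str] = field(default_factory=dict)


_REGISTRY: dict[str, _Entry] = {}


def register_classifier(
    name: str,
    factory: Callable[..., Any],
    *,
    needs_seed: bool = False,
    simpler: Mapping[str, str] | None = None,
) -> None:
    """Register a classifier factory under ``name``.

    The factory must accept its parameters as keyword arguments and return
    an object with ``fit(X, y)`` and ``predict(X)``. ``simpler`` maps a
    tunable parameter name to "largest" or "smallest", the direction
    preferred when internal-CV tuning errors tie.
    """
    _REGISTRY[name] = _Entry(factory, needs_seed, dict(simpler or {}))


register_classifier("nsc", NearestShrunkenCentroids, simpler={"delta": "largest"})
register_classifier("lda", LinearDiscriminant)
register_classifier("dlda", DiagonalLinearDiscriminant)
register_classifier("pls_lda", PLSLinearDiscriminant, simpler={"n_comp": "smallest"})
register_classifier("majority", MajorityClass)
register_classifier(
    "rf", _make_random_forest, needs_seed=True, simpler={"mtry": "smallest"}
)


def classifier_entry(name: str) -> _Entry:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown classifier {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None


def make_classifier(name: str, params: Mapping[str, Any] | None = None,
                    seed: int | None = None):
    """Instantiate a registered classifier with ``params`` (and a seed for
    stochastic plug-ins)."""
    entry = classifier_entry(name)
    kwargs = dict(params or {})
    if entry.needs_seed and seed is not None:
        kwargs.setdefault("random_state", int(seed))
    return entry.factory(**kwargs)


@dataclass(frozen=True)
class ClassifierSpec:
    """Declarative classifier choice for a study configuration.

    ``tune_param``/``tune_grid`` request data-driven selection of one
    parameter by internal 3-fold CV (smallest error wins; ties break toward
    the simpler model per the registry). Where the parameter is actually
    chosen — once on the whole dataset, or anew inside every CV training
    set — is controlled by the study's step chain and boundary.
    """

    name: str
    params: tuple[tuple[str, Any], ...] = ()
    tune_param: str | None = None
    tune_grid: tuple[Any, ...] = ()

    def __post_init__(self) -> None:
        classifier_entry(self.name)  # validate eagerly
        if isinstance(self.params, dict):
            object.__setattr__(self, "params", tuple(sorted(self.params.items())))
        if self.tune_param is not None and not self.tune_grid:
            raise ValueError("tune_grid must be non-empty when tune_param is set")
        object.__setattr__(self, "tune_grid", tuple(self.tune_grid))

    @property
    def param_dict(self) -> dict[str, Any]:
        return dict(self.params)

    def tie_preference(self) -> str:
        if self.tune_param is None:
            return "smallest"
        return classifier_entry(self.name).simpler.get(self.tune_param, "smallest")
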