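"""Repeated K-fold cross-validation with a configurable incompleteness boundary.

A study configuration holds an ordered chain of preparation steps and a
*boundary* b: in the incomplete scheme, steps 1..b are trained once on the
whole dataset before any fold split (the leaky practice under study), while
steps b+1..m and the classifier are re-trained inside every CV iteration
and applied to the held-out fold through their addon transforms. The full
scheme is the same chain with boundary 0. Because a step performed inside
CV forces every subsequent step inside as well, a single boundary index is
the general form of a chain split.

Repetition b of the full and incomplete schemes shares one fold partition
(the per-repetition seed is derived from the master seed only), so the
per-repetition incompleteness estimates reflect incompleteness rather than
partition noise. Folds are stratified by class: the datasets of interest
are small and two-class, and stratification keeps every training fold
two-class, which every classifier here requires.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifiers import ClassifierSpec, make_classifier
from .dataset import LabeledDataset
from .exceptions import (
    DegenerateFoldError,
    InfeasiblePartitionError,
    PipelineCompositionError,
)
from .measure import CVEstimate, CviimResult, summarize_cviim

__all__ = [
    "FoldPartition",
    "StudyConfig",
    "PipelineRun",
    "derive_seed",
    "make_partition",
    "tune_parameter",
    "run_cv_once",
    "estimate_error",
    "cviim_for_dataset",
]


def derive_seed(*keys: int) -> int:
    """Deterministically derive a sub-seed (< 2**31) from integer keys.

    All randomness in a study flows from one master seed through this
    counter scheme, so full/incomplete schemes, repetitions, folds and
    tuning all get reproducible, independent streams.
    """
    state = np.random.SeedSequence([int(k) for k in keys]).generate_state(1)[0]
    return int(state % (2**31))


@dataclass(frozen=True)
class FoldPartition:
    """A class-stratified assignment of n observations to folds 1..K."""

    assignments: np.ndarray
    K: int
    seed: int

    def __post_init__(self) -> None:
        a = np.asarray(self.assignments, dtype=int)
        if a.min() < 1 or a.max() > self.K:
            raise ValueError("fold assignments must lie in 1..K")
        sizes = np.bincount(a, minlength=self.K + 1)[1:]
        if sizes.min() == 0 or sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")
        object.__setattr__(self, "assignments", a)


def make_partition(y: Sequence[int], K: int, seed: int) -> FoldPartition:
    """Draw a deterministic class-stratified K-fold partition.

    Raises :class:`InfeasiblePartitionError` when some class has fewer
    than K members (that class could not reach every fold).
    """
    y = np.asarray(y, dtype=int)
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    for label in np.unique(y):
        count = int(np.sum(y == label))
        if count < K:
            raise InfeasiblePartitionError(
                f"class {label} has only {count} members; cannot stratify into {K} folds"
            )
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=int(seed))
    assignments = np.empty(len(y), dtype=int)
    for fold_index, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y), 1):
        assignments[test_idx] = fold_index
    return FoldPartition(assignments=assignments, K=K, seed=int(seed))


@dataclass(frozen=True)
class StudyConfig:
    """One study setting: step chain, boundary, classifier, CV scheme sizes.

    ``boundary`` = number of leading steps performed once on the whole
    dataset in the incomplete scheme (``None`` means the whole chain, the
    common practice under study). ``B`` repeated runs of K-fold CV are
    averaged for each K in ``K_values``.
    """

    steps: tuple[Any, ...] = ()
    classifier: ClassifierSpec = field(
        default_factory=lambda: ClassifierSpec(name="dlda")
    )
    boundary: int | None = None
    K_values: tuple[int, ...] = (3, 5, 10)
    B: int = 300
    seed: int = 0
    name: str = "setting"

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple(self.steps))
        object.__setattr__(self, "K_values", tuple(int(k) for k in self.K_values))
        b = len(self.steps) if self.boundary is None else int(self.boundary)
        if not 0 <= b <= len(self.steps):
            raise ValueError(
                f"boundary must lie in 0..{len(self.steps)}, got {self.boundary}"
            )
        object.__setattr__(self, "boundary", b)
        if self.B < 1:
            raise ValueError("B must be >= 1")


@dataclass(frozen=True)
class PipelineRun:
    """Audit record of a single K-fold CV run."""

    predictions: np.ndarray
    pooled_error: float
    fold_errors: tuple[float, ...]
    fold_sizes: tuple[int, ...]
    boundary: int
    chosen_params: tuple[tuple[str, Any], ...]


def _fit_step(step: Any, X: np.ndarray, y: np.ndarray, seed: int):
    # Unsupervised steps expose fit(X) only, so they cannot read y.
    if getattr(step, "supervised", False):
        return step.fit(X, y, seed=seed)
    return step.fit(X)


def tune_parameter(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    seed: int,
    n_folds: int = 3,
) -> Any:
    """Choose ``spec.tune_param`` from ``spec.tune_grid`` by internal CV.

    Each candidate is evaluated by ``n_folds``-fold (default 3) stratified
    CV on the given data; the candidate with the smallest pooled error
    wins. Ties break toward the simpler model: the largest shrinkage for
    NSC, the smallest component count / mtry otherwise.
    """
    if spec.tune_param is None:
        raise ValueError("classifier spec has no tuning parameter")
    partition = make_partition(y, n_folds, derive_seed(seed, 0xCAFE))
    errors = []
    for value in spec.tune_grid:
        params = {**spec.param_dict, spec.tune_param: value}
        wrong = 0
        for fold in range(1, n_folds + 1):
            test = partition.assignments == fold
            model = make_classifier(spec.name, params, seed=derive_seed(seed, fold))
            model.fit(X[~test], y[~test])
            wrong += int(np.sum(model.predict(X[test]) != y[test]))
        errors.append(wrong / len(y))
    best = min(errors)
    candidates = [v for v, e in zip(spec.tune_grid, errors) if e == best]
    return max(candidates) if spec.tie_preference() == "largest" else min(candidates)


def run_cv_once(
    data: LabeledDataset,
    config: StudyConfig,
    partition: FoldPartition,
    boundary: int | None = None,
) -> PipelineRun:
    """One K-fold CV run for a given partition and incompleteness boundary.

    Steps before the boundary are fitted on the whole dataset and applied
    before splitting; the remaining steps and the classifier are fitted on
    each training fold and applied to the held-out fold via their addon
    transforms. Returns the pooled misclassification rate over all n
    observations (each predicted exactly once).
    """
    b = config.boundary if boundary is None else int(boundary)
    if not 0 <= b <= len(config.steps):
        raise ValueError(f"boundary must lie in 0..{len(config.steps)}")
    if partition.assignments.shape != (data.n,):
        raise ValueError("partition does not match the dataset size")

    X = data.X
    y = data.y
    overrides: dict[str, Any] = {}
    for idx, step in enumerate(config.steps[:b]):
        fitted = _fit_step(step, X, y, seed=derive_seed(partition.seed, 0, idx))
        X = _apply(fitted, X)
        if fitted.param_override:
            overrides.update(fitted.param_override)

    predictions = np.empty(data.n, dtype=int)
    fold_errors: list[float] = []
    fold_sizes: list[int] = []
    chosen: dict[str, Any] = dict(overrides)
    for fold in range(1, partition.K + 1):
        test = partition.assignments == fold
        X_tr, X_te = X[~test], X[test]
        y_tr = y[~test]
        if len(np.unique(y_tr)) < 2:
            raise DegenerateFoldError(
                f"training data for fold {fold} contains a single class"
            )
        fold_overrides = dict(overrides)
        for idx, step in enumerate(config.steps[b:], start=b):
            fitted = _fit_step(
                step, X_tr, y_tr, seed=derive_seed(partition.seed, fold, idx)
            )
            X_tr = _apply(fitted, X_tr)
            X_te = _apply(fitted, X_te)
            if fitted.param_override:
                fold_overrides.update(fitted.param_override)

        spec = config.classifier
        params = {**spec.param_dict, **fold_overrides}
        if spec.tune_param is not None and spec.tune_param not in fold_overrides:
            params[spec.tune_param] = tune_parameter(
                X_tr, y_tr, spec, seed=derive_seed(partition.seed, fold, 4093)
            )
        chosen.update({k: v for k, v in params.items() if k == spec.tune_param})
        model = make_classifier(
            spec.name, params, seed=derive_seed(partition.seed, fold, 911)
        )
        model.fit(X_tr, y_tr)
        predictions[test] = model.predict(X_te)
        fold_errors.append(float(np.mean(predictions[test] != y[test])))
        fold_sizes.append(int(np.sum(test)))

    pooled = float(np.mean(predictions != y))
    return PipelineRun(
        predictions=predictions,
        pooled_error=pooled,
        fold_errors=tuple(fold_errors),
        fold_sizes=tuple(fold_sizes),
        boundary=b,
        chosen_params=tuple(sorted(chosen.items())),
    )


def _apply(fitted: Any, X: np.ndarray) -> np.ndarray:
    try:
        return fitted.transform(X)
    except PipelineCompositionError:
        raise
    except Exception as exc:
        raise PipelineCompositionError(
            f"step {getattr(fitted, 'kind', type(fitted).__name__)!r} "
            f"could not transform the data: {exc}"
        ) from exc


def estimate_error(
    data: LabeledDataset,
    config: StudyConfig,
    K: int,
    B: int | None = None,
    scheme: str = "full",
) -> CVEstimate:
    """Average B repeated K-fold CV runs under one scheme.

    ``scheme="full"`` re-trains every step inside CV (boundary 0);
    ``scheme="incompl"`` applies the configured boundary. Per-repetition
    partition seeds depend only on (master seed, K, repetition), so the
    two schemes are paired run by run.
    """
    if scheme not in ("full", "incompl"):
        raise ValueError(f"scheme must be 'full' or 'incompl', got {scheme!r}")
    B = config.B if B is None else int(B)
    boundary = 0 if scheme == "full" else config.boundary
    errors = []
    for b in range(B):
        partition = make_partition(data.y, K, derive_seed(config.seed, K, b))
        errors.append(run_cv_once(data, config, partition, boundary=boundary).pooled_error)
    return CVEstimate(per_run_errors=tuple(errors), K=K, scheme=scheme)


def cviim_for_dataset(
    data: LabeledDataset,
    config: StudyConfig,
    K: int,
    B: int | None = None,
) -> CviimResult:
    """CVIIM of one dataset for one setting and one K.

    Runs the paired full and incomplete schemes (shared partitions per
    repetition) and summarizes: truncated CVIIM of the B-run error means,
    per-repetition INIMEs with their 25%/75% quartiles, and the
    rules-of-thumb category.
    """
    full = estimate_error(data, config, K, B, scheme="full")
    incompl = estimate_error(data, config, K, B, scheme="incompl")
    return summarize_cviim(full, incompl)


def with_seed(config: StudyConfig, seed: int) -> StudyConfig:
    """Copy of ``config`` with a different master seed."""
    return replace(config, seed=int(seed))
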