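"""Estimators of the impact of cross-validation incompleteness.

The central quantity is the CV Incompleteness Impact Measure (CVIIM): the
zero-truncated relative shortfall of the error estimated by *incomplete*
K-fold CV (one or more preparation steps trained once on the whole dataset)
against the error estimated by *full* K-fold CV (every step re-trained per
CV iteration and applied to the held-out fold via its addon transform).

For empirical errors ``e_incompl`` and ``e_full`` (each the average of B
repeated K-fold CV runs) the plug-in estimate is::

    CVIIM = 1 - e_incompl / e_full   if e_incompl < e_full and e_full > 0
            0                        otherwise

CVIIM lies in [0, 1]: 0 means the incomplete practice costs nothing, values
near 1 mean the incomplete error estimate is severely optimistic. The
population version of the measure (expectations over samples of size n from
the data-generating distribution) has no runtime representation here; the
plug-in estimator above is its only estimator.

Also provided: the per-repetition *iterationwise non-truncated
incompleteness measure estimates* (INIMEs) ``1 - e_incompl,b / e_full,b``
whose 25%/75% quartiles summarize run-to-run variability; the global CVIIM
pooling error averages across a collection of datasets; the tentative
rules-of-thumb categorization; and the (dispreferred) zero-truncated
difference measure.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CVEstimate",
    "CviimResult",
    "GlobalCviimResult",
    "cviim_estimate",
    "global_cviim",
    "inime_values",
    "inime_quartiles",
    "categorize",
    "zero_truncated_difference",
    "summarize_cviim",
    "CATEGORIES",
]

#: Rules-of-thumb bins: left-open/right-closed intervals over [0, 1].
CATEGORIES: tuple[tuple[float, str], ...] = (
    (0.02, "no influence"),
    (0.10, "weak"),
    (0.20, "medium"),
    (0.40, "strong"),
    (1.00, "very strong"),
)


def _check_error(name: str, value: float, upper: float | None = None) -> float:
    value = float(value)
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and non-negative, got {value!r}")
    if upper is not None and value > upper:
        raise ValueError(f"{name} must be at most {upper}, got {value!r}")
    return value


def cviim_estimate(e_incompl: float, e_full: float) -> float:
    """Plug-in CVIIM estimate from a pair of (averaged) CV errors.

    Parameters
    ----------
    e_incompl : float
        Misclassification rate from incomplete K-fold CV, >= 0.
    e_full : float
        Misclassification rate from full K-fold CV, >= 0.

    Returns
    -------
    float in [0, 1]
        ``1 - e_incompl/e_full`` when the incomplete error undershoots a
        positive full error; 0 otherwise (truncation keeps the measure
        non-negative when incomplete CV happens to look worse).
    """
    e_incompl = _check_error("e_incompl", e_incompl)
    e_full = _check_error("e_full", e_full)
    if e_full > 0 and e_incompl < e_full:
        return 1.0 - e_incompl / e_full
    return 0.0


def zero_truncated_difference(e_incompl: float, e_full: float) -> float:
    """Alternative measure ``max(0, e_full - e_incompl)``.

    Kept for comparison only: unlike the ratio-based CVIIM its value scales
    with the size of the error itself, which makes it a measure of the
    error rather than of the incompleteness impact.
    """
    e_incompl = _check_error("e_incompl", e_incompl, upper=1.0)
    e_full = _check_error("e_full", e_full, upper=1.0)
    return max(0.0, e_full - e_incompl)


def categorize(value: float) -> str:
    """Map a CVIIM value in [0, 1] to its rules-of-thumb category.

    The bins are left-open/right-closed: 0.02 is still "no influence",
    0.0201 is "weak", and so on up to "very strong" on (0.4, 1].
    """
    value = _check_error("value", value, upper=1.0)
    for bound, label in CATEGORIES:
        if value <= bound:
            return label
    raise AssertionError("unreachable")  # pragma: no cover


@dataclass(frozen=True)
class CVEstimate:
    """Error estimate from B repeated runs of one K-fold CV scheme.

    ``scheme`` is ``"full"`` (every preparation step re-trained inside CV)
    or ``"incompl"`` (the steps under study trained once on the whole
    dataset beforehand).
    """

    per_run_errors: tuple[float, ...]
    K: int
    scheme: str

    def __post_init__(self) -> None:
        errors = tuple(float(e) for e in self.per_run_errors)
        if len(errors) < 1:
            raise ValueError("at least one CV run is required (B >= 1)")
        if any(not (0.0 <= e <= 1.0) for e in errors):
            raise ValueError("every per-run error must lie in [0, 1]")
        if self.scheme not in ("full", "incompl"):
            raise ValueError(f"scheme must be 'full' or 'incompl', got {self.scheme!r}")
        object.__setattr__(self, "per_run_errors", errors)

    @property
    def B(self) -> int:
        return len(self.per_run_errors)

    @property
    def mean_error(self) -> float:
        return float(np.mean(self.per_run_errors))


def inime_values(full: CVEstimate, incompl: CVEstimate) -> tuple[np.ndarray, int]:
    """Per-repetition non-truncated incompleteness estimates (INIMEs).

    Repetition b of the full and incomplete schemes must be paired (same
    fold partition), so element b is ``1 - e_incompl,b / e_full,b``. The
    values are *not* truncated at zero. Repetitions with zero full-CV error
    leave the ratio undefined; those elements are dropped and their count
    returned alongside.

    Returns
    -------
    (ndarray, int)
        The defined INIMEs in repetition order, and the number dropped.
    """
    if full.B != incompl.B:
        raise ValueError(f"B mismatch: full has {full.B} runs, incompl has {incompl.B}")
    e_full = np.asarray(full.per_run_errors)
    e_inc = np.asarray(incompl.per_run_errors)
    defined = e_full > 0
    values = 1.0 - e_inc[defined] / e_full[defined]
    return values, int(np.sum(~defined))


def inime_quartiles(inimes: Sequence[float]) -> tuple[float, float]:
    """Empirical 25% and 75% quantiles of the INIMEs.

    Uses linear interpolation between order statistics (the "type 7"
    convention, numpy's default) so reported values are reproducible.
    """
    inimes = np.asarray(inimes, dtype=float)
    if inimes.size == 0:
        raise ValueError("cannot take quartiles of an empty sequence")
    q25, q75 = np.quantile(inimes, [0.25, 0.75])
    return float(q25), float(q75)


@dataclass(frozen=True)
class GlobalCviimResult:
    """Global CVIIM over a collection of L datasets (plug-in estimator)."""

    value: float
    mean_incompl: float
    mean_full: float
    dataset_ids: tuple[str, ...]

    @property
    def n_datasets(self) -> int:
        return len(self.dataset_ids)


def global_cviim(
    e_incompl_list: Sequence[float],
    e_full_list: Sequence[float],
    dataset_ids: Sequence[str] | None = None,
) -> GlobalCviimResult:
    """Plug-in global CVIIM: CVIIM of the across-dataset error averages.

    Pooling the errors before forming the ratio makes the estimate robust
    to individual datasets with tiny full-CV errors, which can produce
    extreme per-dataset CVIIM values.
    """
    e_inc = [
        _check_error(f"e_incompl_list[{i}]", e, upper=1.0)
        for i, e in enumerate(e_incompl_list)
    ]
    e_full = [
        _check_error(f"e_full_list[{i}]", e, upper=1.0)
        for i, e in enumerate(e_full_list)
    ]
    if len(e_inc) != len(e_full):
        raise ValueError(
            f"length mismatch: {len(e_inc)} incomplete vs {len(e_full)} full errors"
        )
    if not e_inc:
        raise ValueError("at least one dataset is required")
    if dataset_ids is None:
        ids = tuple(f"dataset{i + 1}" for i in range(len(e_inc)))
    else:
        ids = tuple(str(d) for d in dataset_ids)
        if len(ids) != len(e_inc):
            raise ValueError("dataset_ids length must match the error lists")
    mean_inc = float(np.mean(e_inc))
    mean_full = float(np.mean(e_full))
    return GlobalCviimResult(
        value=cviim_estimate(mean_inc, mean_full),
        mean_incompl=mean_inc,
        mean_full=mean_full,
        dataset_ids=ids,
    )


@dataclass(frozen=True)
class CviimResult:
    """CVIIM for one dataset/setting/K, with its per-run diagnostics.

    ``value`` is the truncated plug-in estimate from the B-run error
    averages; ``inimes`` are the per-repetition non-truncated estimates
    (mean of ratios differs from the ratio of means in general, so the mean
    INIME is *not* the CVIIM value); ``n_dropped`` counts repetitions whose
    zero full-CV error left the INIME undefined.
    """

    value: float
    inimes: tuple[float, ...]
    q25: float
    q75: float
    category: str
    n_dropped: int
    e_full: float
    e_incompl: float
    K: int
    B: int
    full: CVEstimate | None = None
    incompl: CVEstimate | None = None


def summarize_cviim(full: CVEstimate, incompl: CVEstimate) -> CviimResult:
    """Assemble a :class:`CviimResult` from a paired pair of CV estimates."""
    if full.K != incompl.K:
        raise ValueError("full and incomplete estimates must use the same K")
    inimes, n_dropped = inime_values(full, incompl)
    if inimes.size:
        q25, q75 = inime_quartiles(inimes)
    else:  # all runs had zero full-CV error; quartiles undefined
        q25 = q75 = float("nan")
    value = cviim_estimate(incompl.mean_error, full.mean_error)
    return CviimResult(
        value=value,
        inimes=tuple(float(v) for v in inimes),
        q25=q25,
        q75=q75,
        category=categorize(value),
        n_dropped=n_dropped,
        e_full=full.mean_error,
        e_incompl=incompl.mean_error,
        K=full.K,
        B=full.B,
        full=full,
        incompl=incompl,
    )
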