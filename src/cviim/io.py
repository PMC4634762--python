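"""Dataset/config I/O, multi-dataset study orchestration and reporting."""
from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .classifiers import ClassifierSpec
from .cv import StudyConfig, cviim_for_dataset, derive_seed
from .dataset import LabeledDataset
from .exceptions import DataFormatError
from .measure import CVEstimate, global_cviim, summarize_cviim
from .steps import step_from_dict

__all__ = [
    "read_dataset",
    "write_dataset",
    "config_from_dict",
    "ResultRow",
    "GlobalRow",
    "StudyReport",
    "run_study",
    "sensitivity_drop_datasets",
]

#: decimal places used in flat-text reports
REPORT_PRECISION = 4


def read_dataset(
    matrix_path: str | Path,
    labels_path: str | Path | None = None,
    label_column: str | None = None,
    sep: str | None = None,
    dataset_id: str | None = None,
) -> LabeledDataset:
    """Read a labeled dataset from delimited text (observations in rows).

    The matrix file must have a header row of variable names; "NA"/empty
    cells become missing values. Labels come either from ``label_column``
    of the matrix file or from a separate one-column ``labels_path`` file.
    Any two distinct label values are accepted and mapped to 0/1 in sorted
    order; more (or fewer) than two levels is an error.
    """
    matrix_path = Path(matrix_path)
    try:
        frame = pd.read_csv(matrix_path, sep=sep, engine="python",
                            na_values=["NA", "NaN", ""])
    except Exception as exc:
        raise DataFormatError(f"could not parse {matrix_path}: {exc}") from exc

    if label_column is not None:
        if label_column not in frame.columns:
            raise DataFormatError(
                f"label column {label_column!r} not found in {matrix_path}"
            )
        raw_labels = frame[label_column]
        frame = frame.drop(columns=[label_column])
    elif labels_path is not None:
        try:
            raw_labels = pd.read_csv(labels_path, sep=sep, engine="python").iloc[:, 0]
        except Exception as exc:
            raise DataFormatError(f"could not parse {labels_path}: {exc}") from exc
        if len(raw_labels) != len(frame):
            raise DataFormatError(
                f"{len(raw_labels)} labels for {len(frame)} observations"
            )
    else:
        raise DataFormatError("provide either labels_path or label_column")

    levels = sorted(pd.unique(raw_labels.dropna()))
    if len(levels) != 2:
        raise DataFormatError(
            f"labels must be binary, found {len(levels)} level(s): {levels!r}"
        )
    y = raw_labels.map({levels[0]: 0, levels[1]: 1}).to_numpy()
    if np.any(pd.isna(y)):
        raise DataFormatError("some observations have missing labels")

    bad = [c for c in frame.columns if not pd.api.types.is_numeric_dtype(frame[c])]
    if bad:
        raise DataFormatError(f"non-numeric cells in column(s) {bad!r}")
    return LabeledDataset(
        X=frame.to_numpy(dtype=float),
        y=y.astype(int),
        variable_names=tuple(str(c) for c in frame.columns),
        dataset_id=dataset_id or matrix_path.stem,
    )


def write_dataset(data: LabeledDataset, matrix_path: str | Path,
                  labels_path: str | Path) -> None:
    """Write a dataset as a TSV matrix plus a one-column TSV label file."""
    frame = pd.DataFrame(data.X, columns=list(data.variable_names))
    frame.to_csv(matrix_path, sep="\t", index=False, na_rep="NA")
    pd.DataFrame({"label": data.y}).to_csv(labels_path, sep="\t", index=False)


def config_from_dict(raw: Mapping[str, Any]) -> StudyConfig:
    """Build a StudyConfig from a parsed YAML/JSON mapping."""
    raw = dict(raw)
    clf_raw = dict(raw.get("classifier", {"name": "dlda"}))
    tune = clf_raw.pop("tune", None)
    spec = ClassifierSpec(
        name=clf_raw.pop("name"),
        params=tuple(sorted(clf_raw.items())),
        tune_param=tune["param"] if tune else None,
        tune_grid=tuple(tune["grid"]) if tune else (),
    )
    steps = tuple(step_from_dict(s, classifier=spec) for s in raw.get("steps", []))
    return StudyConfig(
        steps=steps,
        classifier=spec,
        boundary=raw.get("boundary"),
        K_values=tuple(raw.get("K", (3, 5, 10))),
        B=int(raw.get("B", 300)),
        seed=int(raw.get("seed", 0)),
        name=str(raw.get("setting", raw.get("name", "setting"))),
    )


@dataclass(frozen=True)
class ResultRow:
    """CVIIM of one (dataset, setting, K), with raw per-run errors kept so
    every derived number is recomputable."""

    dataset_id: str
    setting: str
    K: int
    B: int
    e_full: float
    e_incompl: float
    cviim: float
    q25: float
    q75: float
    category: str
    n_dropped: int
    per_run_full: tuple[float, ...]
    per_run_incompl: tuple[float, ...]


@dataclass(frozen=True)
class GlobalRow:
    setting: str
    K: int
    value: float
    mean_full: float
    mean_incompl: float
    dataset_ids: tuple[str, ...]


@dataclass(frozen=True)
class StudyReport:
    rows: tuple[ResultRow, ...]
    globals_: tuple[GlobalRow, ...]
    metadata: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "rows": [asdict(r) for r in self.rows],
            "globals": [asdict(g) for g in self.globals_],
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "StudyReport":
        rows = tuple(
            ResultRow(
                **{
                    **r,
                    "per_run_full": tuple(r["per_run_full"]),
                    "per_run_incompl": tuple(r["per_run_incompl"]),
                }
            )
            for r in raw["rows"]
        )
        globals_ = tuple(
            GlobalRow(**{**g, "dataset_ids": tuple(g["dataset_ids"])})
            for g in raw["globals"]
        )
        return cls(rows=rows, globals_=globals_, metadata=dict(raw.get("metadata", {})))

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load_json(cls, path: str | Path) -> "StudyReport":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def summary_frame(self) -> pd.DataFrame:
        """Flat per-(dataset, setting, K) table, values at report precision."""
        records = []
        for r in self.rows:
            records.append(
                {
                    "dataset_id": r.dataset_id,
                    "setting": r.setting,
                    "K": r.K,
                    "B": r.B,
                    "e_full": round(r.e_full, REPORT_PRECISION),
                    "e_incompl": round(r.e_incompl, REPORT_PRECISION),
                    "cviim": round(r.cviim, REPORT_PRECISION),
                    "q25": round(r.q25, REPORT_PRECISION),
                    "q75": round(r.q75, REPORT_PRECISION),
                    "category": r.category,
                }
            )
        return pd.DataFrame.from_records(records)

    def global_frame(self) -> pd.DataFrame:
        records = [
            {
                "setting": g.setting,
                "K": g.K,
                "global_cviim": round(g.value, REPORT_PRECISION),
                "mean_e_full": round(g.mean_full, REPORT_PRECISION),
                "mean_e_incompl": round(g.mean_incompl, REPORT_PRECISION),
                "n_datasets": len(g.dataset_ids),
            }
            for g in self.globals_
        ]
        return pd.DataFrame.from_records(records)

    def save_tsv(self, path: str | Path) -> None:
        self.summary_frame().to_csv(path, sep="\t", index=False)


def _row_from_result(dataset_id: str, setting: str, result) -> ResultRow:
    return ResultRow(
        dataset_id=dataset_id,
        setting=setting,
        K=result.K,
        B=result.B,
        e_full=result.e_full,
        e_incompl=result.e_incompl,
        cviim=result.value,
        q25=result.q25,
        q75=result.q75,
        category=result.category,
        n_dropped=result.n_dropped,
        per_run_full=result.full.per_run_errors,
        per_run_incompl=result.incompl.per_run_errors,
    )


def run_study(
    datasets: Sequence[LabeledDataset],
    settings: Sequence[StudyConfig],
    seed: int | None = None,
) -> StudyReport:
    """Full (dataset x setting x K) grid of CVIIM values plus the global
    CVIIM per (setting, K).

    Each dataset gets its own sub-seed derived from the master seed, so the
    whole report is deterministic. A guideline-style warning (not an
    error) is emitted below 10 datasets, where the global estimate rests
    on a thin universe.
    """
    if not datasets:
        raise ValueError("at least one dataset is required")
    if len(datasets) < 10:
        warnings.warn(
            f"only {len(datasets)} dataset(s); at least 10 are recommended for "
            "a global CVIIM assessment",
            UserWarning,
            stacklevel=2,
        )
    master = settings[0].seed if seed is None else int(seed)
    rows: list[ResultRow] = []
    for s_idx, setting in enumerate(settings):
        # the sub-seed depends on the setting only, so identical datasets
        # under identical seeds yield identical rows
        config = replace(setting, seed=derive_seed(master, s_idx))
        for data in datasets:
            for K in setting.K_values:
                result = cviim_for_dataset(data, config, K)
                rows.append(_row_from_result(data.dataset_id, setting.name, result))

    globals_: list[GlobalRow] = []
    for setting in settings:
        for K in setting.K_values:
            group = [r for r in rows if r.setting == setting.name and r.K == K]
            g = global_cviim(
                [r.e_incompl for r in group],
                [r.e_full for r in group],
                dataset_ids=[r.dataset_id for r in group],
            )
            globals_.append(
                GlobalRow(
                    setting=setting.name,
                    K=K,
                    value=g.value,
                    mean_full=g.mean_full,
                    mean_incompl=g.mean_incompl,
                    dataset_ids=g.dataset_ids,
                )
            )
    metadata = {
        "master_seed": master,
        "n_datasets": len(datasets),
        "settings": [s.name for s in settings],
        "B": {s.name: s.B for s in settings},
        "stratified_folds": True,
    }
    return StudyReport(rows=tuple(rows), globals_=tuple(globals_), metadata=metadata)


def sensitivity_drop_datasets(
    report: StudyReport,
    setting: str,
    K_pair: tuple[int, int] = (3, 10),
    n_drop: int = 1,
) -> dict[int, GlobalRow]:
    """Re-estimate the global CVIIM after dropping unstable datasets.

    A strong decrease of the global estimate with K flags datasets whose
    full-CV error depends heavily on the training-set size; dropping the
    ``n_drop`` datasets with the largest ``|e_full,K1 - e_full,K2|`` and
    recomputing is the recommended sensitivity check. Returns one
    recomputed global row per K available for the setting.
    """
    K1, K2 = K_pair
    rows = [r for r in report.rows if r.setting == setting]
    if not rows:
        raise ValueError(f"setting {setting!r} not found in the report")
    by_K: dict[int, dict[str, ResultRow]] = {}
    for r in rows:
        by_K.setdefault(r.K, {})[r.dataset_id] = r
    if K1 not in by_K or K2 not in by_K:
        raise ValueError(f"report lacks K={K1} or K={K2} for setting {setting!r}")
    ids = sorted(by_K[K1])
    if n_drop >= len(ids):
        raise ValueError(f"n_drop={n_drop} must be smaller than L={len(ids)}")
    gaps = {d: abs(by_K[K1][d].e_full - by_K[K2][d].e_full) for d in ids}
    dropped = set(sorted(ids, key=lambda d: (-gaps[d], d))[:n_drop])
    kept = [d for d in ids if d not in dropped]

    out: dict[int, GlobalRow] = {}
    for K, per_dataset in sorted(by_K.items()):
        group = [per_dataset[d] for d in kept if d in per_dataset]
        g = global_cviim(
            [r.e_incompl for r in group],
            [r.e_full for r in group],
            dataset_ids=[r.dataset_id for r in group],
        )
        out[K] = GlobalRow(
            setting=setting,
            K=K,
            value=g.value,
            mean_full=g.mean_full,
            mean_incompl=g.mean_incompl,
            dataset_ids=g.dataset_ids,
        )
    return out


def recompute_row(row: ResultRow) -> ResultRow:
    """Rebuild a row's summary numbers from its stored per-run errors."""
    full = CVEstimate(per_run_errors=row.per_run_full, K=row.K, scheme="full")
    incompl = CVEstimate(per_run_errors=row.per_run_incompl, K=row.K, scheme="incompl")
    return _row_from_result(row.dataset_id, row.setting, summarize_cviim(full, incompl))
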