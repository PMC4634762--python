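"""Shared runners for the replicated null-data studies used in the
end-to-end checks."""
import numpy as np

from cviim import (
    ClassifierSpec,
    QuantileNormalization,
    StudyConfig,
    TTestSelection,
    VarianceFilter,
    cviim_for_dataset,
    generate,
)
from cviim.simulate import null_spec


def leakage_study(n_datasets=20, B=50, K=5, seed=0):
    """Mean CVIIM over replicate null datasets (n=40, p=2000) for three
    practices performed before CV: supervised t-test selection (psel=10),
    variance filtering (keep p/2), quantile normalization."""
    settings = {
        "ttest_select": (TTestSelection(psel=10),),
        "variance_filter": (VarianceFilter(m=1000),),
        "quantile_norm": (QuantileNormalization(),),
    }
    values = {name: [] for name in settings}
    for rep in range(n_datasets):
        data = generate(null_spec(seed=seed + rep, dataset_id=f"null{rep}"))
        for name, steps in settings.items():
            config = StudyConfig(
                steps=steps, classifier=ClassifierSpec(name="dlda"),
                B=B, seed=seed + rep,
            )
            values[name].append(cviim_for_dataset(data, config, K=K).value)
    return {name: float(np.mean(v)) for name, v in values.items()}


def sample_size_study(n_small=30, n_large=120, n_datasets=10, B=25, K=5, seed=0):
    """Mean CVIIM of whole-dataset t-test selection (psel=10) on null data
    at two sample sizes; returns (mean at n_small, mean at n_large)."""
    means = []
    for n in (n_small, n_large):
        vals = []
        for rep in range(n_datasets):
            data = generate(
                null_spec(n_per_class=n // 2, seed=seed + rep,
                          dataset_id=f"null_n{n}_{rep}")
            )
            config = StudyConfig(
                steps=(TTestSelection(psel=10),),
                classifier=ClassifierSpec(name="dlda"),
                B=B, seed=seed + rep,
            )
            vals.append(cviim_for_dataset(data, config, K=K).value)
        means.append(float(np.mean(vals)))
    return means[0], means[1]
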