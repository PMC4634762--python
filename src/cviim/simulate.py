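"""Seeded generator of two-class, high-dimensional, expression-like data.

Predictors are Gaussian with a block-equicorrelated covariance (a
self-contained parametric stand-in for the gene-cluster correlation seen in
transcriptomic matrices): variables come in blocks of ``block_size`` with
within-block correlation ``rho`` and independence across blocks. The first
``n_informative`` variables carry a class-mean shift of ``effect_size``
standard deviations. Optional extras: an intensity-scale version obtained
by exponentiation (multiplicative noise, so the per-variable SD grows with
the mean — the regime a variance-stabilizing transform targets) and a
missing-completely-at-random mask.

Defaults emulate the small-n / large-p two-class microarray regime:
40 observations, 2000 correlated predictors, a modest number of informative
genes at a one-SD effect.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .classifiers import ClassifierSpec
from .cv import StudyConfig
from .dataset import LabeledDataset
from .steps import PCAStep, QuantileNormalization, TTestSelection, VarianceFilter

__all__ = ["GeneratorSpec", "generate", "StudyPreset", "study_presets"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic dataset.

    effect_size is the standardized mean difference per informative
    variable; rho must keep the block covariance positive definite
    (rho > -1/(block_size - 1)).
    """

    n_per_class: int = 20
    p: int = 2000
    n_informative: int = 20
    effect_size: float = 1.0
    block_size: int = 25
    rho: float = 0.4
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    multiplicative_noise: bool = False
    intensity_log_sd: float = 0.25
    seed: int = 0
    dataset_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.p < 1:
            raise ValueError("n_per_class and p must be positive")
        if not 0 <= self.n_informative <= self.p:
            raise ValueError("n_informative must lie in 0..p")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 1 <= self.block_size:
            raise ValueError("block_size must be >= 1")
        if abs(self.rho) >= 1 or (
            self.block_size > 1 and self.rho <= -1.0 / (self.block_size - 1)
        ):
            raise ValueError(
                "block covariance not positive definite: need "
                f"-1/(block_size-1) < rho < 1, got rho={self.rho}"
            )


def _block_cholesky(m: int, rho: float) -> np.ndarray:
    block = np.full((m, m), rho)
    np.fill_diagonal(block, 1.0)
    return np.linalg.cholesky(block)


def generate(spec: GeneratorSpec) -> LabeledDataset:
    """Draw one dataset; bitwise deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_per_class
    y = np.repeat([0, 1], spec.n_per_class)

    m = min(spec.block_size, spec.p)
    n_blocks = -(-spec.p // m)  # ceil
    Z = rng.standard_normal((n, n_blocks * m))
    if m > 1 and spec.rho != 0.0:
        L = _block_cholesky(m, spec.rho)
        Z = (Z.reshape(n, n_blocks, m) @ L.T).reshape(n, n_blocks * m)
    X = Z[:, : spec.p] * spec.noise_sd

    if spec.n_informative and spec.effect_size:
        shift = spec.effect_size * spec.noise_sd
        X[y == 1, : spec.n_informative] += shift

    if spec.multiplicative_noise:
        # intensity scale: lognormal around per-variable baselines, so the
        # per-variable SD is roughly proportional to the mean
        baselines = np.exp(rng.uniform(np.log(20.0), np.log(2000.0), size=spec.p))
        X = baselines * np.exp(spec.intensity_log_sd * X / spec.noise_sd)

    if spec.missing_rate > 0:
        mask = rng.random(X.shape) < spec.missing_rate
        X = X.copy()
        X[mask] = np.nan

    return LabeledDataset(X=X, y=y, dataset_id=spec.dataset_id)


def null_spec(**overrides) -> GeneratorSpec:
    """A label-independent (no-signal) variant of the default generator."""
    base = GeneratorSpec(n_informative=0, effect_size=0.0)
    return replace(base, **overrides)


@dataclass(frozen=True)
class StudyPreset:
    """A ready-to-run miniature study: one generator, several settings."""

    name: str
    generator: GeneratorSpec
    settings: tuple[StudyConfig, ...]


def study_presets(B: int = 25, seed: int = 0) -> tuple[StudyPreset, ...]:
    """Miniature versions of the variable-selection, normalization and PCA
    studies, scaled for a desktop (small B, one synthetic dataset each;
    K in {3, 5, 10} throughout).

    * variable selection: t-test with psel in {5, 10, 20, p/2}; LDA after
      small selections, DLDA when half the variables are kept;
    * normalization: quantile normalization before NSC (shrinkage tuned on
      the grid {0.05, 0.1, 0.25, 0.5, 1, 1.5}) and PLS-LDA (components
      tuned on 1..10);
    * PCA: n_comp in {2, 5, 10, 15} components before LDA.
    """
    gen = GeneratorSpec(seed=seed)
    p = gen.p

    varsel = []
    for psel in (5, 10, 20, p // 2):
        clf = "dlda" if psel > 20 else "lda"
        varsel.append(
            StudyConfig(
                steps=(TTestSelection(psel=psel),),
                classifier=ClassifierSpec(name=clf),
                B=B,
                seed=seed,
                name=f"varsel_psel{psel}",
            )
        )

    norm = []
    for clf_spec in (
        ClassifierSpec(
            name="nsc", tune_param="delta",
            tune_grid=(0.05, 0.1, 0.25, 0.5, 1.0, 1.5),
        ),
        ClassifierSpec(name="pls_lda", tune_param="n_comp",
                       tune_grid=tuple(range(1, 11))),
    ):
        norm.append(
            StudyConfig(
                steps=(QuantileNormalization(),),
                classifier=clf_spec,
                B=B,
                seed=seed,
                name=f"norm_{clf_spec.name}",
            )
        )

    pca = [
        StudyConfig(
            steps=(PCAStep(n_comp=n_comp),),
            classifier=ClassifierSpec(name="lda"),
            B=B,
            seed=seed,
            name=f"pca_ncomp{n_comp}",
        )
        for n_comp in (2, 5, 10, 15)
    ]

    filtering = [
        StudyConfig(
            steps=(VarianceFilter(m=p // 4),),
            classifier=ClassifierSpec(name="dlda"),
            B=B,
            seed=seed,
            name="variance_filter",
        )
    ]

    return (
        StudyPreset("variable_selection", replace(gen, dataset_id="varsel_synth"),
                    tuple(varsel)),
        StudyPreset(
            "normalization",
            replace(gen, multiplicative_noise=True, dataset_id="norm_synth"),
            tuple(norm),
        ),
        StudyPreset("pca", replace(gen, dataset_id="pca_synth"), tuple(pca)),
        StudyPreset("variance_filter", replace(gen, dataset_id="filter_synth"),
                    tuple(filtering)),
    )
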