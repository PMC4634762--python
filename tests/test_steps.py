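"""Preparation steps: fitted-state oracles and the addon-consistency contract."""
import numpy as np
import pytest

from cviim import (
    ClassifierSpec,
    GeneratorSpec,
    GlobalVSN,
    MeanImputation,
    PCAStep,
    QuantileNormalization,
    TTestSelection,
    TuningStep,
    VarianceFilter,
    generate,
)
from cviim.exceptions import FitFailureError, PipelineCompositionError
from cviim.steps import step_from_dict


def fitted_steps_on(X, y, seed=0):
    """Fit one instance of every step kind on (X, y)."""
    n, p = X.shape
    return {
        "quantile_norm": QuantileNormalization().fit(X),
        "global_vsn": GlobalVSN().fit(X),
        "pca": PCAStep(n_comp=min(3, n - 1, p)).fit(X),
        "ttest_select": TTestSelection(psel=min(4, p)).fit(X, y, seed=seed),
        "variance_filter": VarianceFilter(m=min(4, p)).fit(X),
        "mean_impute": MeanImputation().fit(X),
        "tune": TuningStep(
            ClassifierSpec(name="nsc", tune_param="delta", tune_grid=(0.1, 1.0))
        ).fit(X, y, seed=seed),
    }


class TestQuantileNormalization:
    def test_reference_is_mean_of_sorted_rows(self):
        X = np.array([[1.0, 2.0, 3.0], [3.0, 5.0, 7.0]])
        fitted = QuantileNormalization().fit(X)
        assert np.allclose(fitted.reference, [2.0, 3.5, 5.0])
        assert np.allclose(fitted.transform(X), [[2, 3.5, 5], [2, 3.5, 5]])

    def test_addon_rank_mapping(self):
        fitted = QuantileNormalization().fit(np.array([[1.0, 2, 3], [3.0, 5, 7]]))
        assert np.allclose(fitted.transform([[0.0, 10.0, 5.0]]), [[2.0, 5.0, 3.5]])

    def test_reference_row_is_fixed_point(self):
        fitted = QuantileNormalization().fit(np.array([[1.0, 2, 3], [3.0, 5, 7]]))
        assert np.allclose(fitted.transform([[2.0, 3.5, 5.0]]), [[2.0, 3.5, 5.0]])

    def test_tied_values_get_mean_of_tied_reference(self):
        fitted = QuantileNormalization().fit(np.array([[1.0, 2, 3], [3.0, 5, 7]]))
        assert np.allclose(fitted.transform([[4.0, 4.0, 4.0]]), [[3.5, 3.5, 3.5]])

    def test_identical_observations_identity_up_to_shared_vector(self):
        row = np.array([5.0, 1.0, 3.0])
        X = np.tile(row, (4, 1))
        fitted = QuantileNormalization().fit(X)
        assert np.allclose(fitted.transform(X), X)

    def test_p_equals_one_maps_to_training_mean(self):
        fitted = QuantileNormalization().fit(np.array([[2.0], [4.0]]))
        assert np.allclose(fitted.transform([[100.0]]), [[3.0]])

    def test_normalized_training_rows_sorted_equal_reference(self, rng):
        X = rng.normal(size=(12, 20))
        fitted = QuantileNormalization().fit(X)
        out = fitted.transform(X)
        assert np.allclose(np.sort(out, axis=1), fitted.reference)

    def test_nonfinite_rejected_and_width_mismatch(self, rng):
        with pytest.raises(ValueError):
            QuantileNormalization().fit(np.array([[1.0, np.nan]]))
        fitted = QuantileNormalization().fit(rng.normal(size=(3, 4)))
        with pytest.raises(PipelineCompositionError):
            fitted.transform(np.zeros((2, 5)))


class TestGlobalVSN:
    def test_identity_parameters_and_monotonicity(self):
        from cviim.steps import FittedGlobalVSN

        fitted = FittedGlobalVSN(offset=0.0, scale=1.0, p=1)
        x = np.linspace(-3, 3, 25)[:, None]
        out = fitted.transform(x).ravel()
        assert out[12] == pytest.approx(0.0)
        assert np.all(np.diff(out) > 0)

    def test_addon_on_training_matches_fit_time(self, rng):
        X = np.exp(rng.normal(size=(10, 30)))
        fitted = GlobalVSN().fit(X)
        assert np.allclose(fitted.transform(X), np.arcsinh((X - fitted.offset) / fitted.scale))

    def test_variance_stabilization_under_multiplicative_noise(self):
        data = generate(
            GeneratorSpec(n_per_class=30, p=200, n_informative=0, effect_size=0.0,
                          multiplicative_noise=True, seed=3)
        )
        X = data.X
        out = GlobalVSN().fit(X).transform(X)
        before = np.std(X, axis=0)
        after = np.std(out, axis=0)
        # relative spread of the per-variable SDs shrinks after the glog
        assert np.std(after) / np.mean(after) < 0.5 * np.std(before) / np.mean(before)

    def test_degenerate_scale_raises(self):
        with pytest.raises(FitFailureError):
            GlobalVSN().fit(np.ones((5, 4)))


class TestPCA:
    def test_two_point_toy(self):
        fitted = PCAStep(n_comp=1).fit(np.array([[-1.0, 0.0], [1.0, 0.0]]))
        assert np.allclose(fitted.means, [0.0, 0.0])
        assert np.allclose(fitted.loadings[:, 0], [1.0, 0.0])  # sign convention
        assert np.allclose(fitted.transform([[3.0, 4.0]]), [[3.0]])

    def test_orthonormal_loadings_and_centered_scores(self, rng):
        X = rng.normal(size=(15, 8))
        fitted = PCAStep(n_comp=4).fit(X)
        gram = fitted.loadings.T @ fitted.loadings
        assert np.allclose(gram, np.eye(4), atol=1e-10)
        assert np.allclose(fitted.transform(X).mean(axis=0), 0.0, atol=1e-10)

    def test_training_mean_maps_to_origin(self, rng):
        X = rng.normal(size=(10, 6))
        fitted = PCAStep(n_comp=2).fit(X)
        assert np.allclose(fitted.transform(X.mean(axis=0)[None, :]), 0.0, atol=1e-10)

    def test_matches_sklearn_up_to_convention(self, rng):
        from sklearn.decomposition import PCA

        X = rng.normal(size=(20, 7))
        ours = PCAStep(n_comp=3).fit(X).transform(X)
        theirs = PCA(n_components=3).fit_transform(X)
        assert np.allclose(np.abs(ours), np.abs(theirs), atol=1e-8)

    def test_n_comp_out_of_range(self, rng):
        with pytest.raises(ValueError):
            PCAStep(n_comp=0)
        with pytest.raises(ValueError):
            PCAStep(n_comp=5).fit(rng.normal(size=(4, 10)))


class TestTTestSelection:
    def test_informative_variable_wins(self, rng):
        y = np.repeat([0, 1], 15)
        X = rng.normal(size=(30, 12))
        X[:, 0] = y + 0.01 * rng.normal(size=30)
        fitted = TTestSelection(psel=1).fit(X, y)
        assert fitted.indices.tolist() == [0]

    def test_psel_equals_p_selects_everything(self, rng):
        y = np.repeat([0, 1], 5)
        X = rng.normal(size=(10, 6))
        fitted = TTestSelection(psel=6).fit(X, y)
        assert sorted(fitted.indices.tolist()) == list(range(6))

    def test_tie_breaks_to_lower_index(self, rng):
        y = np.repeat([0, 1], 10)
        base = rng.normal(size=20) + 2.0 * y
        X = np.column_stack([rng.normal(size=20), base, base])
        fitted = TTestSelection(psel=1).fit(X, y)
        assert fitted.indices.tolist() == [1]

    def test_zero_variance_column_uninformative(self, rng):
        y = np.repeat([0, 1], 8)
        X = np.column_stack([np.ones(16), y + 0.1 * rng.normal(size=16)])
        fitted = TTestSelection(psel=1).fit(X, y)
        assert fitted.indices.tolist() == [1]

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            TTestSelection(psel=1).fit(rng.normal(size=(6, 3)), np.zeros(6, int))

    def test_matches_pvalue_ranking_oracle(self, rng):
        import scipy.stats

        y = np.repeat([0, 1], 12)
        X = rng.normal(size=(24, 40))
        X[y == 1, :5] += 1.0
        fitted = TTestSelection(psel=7).fit(X, y)
        p = scipy.stats.ttest_ind(X[y == 0], X[y == 1], axis=0).pvalue
        oracle = np.sort(np.argsort(p, kind="stable")[:7])
        assert fitted.indices.tolist() == oracle.tolist()


class TestVarianceFilter:
    def test_ranks_by_training_variance(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([
            rng.normal(scale=1.0, size=50),
            rng.normal(scale=2.0, size=50),
            rng.normal(scale=0.5, size=50),
        ])
        fitted = VarianceFilter(m=2).fit(X)
        assert fitted.indices.tolist() == [0, 1]

    def test_constant_column_never_beats_varying(self, rng):
        X = np.column_stack([np.full(20, 3.0), rng.normal(size=20)])
        assert VarianceFilter(m=1).fit(X).indices.tolist() == [1]

    def test_m_equals_p_is_identity_selection(self, rng):
        X = rng.normal(size=(8, 5))
        fitted = VarianceFilter(m=5).fit(X)
        assert np.allclose(fitted.transform(X), X)


class TestMeanImputation:
    def test_no_missing_is_identity(self, rng):
        X = rng.normal(size=(6, 4))
        assert np.allclose(MeanImputation().fit(X).transform(X), X)

    def test_training_column_mean_fills_gaps(self):
        X = np.array([[1.0, 0.0], [np.nan, 1.0], [3.0, 2.0]])
        fitted = MeanImputation().fit(X)
        assert fitted.means[0] == pytest.approx(2.0)
        out = fitted.transform(np.array([[np.nan, 5.0]]))
        assert np.allclose(out, [[2.0, 5.0]])

    def test_all_missing_variable_rejected(self):
        with pytest.raises(FitFailureError):
            MeanImputation().fit(np.array([[np.nan, 1.0], [np.nan, 2.0]]))


class TestTuning:
    def test_singleton_grid(self, separable):
        step = TuningStep(
            ClassifierSpec(name="nsc", tune_param="delta", tune_grid=(0.25,))
        )
        fitted = step.fit(separable.X, separable.y, seed=5)
        assert fitted.param_override == {"delta": 0.25}

    def test_separating_parameter_beats_degenerate(self, separable):
        # delta=1000 collapses NSC to the priors; delta=0.1 separates
        step = TuningStep(
            ClassifierSpec(name="nsc", tune_param="delta", tune_grid=(1000.0, 0.1))
        )
        fitted = step.fit(separable.X, separable.y, seed=5)
        assert fitted.param_override == {"delta": 0.1}

    def test_deterministic_given_seed(self, small_null):
        step = TuningStep(
            ClassifierSpec(name="nsc", tune_param="delta",
                           tune_grid=(0.05, 0.5, 1.5))
        )
        a = step.fit(small_null.X, small_null.y, seed=9).param_override
        b = step.fit(small_null.X, small_null.y, seed=9).param_override
        assert a == b

    def test_identity_transform(self, small_null):
        step = TuningStep(
            ClassifierSpec(name="nsc", tune_param="delta", tune_grid=(0.5,))
        )
        fitted = step.fit(small_null.X, small_null.y, seed=1)
        assert np.allclose(fitted.transform(small_null.X), small_null.X)


class TestAddonContract:
    """The operational form of the addon definition, for every step."""

    def test_single_row_equals_batch(self, rng):
        y = np.repeat([0, 1], 8)
        X = np.abs(rng.normal(size=(16, 10))) + 0.5
        X_test = np.abs(rng.normal(size=(5, 10))) + 0.5
        for kind, fitted in fitted_steps_on(X, y).items():
            batch = fitted.transform(X_test)
            rows = np.vstack([fitted.transform(X_test[i:i + 1]) for i in range(5)])
            assert np.allclose(batch, rows, atol=1e-12), kind

    def test_transform_is_deterministic_on_training(self, rng):
        y = np.repeat([0, 1], 8)
        X = np.abs(rng.normal(size=(16, 10))) + 0.5
        for kind, fitted in fitted_steps_on(X, y).items():
            assert np.allclose(fitted.transform(X), fitted.transform(X)), kind

    def test_unsupervised_fit_signature_has_no_label_slot(self):
        import inspect

        for step_cls in (QuantileNormalization, GlobalVSN, MeanImputation):
            params = inspect.signature(step_cls().fit).parameters
            assert list(params) == ["X"]
        assert list(inspect.signature(PCAStep(1).fit).parameters) == ["X"]
        assert list(inspect.signature(VarianceFilter(1).fit).parameters) == ["X"]

    def test_states_are_json_serializable(self, rng):
        import json

        y = np.repeat([0, 1], 8)
        X = np.abs(rng.normal(size=(16, 10))) + 0.5
        for kind, fitted in fitted_steps_on(X, y).items():
            json.dumps(fitted.state())


def test_step_registry_round_trip():
    step = step_from_dict({"kind": "pca", "n_comp": 3})
    assert isinstance(step, PCAStep) and step.n_comp == 3
    with pytest.raises(ValueError):
        step_from_dict({"kind": "nope"})
    tune = step_from_dict(
        {"kind": "tune"},
        classifier=ClassifierSpec(name="nsc", tune_param="delta", tune_grid=(0.5,)),
    )
    assert isinstance(tune, TuningStep)
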