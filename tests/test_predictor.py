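"""Predictive stack: training, prediction, metrics, persistence, transfer."""

import math

import numpy as np
import pytest

from dropforge import physics
from dropforge.dataset import bound_filter, split_train_test
from dropforge.physics import DesignPoint, FEATURE_NAMES
from dropforge.predictor import (
    ExtrapolationWarning,
    HyperSearchSpec,
    TrainingConfig,
    ValidityError,
    _metrics,
    data_reduction_experiment,
    evaluate,
    fine_tune,
    hyper_search,
    load_stack,
    predict,
    save_stack,
    train_stack,
    transfer_experiment,
)
from dropforge.synthetic import (
    SurrogateParams,
    generate_dataset,
    generate_shifted_dataset,
)

FAST = TrainingConfig(epochs=600, patience=100, seed=0)


class TestTrainStack:
    def test_classifier_accuracy_on_separable_regimes(self, trained_stack):
        # surrogate regime labels are noise-free, so held-out accuracy is high
        assert trained_stack.classifier_accuracy >= 0.95

    def test_training_deterministic_given_seed(self, records600,
                                               surrogate_params):
        a = train_stack(records600[:300], FAST, fluids=surrogate_params.fluids)
        b = train_stack(records600[:300], FAST, fluids=surrogate_params.fluids)
        assert a.classifier_accuracy == b.classifier_accuracy
        assert a.tolerances == b.tolerances

    def test_tolerances_are_positive_heldout_maes(self, trained_stack):
        for (regime, target), tol in trained_stack.tolerances.items():
            assert tol > 0

    def test_fluids_required(self, records600):
        with pytest.raises(ValueError, match="fluids"):
            train_stack(records600, FAST, fluids=None)

    def test_sparse_regime_refused(self, records600, surrogate_params):
        dripping_only = [r for r in records600 if r.outcome.regime == "dripping"]
        sparse = dripping_only + [
            r for r in records600 if r.outcome.regime == "jetting"][:10]
        with pytest.raises(ValueError, match="transfer"):
            train_stack(sparse, FAST, fluids=surrogate_params.fluids)


class TestPredict:
    def test_inferred_diameter_conserves_mass(self, trained_stack,
                                              nominal_design):
        perf = predict(trained_stack, nominal_design)
        q_d = physics.flow_rates_from_dimensionless(
            nominal_design.flow, nominal_design.geometry,
            trained_stack.fluids).dispersed_rate
        flux = (math.pi / 6.0) * (perf.inferred_diameter_um * 1e-6) ** 3 \
            * perf.rate_hz
        assert abs(flux - q_d) / q_d <= 1e-9

    def test_out_of_bounds_names_parameter(self, trained_stack):
        bad = DesignPoint.from_vector([150, 2, 2.5, 3, 3, 2, 0.9, 10])
        with pytest.raises(ValidityError, match="capillary_number"):
            predict(trained_stack, bad)

    def test_unseen_surrogate_points_diameter_mape(self, trained_stack):
        # oracle: noise-free surrogate truth on in-window unseen points
        import warnings
        unseen = bound_filter(
            generate_dataset(200, SurrogateParams(noise_sd=0.0), seed=99))
        errors = []
        for r in unseen:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    perf = predict(trained_stack, r.design)
            except ValidityError:
                continue
            errors.append(abs(perf.diameter_um - r.outcome.diameter_um)
                          / r.outcome.diameter_um)
        assert np.mean(errors) <= 0.10

    def test_extrapolation_warning_flags_wild_outputs(self, trained_stack,
                                                      nominal_design):
        import copy
        shrunk = copy.deepcopy(trained_stack)
        shrunk.outcome_ranges = {"diameter": (1000.0, 1001.0),
                                 "rate": (1e5, 1e5 + 1)}
        with pytest.warns(ExtrapolationWarning):
            predict(shrunk, nominal_design)


class TestEvaluate:
    def test_hand_computed_five_point_table(self):
        # spreadsheet-style oracle on a printed toy table
        y_true = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        y_pred = np.array([12.0, 18.0, 33.0, 40.0, 45.0])
        m = _metrics(y_true, y_pred)
        errors = y_pred - y_true
        assert m.mae == pytest.approx(np.mean(np.abs(errors)), abs=1e-12)
        assert m.rmse == pytest.approx(
            math.sqrt(np.mean(errors**2)), abs=1e-12)
        assert m.mape == pytest.approx(
            np.mean(np.abs(errors / y_true)) * 100, abs=1e-12)
        sst = np.sum((y_true - y_true.mean()) ** 2)
        assert m.r2 == pytest.approx(1 - np.sum(errors**2) / sst, abs=1e-12)
        assert m.rmse >= m.mae >= 0

    def test_perfect_predictions(self):
        y = np.array([10.0, 20.0, 30.0])
        m = _metrics(y, y.copy())
        assert m.mae == m.rmse == m.mape == 0.0
        assert m.r2 == 1.0

    def test_constant_predictor_r2_zero(self):
        y = np.array([10.0, 20.0, 30.0])
        m = _metrics(y, np.full(3, y.mean()))
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_metrics_match_brute_force_on_test_run(self, trained_stack,
                                                   records600):
        _, test = split_train_test(records600, 0.2, seed=0)
        report = evaluate(trained_stack, test)
        # brute-force recomputation for one regime/target
        regime, target = "jetting", "diameter"
        recs = [r for r in test if r.outcome.regime == regime]
        z = trained_stack.norm_stats.transform(
            np.array([r.design.to_vector() for r in recs]))
        net = trained_stack.regressors[(regime, target)]
        scale = trained_stack.target_scales[(regime, target)]
        y_pred = scale.inverse(net.predict(z)[:, 0])
        y_true = np.array([r.outcome.diameter_um for r in recs])
        assert report.per_model[(regime, target)].mae == pytest.approx(
            np.mean(np.abs(y_true - y_pred)), rel=1e-12)

    def test_empty_test_set_rejected(self, trained_stack):
        with pytest.raises(ValueError):
            evaluate(trained_stack, [])


class TestPersistence:
    def test_roundtrip_identical_predictions(self, trained_stack, tmp_path):
        save_stack(trained_stack, tmp_path / "stack")
        loaded = load_stack(tmp_path / "stack")
        rng = np.random.default_rng(0)
        lo, hi = (trained_stack.feature_bounds[:, 0],
                  trained_stack.feature_bounds[:, 1])
        for _ in range(50):
            vec = lo + rng.random(8) * (hi - lo)
            point = DesignPoint.from_vector(vec)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                a = predict(trained_stack, point)
                b = predict(loaded, point)
            assert a.regime == b.regime
            assert a.diameter_um == b.diameter_um
            assert a.rate_hz == b.rate_hz

    def test_tampered_weights_detected(self, trained_stack, tmp_path):
        save_stack(trained_stack, tmp_path / "stack")
        weights = (tmp_path / "stack" / "weights.npz")
        data = bytearray(weights.read_bytes())
        data[-1] ^= 0xFF
        weights.write_bytes(bytes(data))
        with pytest.raises(ValueError, match="integrity"):
            load_stack(tmp_path / "stack")

    def test_version_mismatch_refused(self, trained_stack, tmp_path):
        import json
        save_stack(trained_stack, tmp_path / "stack")
        manifest_path = tmp_path / "stack" / "manifest.json"
        manifest = json.loads(manifest_path.read_text())
        manifest["format_version"] = "someone-elses-format-9"
        manifest_path.write_text(json.dumps(manifest))
        with pytest.raises(ValueError, match="format"):
            load_stack(tmp_path / "stack")

    def test_provenance_metadata_echoed(self, trained_stack, tmp_path):
        save_stack(trained_stack, tmp_path / "stack")
        loaded = load_stack(tmp_path / "stack")
        assert loaded.provenance["seed"] == trained_stack.provenance["seed"]
        assert loaded.provenance["data_fingerprint"] == \
            trained_stack.provenance["data_fingerprint"]


@pytest.fixture(scope="module")
def small_shifted(surrogate_params):
    """36-point property-shifted set; its bounded subset is jetting-only."""
    return generate_shifted_dataset(36, surrogate_params,
                                    shift_factor=1.25, seed=100)


class TestFineTune:
    def test_frozen_weights_unchanged(self, trained_stack, small_shifted):
        tuned = fine_tune(trained_stack, small_shifted, frozen_layers=2,
                          config=FAST)
        for key in tuned.regressors:
            before = trained_stack.regressors[key]
            after = tuned.regressors[key]
            for i in range(2):
                assert np.array_equal(before.weights[i], after.weights[i])

    def test_zero_epochs_identical_predictions(self, trained_stack,
                                               small_shifted, nominal_design):
        frozen_cfg = TrainingConfig(epochs=0, seed=0)
        tuned = fine_tune(trained_stack, small_shifted, frozen_layers=2,
                          config=frozen_cfg)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = predict(trained_stack, nominal_design)
            b = predict(tuned, nominal_design)
        assert (a.diameter_um, a.rate_hz) == (b.diameter_um, b.rate_hz)

    def test_excessive_frozen_layers_rejected(self, trained_stack,
                                              small_shifted):
        with pytest.raises(ValueError):
            fine_tune(trained_stack, small_shifted, frozen_layers=9)

    def test_added_layers_deepen_networks(self, trained_stack, small_shifted):
        # light-mineral-oil style protocol: freeze one layer, append layers
        tuned = fine_tune(trained_stack, small_shifted, frozen_layers=1,
                          config=FAST, add_layers=(8,))
        base_depth = trained_stack.regressors[("jetting", "diameter")].n_layers
        assert tuned.regressors[("jetting", "diameter")].n_layers == \
            base_depth + 1

    def test_transfer_beats_scratch_on_shifted_data(self, trained_stack,
                                                    surrogate_params):
        light = TrainingConfig(epochs=1500, patience=100, seed=0)
        small = generate_shifted_dataset(36, surrogate_params,
                                         shift_factor=1.25, seed=100)
        result = transfer_experiment(trained_stack, small, frozen_layers=2,
                                     config=light, seed=0)
        assert result["fine_tuned_wins"]


class TestDataReduction:
    def test_single_repetition_deterministic(self, records600):
        kwargs = dict(sizes=(50,), repetitions=1, seed=3, config=FAST,
                      regimes=("jetting",), targets=("diameter",))
        a = data_reduction_experiment(records600, **kwargs)
        b = data_reduction_experiment(records600, **kwargs)
        assert a == b

    def test_oversized_subsample_skipped_with_warning(self, records600):
        with pytest.warns(UserWarning, match="exceeds"):
            curves = data_reduction_experiment(
                records600, sizes=(5000,), repetitions=1, seed=0, config=FAST,
                regimes=("dripping",), targets=("diameter",))
        assert curves == {}


class TestHyperSearch:
    def test_sabotaged_candidate_loses(self, records600):
        spec = HyperSearchSpec(hidden_grid=((16, 16, 8),),
                               epochs_grid=(0, 400),
                               validation="holdout", seed=0)
        best, board = hyper_search(records600[:200], spec)
        assert best.epochs == 400

    def test_selected_config_is_argmin(self, records600):
        spec = HyperSearchSpec(hidden_grid=((8, 8, 8), (32, 16, 8)),
                               epochs_grid=(300,), n_folds=2, seed=0)
        best, board = hyper_search(records600[:200], spec)
        assert board[0]["score"] == min(c["score"] for c in board)
        assert best.regressor_hidden == board[0]["hidden"]
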