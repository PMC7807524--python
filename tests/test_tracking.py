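import numpy as np
import pytest

from livertrack.lstm import NetworkConfig, TrainConfig
from livertrack.signals import MotionTrace, PairedTraces
from livertrack.svr import SVRConfig
from livertrack.synthetic import (BreathingParams, CorrelationParams,
                                  simulate_session)
from livertrack.tracking import (Correlator, ExternalPredictor,
                                 IntegratedTracker, LatencySpec,
                                 chronological_split, evaluate_integrated,
                                 latency_to_steps, make_correlation_dataset,
                                 make_prediction_dataset, persistence_rmse,
                                 train_correlator, train_external_predictor)

FAST_SVR = SVRConfig()
# noise-free recovery checks: tube half-width below the precision being asserted
PRECISE_SVR = SVRConfig(epsilon=0.01)


def index_trace(n):
    vals = np.arange(n, dtype=float)
    return MotionTrace(np.column_stack([vals, vals + 100, vals + 200]), 20.0)


class TestLatencySteps:
    @pytest.mark.parametrize("ms, expected", [
        (50, 1), (150, 3), (200, 4), (450, 9), (0, 0)])
    def test_20hz_mapping(self, ms, expected):
        assert latency_to_steps(ms, 20.0) == expected
        assert LatencySpec(ms, 20.0).steps == expected

    def test_ties_round_up(self):
        assert latency_to_steps(25, 20.0) == 1  # 0.5 steps -> 1

    def test_negative_latency_rejected(self):
        with pytest.raises(ValueError):
            latency_to_steps(-1, 20.0)


class TestPredictionDataset:
    def test_index_arithmetic(self):
        ds = make_prediction_dataset(index_trace(10), window=3, steps=2)
        aw = ds["x"]
        assert len(aw) == 6
        np.testing.assert_array_equal(aw.X[0], [0, 1, 2])
        assert aw.y[0] == 4
        np.testing.assert_array_equal(aw.X[-1], [5, 6, 7])
        assert aw.y[-1] == 9

    def test_zero_latency_targets_window_end(self):
        ds = make_prediction_dataset(index_trace(10), window=3, steps=0)
        aw = ds["x"]
        assert len(aw) == 8  # N - W + 1
        assert aw.y[0] == 2.0  # target == last window element

    def test_boundary_single_pair(self):
        ds = make_prediction_dataset(index_trace(12), window=9, steps=3)
        assert ds.n_pairs() == 1

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            make_prediction_dataset(index_trace(10), window=9, steps=3)

    def test_targets_reconstruct_source_exactly(self, short_session):
        trace = short_session.external
        ds = make_prediction_dataset(trace, window=20, steps=9)
        for ax in ("x", "y", "z"):
            aw = ds[ax]
            np.testing.assert_array_equal(
                aw.y, trace.axis(ax)[aw.target_indices])
            k = 17
            np.testing.assert_array_equal(
                aw.X[k], trace.axis(ax)[k:k + 20])


class TestCorrelationDataset:
    def test_pair_count(self):
        paired = PairedTraces(index_trace(100), index_trace(100))
        ds = make_correlation_dataset(paired, window=20)
        assert ds.n_pairs() == 81

    def test_target_is_internal_at_window_end(self):
        internal = index_trace(50)
        shifted = MotionTrace(internal.values * 2 + 1, 20.0)
        ds = make_correlation_dataset(PairedTraces(internal, shifted), 5)
        aw = ds["x"]
        np.testing.assert_array_equal(aw.y, shifted.axis("x")[4:])

    def test_axes_are_independent(self, short_session):
        ds_full = make_correlation_dataset(short_session, 10)
        # corrupt y and z of both traces; the x dataset must be unchanged
        ext = short_session.external.values.copy()
        ext[:, 1:] = -999.0
        intr = short_session.internal.values.copy()
        intr[:, 1:] = 999.0
        mangled = PairedTraces(MotionTrace(ext, 20.0),
                               MotionTrace(intr, 20.0))
        ds_m = make_correlation_dataset(mangled, 10)
        np.testing.assert_array_equal(ds_m["x"].X, ds_full["x"].X)
        np.testing.assert_array_equal(ds_m["x"].y, ds_full["x"].y)

    def test_misaligned_pair_rejected(self):
        with pytest.raises(ValueError):
            PairedTraces(index_trace(100), index_trace(99))


class TestSplit:
    def test_nine_to_one(self):
        ds = make_prediction_dataset(index_trace(104), window=3, steps=2)
        assert ds.n_pairs() == 100
        train, test = chronological_split(ds, 0.9)
        assert train.n_pairs() == 90 and test.n_pairs() == 10

    def test_half_split(self):
        ds = make_prediction_dataset(index_trace(14), window=3, steps=2)
        train, test = chronological_split(ds, 0.5)
        assert train.n_pairs() == 5 and test.n_pairs() == 5

    def test_ordering_preserved(self):
        ds = make_prediction_dataset(index_trace(50), window=5, steps=1)
        train, test = chronological_split(ds, 0.8)
        assert train["x"].target_indices.max() < test["x"].target_indices.min()

    def test_invalid_fraction_rejected(self):
        ds = make_prediction_dataset(index_trace(50), window=5, steps=1)
        with pytest.raises(ValueError):
            chronological_split(ds, 0.0)


class TestTrainedModels:
    def test_standardization_uses_training_region_only(self, short_session):
        trace = short_session.external
        pred = train_external_predictor(trace, "svr", LatencySpec(50),
                                        svr_config=FAST_SVR, seed=0)
        i, W = 1, 20
        ds = make_prediction_dataset(trace, W, i)
        m_train = int(0.9 * ds.n_pairs())
        region = trace.axis("y")[: W + i + m_train - 1]
        assert pred.axis_models["y"].x_mean == pytest.approx(region.mean())
        assert pred.axis_models["y"].x_std == pytest.approx(region.std())

    def test_noise_free_zero_latency_prediction_is_trivial(self):
        params = BreathingParams(duration_s=60.0, noise_sd_mm=0.0,
                                 baseline_drift_mm_per_min=0.0)
        trace = simulate_session(params, seed=1).external
        pred = train_external_predictor(trace, "svr", LatencySpec(0),
                                        svr_config=PRECISE_SVR, seed=0)
        for ax in ("x", "y", "z"):
            assert pred.report.per_axis[ax]["rmse"] < 0.05

    def test_affine_correlator_recovery_svr(self, affine_session):
        corr = train_correlator(affine_session, "svr",
                                svr_config=PRECISE_SVR, seed=0)
        for ax in ("x", "y", "z"):
            assert corr.report.per_axis[ax]["rmse"] < 0.05

    def test_gain_drift_degrades_static_correlator(self):
        params = BreathingParams(duration_s=120.0)
        cp = CorrelationParams(gain_drift_per_min=0.5)
        paired = simulate_session(params, cp, seed=4)
        corr = train_correlator(paired, "svr", svr_config=FAST_SVR, seed=0)
        ds = make_correlation_dataset(paired, 20)
        m = ds.n_pairs()
        early = slice(0, m // 10)
        am = corr.axis_models["y"]
        aw = ds["y"]
        rmse_early = float(np.sqrt(np.mean(
            (am.predict(aw.X[early]) - aw.y[early]) ** 2)))
        rmse_late = corr.report.per_axis["y"]["rmse"]
        assert rmse_late > rmse_early

    def test_unknown_model_kind_rejected(self, short_session):
        with pytest.raises(ValueError):
            train_correlator(short_session, "forest")

    def test_lstm_training_is_seed_reproducible(self, short_session):
        kw = dict(window=10,
                  net_config=NetworkConfig(num_layers=1, hidden_size=4,
                                           window=10, dropout=0.0),
                  train_config=TrainConfig(epochs=2, seed=0), seed=5,
                  axes=("y",))
        a = train_correlator(short_session, "lstm", **kw)
        b = train_correlator(short_session, "lstm", **kw)
        assert a.report.per_axis["y"] == b.report.per_axis["y"]


class TestIntegrated:
    def test_zero_latency_reduces_to_correlator(self, affine_session):
        pred = train_external_predictor(affine_session.external, "svr",
                                        LatencySpec(0), svr_config=FAST_SVR,
                                        seed=0)
        corr = train_correlator(affine_session, "svr", svr_config=FAST_SVR,
                                seed=0)
        tracker = IntegratedTracker(predictor=pred, correlator=corr)
        targets, preds = tracker.track(affine_session.external,
                                       start_index=2000)
        from livertrack.tracking import make_correlation_dataset
        ds = make_correlation_dataset(affine_session, 20)
        aw = ds["y"]
        sel = np.isin(aw.target_indices, targets)
        direct = corr.axis_models["y"].predict(aw.X[sel])
        np.testing.assert_allclose(preds[:, 1], direct, atol=1e-12)

    def test_perfect_predictor_collapses_to_correlator_error(
            self, affine_session):
        corr = train_correlator(affine_session, "svr", svr_config=FAST_SVR,
                                seed=0)

        class OracleAxisModel:
            """Returns the true future external values by anchor position."""

            def __init__(self, series, W, i):
                self.series, self.W, self.i = series, W, i

            def predict(self, X):
                X = np.atleast_2d(X)
                m = len(X)
                return self.series[self.W - 1 + self.i:
                                   self.W - 1 + self.i + m]

        W, i = 20, 5
        oracle = ExternalPredictor(
            axis_models={ax: OracleAxisModel(
                affine_session.external.axis(ax), W, i)
                for ax in ("x", "y", "z")},
            window=W, latency=LatencySpec(250), kind="oracle")
        tracker = IntegratedTracker(predictor=oracle, correlator=corr)
        targets, preds = tracker.track(affine_session.external,
                                       start_index=2000)
        ds = make_correlation_dataset(affine_session, W)
        aw = ds["y"]
        sel = np.isin(aw.target_indices, targets)
        direct = corr.axis_models["y"].predict(aw.X[sel])
        np.testing.assert_allclose(preds[:, 1], direct, atol=1e-9)

    def test_insufficient_history_rejected(self, affine_session):
        pred = train_external_predictor(affine_session.external, "svr",
                                        LatencySpec(450),
                                        svr_config=FAST_SVR, seed=0)
        corr = train_correlator(affine_session, "svr", svr_config=FAST_SVR,
                                seed=0)
        tracker = IntegratedTracker(predictor=pred, correlator=corr)
        with pytest.raises(ValueError):
            tracker.predict(np.zeros((10, 3)))

    def test_single_step_predict_matches_track(self, affine_session):
        pred = train_external_predictor(affine_session.external, "svr",
                                        LatencySpec(150),
                                        svr_config=FAST_SVR, seed=0)
        corr = train_correlator(affine_session, "svr", svr_config=FAST_SVR,
                                seed=0)
        tracker = IntegratedTracker(predictor=pred, correlator=corr)
        targets, preds = tracker.track(affine_session.external,
                                       start_index=2300)
        j = targets[5]
        i = tracker.steps
        history = affine_session.external.values[: j - i + 1]
        single = tracker.predict(history)
        np.testing.assert_allclose(single, preds[5], atol=1e-9)


def test_persistence_baseline_shape(short_session):
    out = persistence_rmse(short_session.external, 20, 9)
    assert set(out) == {"x", "y", "z"} and all(v > 0 for v in out.values())
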