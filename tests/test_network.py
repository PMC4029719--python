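import copy

import numpy as np
import pytest

from emgexo import (
    ActivationParams,
    TrialConfig,
    WindowSpec,
    forward,
    generate_trial,
    make_dataset,
    split_data,
    train,
)
from emgexo.errors import CannotSplitError, InvalidConfigurationError, InvalidInputError
from emgexo.network import (
    BpnModel,
    LabeledDataset,
    TrainSpec,
    init_model,
    loss_and_gradients,
    model_from_dict,
    model_to_dict,
)


def random_dataset(n_rows=200, n_trials=10, seed=0):
    rng = np.random.default_rng(seed)
    return LabeledDataset(
        features=rng.uniform(0, 100, (n_rows, 4)),
        targets_deg=rng.uniform(0, 90, n_rows),
        trial_ids=rng.integers(0, n_trials, n_rows),
    )


class TestLabeledDataset:
    def test_row_count_mismatch(self):
        with pytest.raises(InvalidInputError):
            LabeledDataset(
                features=np.zeros((5, 4)),
                targets_deg=np.zeros(4),
                trial_ids=np.zeros(5, int),
            )

    def test_angle_bounds(self):
        with pytest.raises(InvalidInputError):
            LabeledDataset(
                features=np.zeros((2, 4)),
                targets_deg=np.array([0.0, 150.0]),
                trial_ids=np.zeros(2, int),
            )


class TestMakeDataset:
    def test_row_count_delegates_to_window_formula(self, small_session, window_1024):
        ds = make_dataset(small_session[:2], window_1024)
        per_trial = window_1024.n_windows(small_session[0].n_samples)
        assert ds.n_rows == 2 * per_trial

    def test_zero_emg_features_are_zero(self, window_1024):
        rec = generate_trial(TrialConfig(period_s=4.0, amplitude_scale_uV=0.0))
        ds = make_dataset([rec], window_1024)
        assert np.allclose(ds.features, 0.0)
        assert np.max(ds.targets_deg) > 45.0  # trajectory labels still there

    def test_order_independence(self, small_session, window_1024):
        a = make_dataset(small_session[:3], window_1024)
        b = make_dataset(small_session[:3][::-1], window_1024)
        assert sorted(map(tuple, a.features)) == sorted(map(tuple, b.features))

    def test_short_trial_skipped_with_warning(self, window_1024):
        from emgexo.synth import EmgRecording

        good = generate_trial(TrialConfig(period_s=2.0, seed=0))
        stub = EmgRecording(
            emg_uV=np.zeros((4, 50)), angle_deg=np.zeros(50), fs_hz=1024.0
        )
        with pytest.warns(UserWarning, match="skipped 1"):
            ds = make_dataset([good, stub], window_1024)
        assert set(np.unique(ds.trial_ids)) == {0}

    def test_empty_input(self, window_1024):
        with pytest.raises(InvalidInputError):
            make_dataset([], window_1024)

    def test_causal_label_alignment(self, window_1024):
        # label equals the angle at the window-end sample
        rec = generate_trial(TrialConfig(period_s=4.0, seed=1))
        ds = make_dataset([rec], window_1024)
        L, S = window_1024.length_samples, window_1024.step_samples
        assert ds.targets_deg[0] == rec.angle_deg[L - 1]
        assert ds.targets_deg[3] == rec.angle_deg[3 * S + L - 1]


class TestSplitData:
    def test_sixty_to_48_12(self):
        ds = random_dataset(n_rows=600, n_trials=60, seed=1)
        assert ds.trials.size == 60
        tr, te = split_data(ds, 0.8, seed=5)
        assert tr.trials.size == 48
        assert te.trials.size == 12

    def test_ten_half(self):
        ds = random_dataset(n_rows=100, n_trials=10, seed=2)
        tr, te = split_data(ds, 0.5, seed=0)
        assert tr.trials.size == 5 and te.trials.size == 5

    def test_determinism(self):
        ds = random_dataset()
        a = split_data(ds, 0.8, seed=3)
        b = split_data(ds, 0.8, seed=3)
        np.testing.assert_array_equal(a[0].trial_ids, b[0].trial_ids)

    def test_whole_trial_granularity(self):
        ds = random_dataset()
        tr, te = split_data(ds, 0.8, seed=4)
        assert set(tr.trials) & set(te.trials) == set()
        assert tr.n_rows + te.n_rows == ds.n_rows

    def test_too_few_trials(self):
        ds = LabeledDataset(
            features=np.zeros((5, 4)),
            targets_deg=np.zeros(5),
            trial_ids=np.zeros(5, int),
        )
        with pytest.raises(CannotSplitError):
            split_data(ds, 0.8)

    def test_bad_fraction(self):
        with pytest.raises(InvalidConfigurationError):
            split_data(random_dataset(), 1.5)


class TestForward:
    def test_zero_weights_give_midpoint(self):
        m = BpnModel(
            w_hidden=np.zeros((3, 4)), b_hidden=np.zeros(3), w_out=np.zeros(3), b_out=0.0
        )
        # sigma(0) = 0.5 -> midpoint of the angle range
        assert forward(m, np.zeros(4)) == pytest.approx(45.0)

    def test_output_inside_scaler_range(self):
        rng = np.random.default_rng(0)
        m = init_model(1)
        X = rng.uniform(-100, 100, (200, 4))
        pred = forward(m, X)
        lo, hi = m.angle_range_deg
        margin = (hi - lo) * 0.05 / 0.9
        assert np.all(pred > lo - margin - 1e-9) and np.all(pred < hi + margin + 1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidInputError):
            forward(init_model(0), np.array([1.0, np.nan, 0.0, 0.0]))

    def test_scaler_roundtrip(self):
        m = init_model(0)
        deg = np.linspace(0, 90, 11)
        np.testing.assert_allclose(m.unscale_angle(m.scale_angle(deg)), deg, atol=1e-12)


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        # central-difference oracle over >=100 random 4-3-1 instances
        rng = np.random.default_rng(42)
        eps = 1e-6
        checked = 0
        for trial in range(25):
            m = init_model(seed=trial)
            X = rng.uniform(-1, 1, (8, 4))
            t = rng.uniform(0.1, 0.9, 8)
            _, g = loss_and_gradients(m, X, t)
            for attr, idx in (
                ("w_hidden", (rng.integers(3), rng.integers(4))),
                ("b_hidden", (rng.integers(3),)),
                ("w_out", (rng.integers(3),)),
                ("b_out", None),
            ):
                m2 = copy.deepcopy(m)
                if attr == "b_out":
                    m2.b_out += eps
                    lp, _ = loss_and_gradients(m2, X, t)
                    m2.b_out -= 2 * eps
                    lm, _ = loss_and_gradients(m2, X, t)
                    analytic = float(g[attr])
                else:
                    arr = getattr(m2, attr)
                    arr[idx] += eps
                    lp, _ = loss_and_gradients(m2, X, t)
                    arr[idx] -= 2 * eps
                    lm, _ = loss_and_gradients(m2, X, t)
                    analytic = g[attr][idx]
                numeric = (lp - lm) / (2 * eps)
                assert analytic == pytest.approx(numeric, rel=1e-6, abs=1e-9)
                checked += 1
        assert checked >= 100


class TestTrain:
    def test_fits_affine_single_feature(self):
        # target affine in feature 0, the rest silent
        rng = np.random.default_rng(0)
        X = np.zeros((400, 4))
        X[:, 0] = rng.uniform(0, 1, 400)
        y = 90.0 * X[:, 0]
        ds = LabeledDataset(features=X, targets_deg=y, trial_ids=np.zeros(400, int))
        model, _ = train(ds, TrainSpec(seed=1))
        pred = forward(model, X)
        assert np.sqrt(np.mean((pred - y) ** 2)) < 2.0

    def test_zero_learning_rate_is_a_no_op(self):
        ds = random_dataset()
        spec = TrainSpec(learning_rate=0.0, max_epochs=5, tol=0.0, seed=2)
        model, losses = train(ds, spec)
        reference = init_model(2)
        np.testing.assert_array_equal(model.w_hidden, reference.w_hidden)
        assert np.allclose(losses, losses[0])

    def test_determinism(self):
        ds = random_dataset()
        a, _ = train(ds, TrainSpec(max_epochs=50, seed=7))
        b, _ = train(ds, TrainSpec(max_epochs=50, seed=7))
        np.testing.assert_array_equal(a.w_hidden, b.w_hidden)
        np.testing.assert_array_equal(a.w_out, b.w_out)

    def test_loss_decreases(self, trained_model):
        _, _, _, losses = trained_model
        assert losses[-1] <= losses[0]

    def test_input_scaling_invariance(self):
        # rescaling raw features and refitting the scaler changes nothing
        ds = random_dataset(seed=5)
        m1, _ = train(ds, TrainSpec(max_epochs=200, seed=3))
        ds2 = LabeledDataset(
            features=ds.features * 37.5,
            targets_deg=ds.targets_deg,
            trial_ids=ds.trial_ids,
        )
        m2, _ = train(ds2, TrainSpec(max_epochs=200, seed=3))
        p1 = forward(m1, ds.features)
        p2 = forward(m2, ds2.features)
        np.testing.assert_allclose(p1, p2, atol=1e-8)

    def test_empty_dataset(self):
        ds = LabeledDataset(
            features=np.zeros((0, 4)), targets_deg=np.zeros(0), trial_ids=np.zeros(0, int)
        )
        with pytest.raises(InvalidInputError):
            train(ds)


class TestPersistence:
    def test_roundtrip(self, trained_model):
        model, _, test_set, _ = trained_model
        clone = model_from_dict(model_to_dict(model))
        np.testing.assert_array_equal(
            forward(model, test_set.features), forward(clone, test_set.features)
        )
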