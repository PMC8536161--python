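"""Imputation, scaling, splitting, ranking, windowing, resizing, CAE."""

import numpy as np
import pytest

from deepens import (
    FeatureTable,
    Recording,
    RecordingSet,
    SplitSpec,
    apply_standard_scaler,
    cae_extract,
    cae_fit,
    fit_standard_scaler,
    generate_windows,
    impute_feature_mean,
    impute_participant_time_mean,
    rank_features_rf,
    resize_images,
    split_dataset,
)
from deepens.preprocessing import (
    MINUTES_PER_DAY,
    ImageStack,
    apportion,
    downsample_to_daily_profile,
    invert_standard_scaler,
)


def make_table(values, mask=None, labels=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros_like(values, dtype=bool)
    if labels is None:
        labels = np.zeros(len(values), dtype=int)
        labels[: len(values) // 2] = 1
    names = [f"f{j}" for j in range(values.shape[1])]
    return FeatureTable(values, np.asarray(mask, dtype=bool), labels, names)


def make_recording(day_values, pid="p0", label=0, missing=None):
    """day_values: (D, 1440) array; missing: boolean same shape."""
    day_values = np.asarray(day_values, dtype=float)
    mask = np.zeros_like(day_values, dtype=bool) if missing is None else np.asarray(missing, dtype=bool)
    return Recording(pid, label, day_values.reshape(-1), mask.reshape(-1))


class TestFeatureImputation:
    def test_column_mean_fills_missing(self):
        t = make_table([[1.0], [0.0], [3.0]], mask=[[False], [True], [False]])
        out = impute_feature_mean(t)
        np.testing.assert_array_equal(out.values[:, 0], [1.0, 2.0, 3.0])
        assert not out.missing_mask.any()

    def test_no_missing_is_identity(self):
        t = make_table([[1.0, 2.0], [3.0, 4.0]])
        out = impute_feature_mean(t)
        np.testing.assert_array_equal(out.values, t.values)

    def test_all_missing_column_names_offender(self):
        t = make_table([[0.0], [0.0]], mask=[[True], [True]])
        with pytest.raises(ValueError, match="f0"):
            impute_feature_mean(t)

    def test_idempotent(self):
        t = make_table(np.arange(12.0).reshape(4, 3), mask=np.eye(4, 3, dtype=bool))
        once = impute_feature_mean(t)
        twice = impute_feature_mean(once)
        np.testing.assert_array_equal(once.values, twice.values)


class TestParticipantTimeImputation:
    def test_minute_of_day_mean_across_days(self):
        days = np.ones((3, MINUTES_PER_DAY))
        days[0, 600] = 10.0
        days[1, 600] = 0.0  # missing
        days[2, 600] = 20.0
        missing = np.zeros_like(days, dtype=bool)
        missing[1, 600] = True
        rec = make_recording(days, missing=missing)
        out = impute_participant_time_mean(RecordingSet([rec]))
        assert out.recordings[0].values.reshape(3, -1)[1, 600] == 15.0

    def test_identity_without_missing(self):
        days = np.arange(2 * MINUTES_PER_DAY, dtype=float).reshape(2, -1)
        out = impute_participant_time_mean(RecordingSet([make_recording(days)]))
        np.testing.assert_array_equal(out.recordings[0].values, days.reshape(-1))

    def test_minute_missing_every_day_falls_back_to_overall_mean(self):
        days = np.full((2, MINUTES_PER_DAY), 4.0)
        missing = np.zeros_like(days, dtype=bool)
        missing[:, 100] = True  # minute 100 missing on all days
        rec = make_recording(days, missing=missing)
        out = impute_participant_time_mean(RecordingSet([rec]))
        overall = 4.0  # mean of all observed values
        assert out.recordings[0].values.reshape(2, -1)[0, 100] == overall

    def test_entirely_missing_series_rejected(self):
        days = np.zeros((1, MINUTES_PER_DAY))
        rec = make_recording(days, missing=np.ones_like(days, dtype=bool))
        with pytest.raises(ValueError, match="entirely missing"):
            impute_participant_time_mean(RecordingSet([rec]))

    def test_idempotent(self):
        days = np.ones((2, MINUTES_PER_DAY))
        missing = np.zeros_like(days, dtype=bool)
        missing[0, :50] = True
        rec = make_recording(days, missing=missing)
        once = impute_participant_time_mean(RecordingSet([rec]))
        twice = impute_participant_time_mean(once)
        np.testing.assert_array_equal(once.recordings[0].values, twice.recordings[0].values)


class TestStandardScaler:
    def test_population_sd_hand_example(self):
        t = make_table([[0.0], [2.0]])
        params = fit_standard_scaler(t)
        assert params.mu[0] == 1.0 and params.sigma[0] == 1.0
        np.testing.assert_array_equal(apply_standard_scaler(params, t).values[:, 0], [-1.0, 1.0])

    def test_constant_column_centres_to_zero(self):
        t = make_table([[5.0], [5.0], [5.0]])
        params = fit_standard_scaler(t)
        np.testing.assert_array_equal(apply_standard_scaler(params, t).values[:, 0], [0.0, 0.0, 0.0])

    def test_out_of_sample_value(self):
        train = make_table([[0.0], [2.0]])
        params = fit_standard_scaler(train)
        test = make_table([[4.0]])
        assert apply_standard_scaler(params, test).values[0, 0] == 3.0

    def test_train_set_standardised_to_unit_moments(self, rng):
        t = make_table(rng.normal(5, 3, size=(50, 4)))
        scaled = apply_standard_scaler(fit_standard_scaler(t), t)
        np.testing.assert_allclose(scaled.values.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(scaled.values.std(axis=0), 1.0, atol=1e-9)

    def test_round_trip_recovers_inputs(self, rng):
        t = make_table(rng.normal(size=(30, 3)))
        params = fit_standard_scaler(t)
        back = invert_standard_scaler(params, apply_standard_scaler(params, t))
        np.testing.assert_allclose(back.values, t.values, atol=1e-9)


class TestSplitDataset:
    def test_exact_proportions_of_100(self):
        tr, va, te = split_dataset(100, SplitSpec(seed=0))[0]
        assert (len(tr), len(va), len(te)) == (80, 4, 16)

    def test_largest_remainder_at_25(self):
        tr, va, te = split_dataset(25, SplitSpec(seed=0))[0]
        assert (len(tr), len(va), len(te)) == (20, 1, 4)

    def test_same_seed_identical_partitions(self):
        a = split_dataset(97, SplitSpec(seed=5))
        b = split_dataset(97, SplitSpec(seed=5))
        for (ta, va_, xa), (tb, vb, xb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(va_, vb)
            np.testing.assert_array_equal(xa, xb)

    def test_folds_disjoint_exhaustive_fixed_test(self):
        folds = split_dataset(137, SplitSpec(seed=3))
        test0 = folds[0][2]
        for tr, va, te in folds:
            np.testing.assert_array_equal(te, test0)
            combined = np.sort(np.concatenate([tr, va, te]))
            np.testing.assert_array_equal(combined, np.arange(137))

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(train=0.8, val=0.3, test=0.16)

    def test_apportion_ties_favour_earlier_partition(self):
        assert apportion(10, [0.25, 0.25, 0.5]) == [3, 2, 5]


class TestRankFeaturesRF:
    def test_planted_deterministic_feature_ranked_first(self, rng):
        n = 400
        y = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, 5))
        X[:, 2] = y * 2.0 - 1.0  # feature 2 fully determines the label
        t = FeatureTable(X, np.zeros_like(X, dtype=bool), y, [f"f{j}" for j in range(5)])
        ranking = rank_features_rf(t, seed=1)
        assert ranking.iloc[0]["feature"] == "f2"

    def test_importances_sum_to_one(self, planted_table):
        ranking = rank_features_rf(planted_table, seed=0)
        assert ranking["importance"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_exchangeable_noise_features_near_equal_importance(self, rng):
        n = 1000
        y = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, 2))
        t = FeatureTable(X, np.zeros_like(X, dtype=bool), y, ["a", "b"])
        ranking = rank_features_rf(t, seed=0)
        assert abs(ranking["importance"].iloc[0] - ranking["importance"].iloc[1]) < 0.1


class TestGenerateWindows:
    def test_seven_days_yield_one_window_of_10080(self):
        rec = make_recording(np.ones((7, MINUTES_PER_DAY)))
        w = generate_windows(RecordingSet([rec]))
        assert len(w) == 1 and w.values.shape[1] == 10080

    def test_thirteen_days_yield_seven_windows(self):
        rec = make_recording(np.ones((13, MINUTES_PER_DAY)))
        w = generate_windows(RecordingSet([rec]))
        assert len(w) == 7

    def test_six_days_yield_zero_windows(self):
        rec = make_recording(np.ones((6, MINUTES_PER_DAY)))
        assert len(generate_windows(RecordingSet([rec]))) == 0

    def test_consecutive_windows_start_one_day_apart(self):
        days = np.arange(9 * MINUTES_PER_DAY, dtype=float).reshape(9, -1)
        w = generate_windows(RecordingSet([make_recording(days)]))
        np.testing.assert_array_equal(w.start_days, [0, 1, 2])
        # window k starts exactly one day after window k-1
        np.testing.assert_array_equal(w.values[1][:MINUTES_PER_DAY], days[1])

    def test_labels_inherited(self):
        rec = make_recording(np.ones((8, MINUTES_PER_DAY)), label=1)
        w = generate_windows(RecordingSet([rec]))
        assert (w.labels == 1).all()

    def test_daily_profile_downsample(self):
        days = np.vstack([np.full(MINUTES_PER_DAY, d) for d in range(7, 14)])
        w = generate_windows(RecordingSet([make_recording(days.astype(float))]))
        prof = downsample_to_daily_profile(w)
        assert prof.values.shape == (1, MINUTES_PER_DAY)
        np.testing.assert_allclose(prof.values[0], np.mean(np.arange(7, 14)))


class TestResizeImages:
    def test_shape_contract(self, rng):
        stack = ImageStack([rng.uniform(size=(40, 30))], np.array([0]))
        out = resize_images(stack, target=(20, 20, 1))
        assert out.images[0].shape == (20, 20, 1)

    def test_constant_image_stays_constant(self):
        stack = ImageStack([np.full((17, 9), 0.42)], np.array([1]))
        out = resize_images(stack, target=(20, 20, 1))
        np.testing.assert_allclose(out.images[0], 0.42)

    def test_identity_when_already_target(self, rng):
        im = rng.uniform(size=(20, 20))
        out = resize_images(ImageStack([im], np.array([0])), target=(20, 20, 1))
        np.testing.assert_array_equal(out.images[0][:, :, 0], im)

    def test_integer_input_normalised_to_unit_range(self, rng):
        im = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
        out = resize_images(ImageStack([im], np.array([0])), target=(16, 16, 1))
        assert out.images[0].max() <= 1.0
        np.testing.assert_allclose(out.images[0][:, :, 0], im / 255.0)

    def test_zero_area_image_rejected(self):
        with pytest.raises(ValueError):
            resize_images(ImageStack([np.empty((0, 5))], np.array([0])), target=(8, 8, 1))


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(0)
    images = [np.clip(rng.uniform(size=(16, 16)) + 0.3 * (i % 2), 0, 1)[:, :, None] for i in range(40)]
    stack = ImageStack(images, np.arange(40) % 2)
    model = cae_fit(stack, bottleneck_dim=12, epochs=5, seed=0)
    return stack, model


class TestCAE:

    def test_feature_shape_contract(self, fitted):
        stack, model = fitted
        feats = cae_extract(model, stack)
        assert feats.values.shape == (40, 12)

    def test_extraction_deterministic_with_frozen_weights(self, fitted):
        stack, model = fitted
        a = cae_extract(model, stack).values
        b = cae_extract(model, stack).values
        np.testing.assert_array_equal(a, b)

    def test_reconstruction_loss_improves(self, fitted):
        _, model = fitted
        assert min(model.train_losses) < model.train_losses[0]

    def test_unfitted_extraction_rejected(self, fitted):
        stack, model = fitted
        from deepens.preprocessing import CAEModel

        unfitted = CAEModel(model.network, model.bottleneck_index, model.input_shape, model.bottleneck_dim)
        with pytest.raises(RuntimeError):
            cae_extract(unfitted, stack)

    def test_cae_ignores_non_training_images(self):
        """Fitting is a function of the training stack only."""
        rng = np.random.default_rng(1)
        images = [rng.uniform(size=(8, 8, 1)) for _ in range(20)]
        stack = ImageStack(images, np.zeros(20, dtype=int))
        m1 = cae_fit(stack, bottleneck_dim=4, epochs=2, seed=3)
        m2 = cae_fit(stack, bottleneck_dim=4, epochs=2, seed=3)
        for a, b in zip(m1.network.get_weights(), m2.network.get_weights()):
            np.testing.assert_array_equal(a, b)


class TestRoundTrips:
    def test_feature_table_csv_round_trip(self, tmp_path, rng):
        values = rng.normal(size=(10, 3))
        mask = rng.random((10, 3)) < 0.2
        t = FeatureTable(np.where(mask, 0, values), mask, rng.integers(0, 2, 10), ["a", "b", "c"])
        path = tmp_path / "t.csv"
        t.to_csv(path)
        back = FeatureTable.from_csv(path)
        np.testing.assert_array_equal(back.missing_mask, t.missing_mask)
        np.testing.assert_allclose(back.values[~back.missing_mask], t.values[~t.missing_mask])
        np.testing.assert_array_equal(back.labels, t.labels)

    def test_recording_set_csv_round_trip(self, tmp_path, rng):
        days = rng.uniform(size=(2, MINUTES_PER_DAY))
        missing = rng.random((2, MINUTES_PER_DAY)) < 0.1
        rec = make_recording(np.where(missing, 0, days), pid="p7", label=1, missing=missing)
        rs = RecordingSet([rec])
        path = tmp_path / "rs.csv"
        rs.to_csv(path)
        back = RecordingSet.from_csv(path)
        np.testing.assert_array_equal(back.recordings[0].missing_mask, missing.reshape(-1))
        assert back.recordings[0].label == 1
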