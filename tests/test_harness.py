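import numpy as np
import pytest

from ezar import (
    ExampleSet,
    TrainConfig,
    ValidationError,
    build_model,
    desk_preset,
    duplication_selection,
    fscore,
    measure_area_pct,
    full_scale_preset,
    predict_bscan,
    preprocess,
    split_patients,
    train,
)
from ezar.harness import EarlyStopping, ScaleRecord, _largest_remainder


class TestSplitPatients:
    def test_ten_patients_split_8_1_1(self):
        plan = split_patients([f"p{i}" for i in range(10)], seed=0)
        assert (len(plan.train_ids), len(plan.val_ids), len(plan.test_ids)) == (
            8, 1, 1,
        )

    def test_largest_remainder_rounding(self):
        # 12 * (0.8, 0.1, 0.1) = (9.6, 1.2, 1.2): the extra unit goes to
        # the largest fractional remainder (train)
        assert _largest_remainder(12, (0.8, 0.1, 0.1)) == [10, 1, 1]
        assert _largest_remainder(10, (0.8, 0.1, 0.1)) == [8, 1, 1]
        assert _largest_remainder(7, (0.5, 0.25, 0.25)) == [3, 2, 2]

    def test_deterministic_in_seed(self):
        ids = [f"p{i}" for i in range(30)]
        assert split_patients(ids, seed=5) == split_patients(ids, seed=5)
        assert split_patients(ids, seed=5) != split_patients(ids, seed=6)

    def test_partition_is_disjoint_and_complete(self):
        ids = [f"p{i}" for i in range(37)]
        for seed in range(50):
            plan = split_patients(ids, seed=seed)
            union = set(plan.train_ids) | set(plan.val_ids) | set(plan.test_ids)
            assert union == set(ids)
            assert len(plan.train_ids) + len(plan.val_ids) + len(
                plan.test_ids
            ) == len(ids)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValidationError):
            split_patients(["a", "b"], fractions=(0.5, 0.2, 0.2))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError):
            split_patients(["a", "a", "b"])


class TestPreprocess:
    def test_scale_factors(self):
        img = np.zeros((512, 512))
        _, _, rec = preprocess(img, input_size=256)
        assert (rec.row_factor, rec.col_factor) == (2.0, 2.0)
        _, _, rec = preprocess(np.zeros((256, 256)), input_size=256)
        assert (rec.row_factor, rec.col_factor) == (1.0, 1.0)

    def test_non_2d_rejected(self):
        with pytest.raises(ValidationError):
            preprocess(np.zeros((4, 4, 4)))

    def test_mask_area_preserved_through_round_trip(self):
        mask = np.zeros((200, 300), dtype=bool)
        mask[40:90, 100:220] = True  # 50 x 120 px blob
        _, mask_r, rec = preprocess(np.zeros((200, 300)), mask, input_size=64)
        from skimage.transform import resize

        back = resize(mask_r.astype(float), rec.original, order=0,
                      preserve_range=True) >= 0.5
        assert back.mean() == pytest.approx(mask.mean(), rel=0.02)


class TestMeasureArea:
    def test_all_zero_map(self):
        rec = ScaleRecord((100, 100), (64, 64))
        assert measure_area_pct(np.zeros((64, 64)), 0.5, rec) == 0.0

    def test_uniform_above_threshold(self):
        rec = ScaleRecord((100, 100), (64, 64))
        assert measure_area_pct(np.full((64, 64), 0.9), 0.5, rec) == 100.0

    def test_half_plane_through_resize(self):
        prob = np.zeros((64, 64))
        prob[:32] = 1.0
        rec = ScaleRecord((496, 512), (64, 64))
        assert measure_area_pct(prob, 0.5, rec) == pytest.approx(50.0, abs=0.5)

    def test_threshold_bounds(self):
        rec = ScaleRecord((10, 10), (10, 10))
        with pytest.raises(ValidationError):
            measure_area_pct(np.zeros((10, 10)), 1.0, rec)


class TestFscore:
    def test_worked_cases(self):
        a = np.zeros((4, 4), dtype=bool)
        a[0, :4] = True
        assert fscore(a, a) == 1.0
        b = np.zeros((4, 4), dtype=bool)
        b[1, :4] = True
        assert fscore(a, b) == 0.0
        c = np.zeros((4, 4), dtype=bool)
        c[0, 2:4] = True
        c[1, 0:2] = True
        assert fscore(a, c) == pytest.approx(0.5)

    def test_empty_masks_agree_perfectly(self):
        empty = np.zeros((3, 3), dtype=bool)
        assert fscore(empty, empty) == 1.0
        nonempty = empty.copy()
        nonempty[0, 0] = True
        assert fscore(empty, nonempty) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            fscore(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestEarlyStopping:
    def test_patience_schedule(self):
        # no improvement for 7 epochs after epoch 2 -> stop at epoch 9
        stopper = EarlyStopping(patience=7)
        losses = [1.0] + [0.9] * 8
        stops = [stopper.update(v) for v in losses]
        assert stops == [False] * 8 + [True]
        assert stopper.best_epoch == 2
        assert stopper.epoch == 9

    def test_improvement_resets_counter(self):
        stopper = EarlyStopping(patience=2)
        assert [stopper.update(v) for v in [1.0, 0.9, 0.95, 0.8, 0.9, 0.85]] == [
            False, False, False, False, False, True,
        ]
        assert stopper.best_epoch == 4


class TestDuplicationRule:
    def test_hundred_distinct_scores_duplicate_thirty(self):
        rng = np.random.default_rng(0)
        scores = rng.permutation(np.linspace(0.01, 0.99, 100))
        cut, mask = duplication_selection(scores, 30)
        assert mask.sum() == 30
        assert (scores[mask] < cut).all()

    def test_equal_scores_duplicate_nothing(self):
        cut, mask = duplication_selection(np.full(100, 0.7), 30)
        assert mask.sum() == 0


class TestModel:
    def test_desk_preset_parameter_budget(self):
        assert build_model(desk_preset()).n_params < 500_000

    def test_full_scale_preset_is_about_twenty_million(self):
        n = build_model(full_scale_preset()).n_params
        assert 1.5e7 < n < 2.5e7

    def test_seeded_init_is_reproducible(self):
        cfg = desk_preset(seed=3)
        w1 = build_model(cfg).get_weights()
        w2 = build_model(cfg).get_weights()
        for a, b in zip(w1, w2):
            np.testing.assert_array_equal(a, b)

    def test_output_shape_and_range(self):
        cfg = TrainConfig(input_size=32, base_filters=4, depth=2,
                          batch_size=2, samples_per_epoch=4)
        model = build_model(cfg)
        x = np.random.default_rng(0).random((3, 32, 32))
        prob = model.predict_proba(x)
        assert prob.shape == (3, 32, 32)
        assert prob.min() > 0.0 and prob.max() < 1.0

    def test_invalid_input_size_rejected(self):
        with pytest.raises(ValidationError):
            TrainConfig(input_size=100)
        with pytest.raises(ValidationError):
            TrainConfig(input_size=4, depth=3)


def _band_examples(n, size=32, seed=0):
    """Tiny synthetic task: segment a bright horizontal band."""
    rng = np.random.default_rng(seed)
    images = np.zeros((n, size, size), dtype=np.float32)
    masks = np.zeros((n, size, size), dtype=bool)
    rows = np.arange(size)[:, None]
    for i in range(n):
        r = rng.integers(8, size - 8)
        images[i] = 0.1 + 0.8 * np.exp(-((rows - r) ** 2) / 4.0)
        images[i] += 0.05 * rng.standard_normal((size, size))
        masks[i, r - 2 : r + 3, :] = True
    return np.clip(images, 0, 1), masks


@pytest.fixture(scope="module")
def tiny_run():
    images, masks = _band_examples(48)
    cfg = TrainConfig(input_size=32, base_filters=4, depth=2,
                      batch_size=8, samples_per_epoch=40,
                      learning_rate=3e-3, max_epochs=4, seed=0)
    train_set = ExampleSet(images[:32], masks[:32],
                           [str(i) for i in range(32)])
    val_set = ExampleSet(images[32:40], masks[32:40],
                         [str(i) for i in range(32, 40)])
    model = build_model(cfg)
    state = train(model, train_set, val_set, cfg)
    return model, state, cfg, (images[40:], masks[40:])


class TestTraining:
    def test_loss_decreases(self, tiny_run):
        _, state, _, _ = tiny_run
        assert state.train_losses[-1] < state.train_losses[0]

    def test_state_bookkeeping(self, tiny_run):
        _, state, cfg, _ = tiny_run
        assert 1 <= state.best_epoch <= state.stopped_epoch
        assert state.stopped_epoch <= cfg.max_epochs
        assert len(state.train_losses) == len(state.val_losses)

    def test_same_seed_reproduces_history(self, tiny_run):
        _, state, cfg, _ = tiny_run
        images, masks = _band_examples(48)
        train_set = ExampleSet(images[:32], masks[:32],
                               [str(i) for i in range(32)])
        val_set = ExampleSet(images[32:40], masks[32:40],
                             [str(i) for i in range(32, 40)])
        model = build_model(cfg)
        state2 = train(model, train_set, val_set, cfg)
        np.testing.assert_allclose(state2.train_losses, state.train_losses)

    def test_predict_bscan_returns_prob_and_scale(self, tiny_run):
        model, _, cfg, (images, _) = tiny_run
        prob, rec = predict_bscan(model, images[0], cfg.input_size)
        assert prob.shape == (32, 32)
        assert 0 <= prob.min() and prob.max() <= 1
        assert rec.original == images[0].shape


class TestUNetSegmenterEstimator:
    def test_fit_predict_and_param_round_trip(self):
        from ezar import UNetSegmenter

        images, masks = _band_examples(24, size=32, seed=4)
        est = UNetSegmenter(input_size=32, base_filters=4, depth=2,
                            batch_size=8, samples_per_epoch=24,
                            learning_rate=3e-3, max_epochs=2, random_state=0)
        params = est.get_params()
        assert params["base_filters"] == 4
        est.set_params(max_epochs=3)
        assert est.max_epochs == 3
        with pytest.raises(ValueError):
            est.set_params(bogus=1)

        est.set_params(max_epochs=2).fit(images[:20], masks[:20])
        assert est.n_params_ > 0
        prob = est.predict_proba(images[20:])
        assert prob.shape == (4, 32, 32)
        pred = est.predict(images[20:])
        assert pred.dtype == bool
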