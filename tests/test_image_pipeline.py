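from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from phenoscale.errors import ParameterError
from phenoscale.images import (
    CanopyRegressor,
    ImageTensor,
    RegressorSpec,
    augment,
    evaluate_daily,
    preprocess_image,
    select_time_window,
    split_by_dat,
)
from phenoscale.simulate import CameraSpec, green_fraction, render_canopy_image
from phenoscale.types import CanopyImage, LabelTable


def manifest_at(times):
    return pd.DataFrame(
        {
            "filename": [f"f{i}.png" for i in range(len(times))],
            "dat": 1,
            "timestamp": [f"2020-03-01T{t}" for t in times],
        }
    )


class TestTimeWindow:
    def test_closed_boundaries(self):
        m = select_time_window(manifest_at(["07:50:00", "08:00:00", "16:00:00", "16:10:00"]))
        assert m.filename.tolist() == ["f1.png", "f2.png"]

    def test_all_night_manifest_is_empty(self):
        m = select_time_window(manifest_at(["22:00:00", "03:10:00"]))
        assert len(m) == 0

    def test_ten_minute_grid_keeps_49_frames_per_day(self):
        times = pd.date_range("2020-03-01", periods=144, freq="10min")
        m = pd.DataFrame(
            {"filename": "x.png", "dat": 1, "timestamp": times.astype(str)}
        )
        assert len(select_time_window(m)) == 49


class TestPreprocess:
    def test_hd_frame_becomes_128_square(self):
        img = render_canopy_image(2000.0, CameraSpec(), seed=1)
        t = preprocess_image(img)
        assert t.pixels.shape == (128, 128, 3)
        assert 0.0 <= t.pixels.min() and t.pixels.max() <= 1.0

    def test_uniform_image_stays_uniform(self):
        px = np.full((720, 1280, 3), 77, dtype=np.uint8)
        img = CanopyImage(px, datetime(2020, 3, 1, 12), 1)
        t = preprocess_image(img)
        assert np.allclose(t.pixels, 77 / 255.0)
        assert t.pixels.shape == (128, 128, 3)

    def test_identity_path_only_rescales(self):
        rng = np.random.default_rng(0)
        px = rng.integers(0, 256, size=(128, 128, 3), dtype=np.uint8)
        img = CanopyImage(px, datetime(2020, 3, 1, 12), 4)
        t = preprocess_image(img, margins=(0, 0))
        assert np.array_equal(t.pixels, px / 255.0)
        assert t.dat == 4

    def test_margins_larger_than_frame_rejected(self):
        px = np.zeros((100, 100, 3), dtype=np.uint8)
        img = CanopyImage(px, datetime(2020, 3, 1, 12), 1)
        with pytest.raises(ParameterError):
            preprocess_image(img, margins=(60, 10))


class TestAugment:
    def tensor(self):
        img = render_canopy_image(2500.0, CameraSpec(height=180, width=320), seed=2)
        return preprocess_image(img, margins=(20, 10))

    def test_seeded_determinism(self):
        t = self.tensor()
        a = augment(t, seed=5)
        b = augment(t, seed=5)
        assert np.array_equal(a.pixels, b.pixels)

    def test_double_horizontal_flip_is_identity(self):
        t = self.tensor()
        once = augment(t, seed=0, flip_h=True, flip_v=False, shift=(0, 0), angle=0.0)
        twice = augment(once, seed=0, flip_h=True, flip_v=False, shift=(0, 0), angle=0.0)
        assert np.array_equal(twice.pixels, t.pixels)

    def test_mean_green_intensity_approximately_preserved(self):
        t = self.tensor()
        base = t.pixels[..., 1].mean()
        flip_devs, full_devs = [], []
        for seed in range(100):
            f = augment(t, seed=seed, shift=(0, 0), angle=0.0)
            flip_devs.append(abs(f.pixels[..., 1].mean() - base) / base)
            g = augment(t, seed=seed)
            full_devs.append(abs(g.pixels[..., 1].mean() - base) / base)
        assert max(flip_devs) < 0.02  # flips are exact
        assert max(full_devs) < 0.05  # reflection padding perturbs mildly


class TestSplit:
    def test_stratified_by_dat(self):
        dats = np.repeat(np.arange(10), 10)
        tr, va = split_by_dat(dats, 0.7, seed=0)
        assert len(tr) + len(va) == 100
        assert set(tr).isdisjoint(va)
        for d in range(10):
            assert (dats[tr] == d).sum() == 7
            assert (dats[va] == d).sum() == 3

    def test_bad_fraction_rejected(self):
        with pytest.raises(ParameterError):
            split_by_dat(np.array([1, 2]), 1.5, seed=0)


def _toy_dataset(n_dats=10, per_day=2, seed=0):
    """Tiny gradient-patterned tensors whose brightness tracks the label."""
    rng = np.random.default_rng(seed)
    tensors, labels = [], np.linspace(200, 4000, n_dats)
    for d in range(n_dats):
        level = labels[d] / 4000.0
        for _ in range(per_day):
            px = np.clip(
                level * np.ones((128, 128, 3)) * 0.8
                + rng.normal(0, 0.02, size=(128, 128, 3)),
                0,
                1,
            )
            tensors.append(ImageTensor(px, d + 1, datetime(2020, 3, 1, 12)))
    table = LabelTable(dat=np.arange(1, n_dats + 1), leaf_area_label=labels)
    return tensors, table


class TestRegressor:
    def test_overfit_smoke_capacity(self):
        tensors, table = _toy_dataset()
        spec = RegressorSpec(
            conv_filters=(8, 16), epochs=200, lr=3e-3, batch_size=20, augment_prob=0.0
        )
        res = CanopyRegressor(tensors, table, spec).fit(train_fraction=0.9, seed=1)
        label_range = table.leaf_area_label.max() - table.leaf_area_label.min()
        train_mae_cm2 = res.history["train_mae"][-1] * res.label_sd
        assert train_mae_cm2 < 0.05 * label_range

    def test_same_seed_same_validation_curve(self):
        tensors, table = _toy_dataset()
        spec = RegressorSpec(conv_filters=(8,), epochs=3, augment_prob=0.0)
        r1 = CanopyRegressor(tensors, table, spec).fit(seed=2)
        r2 = CanopyRegressor(tensors, table, spec).fit(seed=2)
        assert r1.history["val_mae"] == r2.history["val_mae"]

    def test_checkpoint_roundtrip_preserves_predictions(self, tmp_path):
        tensors, table = _toy_dataset()
        spec = RegressorSpec(conv_filters=(8,), epochs=2, augment_prob=0.0)
        res = CanopyRegressor(tensors, table, spec).fit(seed=3)
        before = res.predict(tensors)
        path = tmp_path / "model.npz"
        res.save_weights(path)
        fresh = CanopyRegressor(tensors, table, spec).fit(seed=99)
        fresh.load_weights(path)
        assert np.allclose(fresh.predict(tensors), before)

    def test_single_dat_rejected(self):
        tensors, table = _toy_dataset(n_dats=1, per_day=3)
        with pytest.raises(ParameterError):
            CanopyRegressor(tensors, table, RegressorSpec())


class TestPermutedLabels:
    def test_null_labels_are_decorrelated_and_value_preserving(self):
        from phenoscale.images import permuted_labels

        labels = LabelTable(
            dat=np.arange(80), leaf_area_label=np.linspace(100, 5100, 80)
        )
        for seed in range(5):
            null = permuted_labels(labels, seed=seed)
            assert sorted(null.leaf_area_label) == sorted(labels.leaf_area_label)
            r = np.corrcoef(labels.leaf_area_label, null.leaf_area_label)[0, 1]
            assert abs(r) < 0.05
            assert np.array_equal(null.dat, labels.dat)


class TestDailyAggregation:
    def test_mean_min_max_per_day(self, cross_season_imageset, trained_canopy_model):
        tensors_b, _ = cross_season_imageset["test"]
        daily = trained_canopy_model.predict_daily(tensors_b)
        assert (daily["min"] <= daily["mean"]).all()
        assert (daily["mean"] <= daily["max"]).all()
        assert daily.dat.is_unique

    def test_evaluate_requires_overlap(self):
        preds = pd.DataFrame({"dat": [1], "mean": [1.0], "min": [1.0], "max": [1.0]})
        table = LabelTable(dat=np.array([1]), leaf_area_label=np.array([1.0]))
        from phenoscale.errors import EvaluationError

        with pytest.raises(EvaluationError):
            evaluate_daily(preds, table)


def test_predictions_track_green_pixel_fraction(
    cross_season_imageset, trained_canopy_model
):
    """The regressor must rely on the projected-canopy-area signal."""
    from scipy.stats import spearmanr

    tensors_b, _ = cross_season_imageset["test"]
    pred = trained_canopy_model.predict(tensors_b)
    gf = [
        green_fraction((t.pixels * 255).astype(np.uint8)) for t in tensors_b
    ]
    rho = spearmanr(gf, pred).statistic
    assert rho >= 0.8
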