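import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pondcast import imaging
from pondcast.imaging import (
    PerturbationSpec,
    ProfileImage,
    ProfileImageEncoder,
    band_heights,
    perturb,
    render_interval_image,
    render_panel,
)
from pondcast.types import SensorSeries


def _series(values, cadence=15):
    times = pd.date_range("2014-06-01", periods=len(values), freq=f"{cadence}min")
    return SensorSeries("P1", "T", times, np.asarray(values, float), cadence)


# ------------------------------------------------------------- perturbations

@pytest.mark.parametrize("kind", ["offset", "expand", "shrink"])
def test_zero_factor_is_identity(kind):
    s = _series([1.0, 2.0, 3.0, 4.0])
    out = perturb(s, PerturbationSpec(kind=kind, factor=0.0, parameter="T"))
    np.testing.assert_allclose(out.values, s.values, rtol=1e-15)


def test_shrink_constant_series_unchanged():
    s = _series([5.0] * 8)
    out = perturb(s, PerturbationSpec(kind="shrink", factor=0.7, parameter="T"))
    np.testing.assert_array_equal(out.values, s.values)


def test_shrink_unit_factor_halves_deviations():
    vals = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0])
    s = _series(vals)
    out = perturb(s, PerturbationSpec(kind="shrink", factor=1.0, parameter="T"))
    np.testing.assert_allclose(out.values - vals.mean(), (vals - vals.mean()) / 2, rtol=1e-12)
    assert out.values.mean() == pytest.approx(vals.mean(), rel=1e-12)


@given(
    vals=st.lists(st.floats(-50, 50), min_size=3, max_size=30),
    factor=st.sampled_from([0.05, 0.25, 0.5, 1.0]),
)
def test_expand_and_shrink_preserve_mean(vals, factor):
    s = _series(vals)
    for kind in ("expand", "shrink"):
        out = perturb(s, PerturbationSpec(kind=kind, factor=factor, parameter="T"))
        assert out.values.mean() == pytest.approx(s.values.mean(), abs=1e-9)


def test_invalid_spec_rejected():
    with pytest.raises(ValueError):
        PerturbationSpec(kind="multiply", factor=0.5, parameter="T")
    with pytest.raises(ValueError):
        PerturbationSpec(kind="shrink", factor=0.5, parameter="XX")


# ------------------------------------------------------------- panels

def test_constant_series_draws_midline():
    s = _series([5.0] * 10)
    mask, _ = render_panel(s, width=40, height=21)
    rows = np.unique(np.where(mask)[0])
    assert list(rows) == [10]


def test_vertical_offset_invisible_in_panel():
    rng = np.random.default_rng(2)
    s = _series(rng.normal(10, 2, 96))
    shifted = _series(s.values + 123.456)
    m1, _ = render_panel(s, 224, 44)
    m2, _ = render_panel(shifted, 224, 44)
    np.testing.assert_array_equal(m1, m2)


def test_axis_limits_equal_to_range_are_idempotent():
    rng = np.random.default_rng(3)
    s = _series(rng.normal(0, 1, 50))
    m1, lim1 = render_panel(s, 100, 44)
    m2, lim2 = render_panel(s, 100, 44, axis_limits=(s.values.min(), s.values.max()))
    np.testing.assert_array_equal(m1, m2)
    assert lim1 == lim2


def test_gap_breaks_line():
    times = pd.DatetimeIndex(
        list(pd.date_range("2014-06-01", periods=5, freq="15min"))
        + list(pd.date_range("2014-06-01 06:00", periods=5, freq="15min"))
    )
    s = SensorSeries("P1", "T", times, np.linspace(0, 1, 10), 15)
    mask, _ = render_panel(s, 200, 44)
    # the 6 h gap leaves empty columns between the two runs
    cols = mask.any(axis=0)
    assert not cols.all()


# ------------------------------------------------------------- spliced images

@pytest.mark.parametrize("size,total", [(224, 50176), (336, 112896), (448, 200704)])
def test_pixel_counts(one_interval, size, total):
    img = render_interval_image(one_interval, size=size)
    assert img.n_pixels == total
    assert img.pixels.shape == (size, size, 3)


def test_band_layout_covers_image():
    for size in (224, 336, 448):
        hs = band_heights(size)
        assert sum(hs) == size and len(hs) == 5


def test_every_pixel_written(one_interval):
    img = render_interval_image(one_interval)
    # background is white; panels contain colored ink
    assert (img.pixels == 255).all(axis=2).mean() < 1.0
    for panel in img.layout:
        band = img.pixels[panel["row0"] : panel["row1"]]
        assert (band != 255).any()


def test_encoding_deterministic(one_interval):
    a = render_interval_image(one_interval)
    b = render_interval_image(one_interval)
    np.testing.assert_array_equal(a.pixels, b.pixels)


@pytest.mark.parametrize("sign", [1, -1])
def test_offset_perturbation_invisible(one_interval, sign):
    base = render_interval_image(one_interval)
    for factor in (0.05, 0.5, 1.0):
        spec = PerturbationSpec(kind="offset", factor=factor, parameter="DO", sign=sign)
        img = render_interval_image(one_interval, perturbation=spec)
        np.testing.assert_array_equal(img.pixels, base.pixels)


def test_expand_perturbation_invisible_under_axis_rule(one_interval):
    base = render_interval_image(one_interval)
    spec = PerturbationSpec(kind="expand", factor=0.5, parameter="T")
    img = render_interval_image(one_interval, perturbation=spec)
    np.testing.assert_array_equal(img.pixels, base.pixels)


def test_shrink_perturbation_changes_pixels(one_interval):
    base = render_interval_image(one_interval)
    spec = PerturbationSpec(kind="shrink", factor=0.5, parameter="T")
    img = render_interval_image(one_interval, perturbation=spec)
    assert (img.pixels != base.pixels).any()
    # only the targeted band may change
    t_panel = next(p for p in base.layout if p["parameter"] == "T")
    diff_rows = np.unique(np.where((img.pixels != base.pixels).any(axis=(1, 2)))[0])
    assert diff_rows.min() >= t_panel["row0"] and diff_rows.max() < t_panel["row1"]


def test_missing_parameter_raises(one_interval):
    import copy

    broken = copy.copy(one_interval)
    broken.sensor_windows = {k: v for k, v in one_interval.sensor_windows.items() if k != "PAR"}
    with pytest.raises(ValueError, match="PAR"):
        render_interval_image(broken)


def test_png_roundtrip(tmp_path, one_interval):
    img = render_interval_image(one_interval)
    path = tmp_path / "iv.png"
    img.save(path)
    loaded = ProfileImage.load(path)
    np.testing.assert_array_equal(loaded.pixels, img.pixels)
    assert loaded.layout[0]["parameter"] == "pH"


def test_encoder_transform_and_downsampling(tiny_intervals):
    enc = ProfileImageEncoder(size=224, resolution_minutes=60)
    images = enc.transform(tiny_intervals[:2])
    assert len(images) == 2
    base = ProfileImageEncoder(size=224).transform(tiny_intervals[:2])
    assert (images[0].pixels != base[0].pixels).any()  # coarser cadence draws differently
    assert enc.get_params()["size"] == 224


def test_model_input_pooling(one_interval):
    arr = imaging.images_to_model_input([render_interval_image(one_interval)], pool=4)
    assert arr.shape == (1, 1, 56, 56)
    assert 0.0 < arr.mean() < 1.0
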