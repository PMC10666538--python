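import numpy as np
import pytest

from pondcast.imaging import FACTOR_GRID
from pondcast.sensitivity import (
    LogFit,
    fit_log_curve,
    parameter_sensitivity,
    percent_change,
    select_best_predicted,
)
from pondcast.types import PARAMETERS


# ----------------------------------------------------------- percent change

def test_improvement_examples_from_headline_metrics():
    # R^2 is higher-better; RMSE/MAE lower-better (reference = AVM test set)
    assert percent_change(0.3883, 0.7668) == pytest.approx(97.47, abs=0.01)
    assert percent_change(3.1257, 1.9901, lower_is_better=True) == pytest.approx(36.33, abs=0.01)
    assert percent_change(2.4711, 1.5081, lower_is_better=True) == pytest.approx(38.97, abs=0.01)


def test_penalty_is_sign_flipped_improvement():
    assert percent_change(1.9901, 2.7581, lower_is_better=True, direction="penalty") == (
        pytest.approx(38.59, abs=0.01)
    )
    assert percent_change(0.7668, 0.4902, direction="penalty") == pytest.approx(36.07, abs=0.01)


def test_no_change_is_zero_and_zero_reference_rejected():
    assert percent_change(1.5, 1.5) == 0.0
    with pytest.raises(ValueError):
        percent_change(0.0, 1.0)


def test_percent_change_round_trips(rng):
    for _ in range(25):
        ref = rng.uniform(0.1, 5.0)
        new = rng.uniform(0.1, 5.0)
        pct = percent_change(ref, new)
        assert ref * (1 + pct / 100.0) == pytest.approx(new, rel=1e-12)


# ----------------------------------------------------------- log fit

def test_exact_log_line_recovered():
    x = np.array([10.0, 40.0, 160.0, 640.0])
    pts = [(v, -0.1 * np.log(v) + 1.0) for v in x]
    fit = fit_log_curve(pts)
    assert fit.slope == pytest.approx(-0.1, abs=1e-12)
    assert fit.intercept == pytest.approx(1.0, abs=1e-12)
    assert fit.fit_r2 == pytest.approx(1.0, abs=1e-12)


def test_two_points_fit_perfectly():
    fit = fit_log_curve([(15.0, 0.8), (240.0, 0.5)])
    assert fit.fit_r2 == pytest.approx(1.0)


def test_log_fit_matches_normal_equations_oracle(rng):
    for _ in range(20):
        x = rng.uniform(5, 500, size=6)
        y = rng.normal(size=6)
        fit = fit_log_curve(list(zip(x, y)))
        lx = np.log(x)
        n = len(x)
        slope = (n * (lx * y).sum() - lx.sum() * y.sum()) / (n * (lx**2).sum() - lx.sum() ** 2)
        intercept = (y.sum() - slope * lx.sum()) / n
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)


def test_log_fit_input_validation():
    with pytest.raises(ValueError):
        fit_log_curve([(15.0, 0.5)])
    with pytest.raises(ValueError):
        fit_log_curve([(15.0, 0.5), (15.0, 0.6)])
    fit = fit_log_curve([(15.0, 0.5), (15.0, 0.6), (60.0, 0.4)])  # duplicate x allowed
    assert isinstance(fit, LogFit)


def test_log_fit_prediction():
    fit = LogFit(slope=-0.1, intercept=1.0, fit_r2=1.0)
    assert fit.predict(np.e**2) == pytest.approx(0.8)


# ----------------------------------------------------------- sensitivity index

class _BandMeanModel:
    """Stub ensemble whose prediction reads ink geometry of chosen panels.

    Responds to vertical compression of the targeted band (mean ink row
    position within the band), so shrink perturbations move its prediction
    while untargeted parameters leave it unchanged.
    """

    def __init__(self, params=("T",), scale=1.0):
        self.params = params
        self.scale = scale

    def predict(self, images):
        out = []
        for im in images:
            total = 0.0
            for panel in im.layout:
                if panel["parameter"] not in self.params:
                    continue
                band = im.pixels[panel["row0"] : panel["row1"]]
                ink = (band != 255).any(axis=2)
                rows = np.where(ink)[0]
                total += rows.std() if len(rows) else 0.0
            out.append(self.scale * total)
        return np.asarray(out)


def test_index_normalizes_most_sensitive_to_one(tiny_intervals):
    model = _BandMeanModel(params=("T",))
    res = parameter_sensitivity(model, tiny_intervals[:2], factor_grid=(0.25, 0.5, 1.0))
    assert res.index["T"] == 1.0
    assert res.most_sensitive == "T"
    for p in PARAMETERS:
        if p != "T":
            assert res.cumulative_error[p] == 0.0
            assert res.index[p] == 0.0


def test_index_is_scale_free(tiny_intervals):
    a = parameter_sensitivity(_BandMeanModel(scale=1.0), tiny_intervals[:2],
                              factor_grid=(0.5, 1.0))
    b = parameter_sensitivity(_BandMeanModel(scale=7.5), tiny_intervals[:2],
                              factor_grid=(0.5, 1.0))
    for p in PARAMETERS:
        assert a.index[p] == pytest.approx(b.index[p], abs=1e-12)


def test_offset_perturbations_give_zero_errors(tiny_intervals):
    model = _BandMeanModel(params=PARAMETERS)
    with pytest.warns(UserWarning, match="zero"):
        res = parameter_sensitivity(
            model, tiny_intervals[:2], factor_grid=(0.5, 1.0), perturb_kind="offset"
        )
    assert all(v == 0.0 for v in res.cumulative_error.values())
    assert res.index is None and res.most_sensitive is None


def test_tied_parameters_both_report_one(tiny_intervals):
    # a model reading only pH and T bands with identical geometry response
    # cannot single out one winner; both report 1.0 with a warning when tied
    model = _BandMeanModel(params=("pH",))
    res = parameter_sensitivity(model, tiny_intervals[:2], factor_grid=(1.0,))
    winners = [p for p, v in res.index.items() if v == 1.0]
    assert winners == ["pH"]


def test_default_factor_grid_matches_manipulation_range():
    assert FACTOR_GRID[0] == 0.05 and FACTOR_GRID[-1] == 1.0 and len(FACTOR_GRID) == 20


# ----------------------------------------------------------- interval choice

def test_select_best_predicted_per_hrt(tiny_intervals):
    labels = np.array([iv.productivity for iv in tiny_intervals])
    preds = labels.copy()
    preds[0] += 5.0  # first interval badly predicted
    chosen = select_best_predicted(tiny_intervals, preds, hrt_days=(3,))
    assert len(chosen) == 1
    assert chosen[0] is not tiny_intervals[0]
    with pytest.warns(UserWarning, match="HRT"):
        select_best_predicted(tiny_intervals, preds, hrt_days=(13,))
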