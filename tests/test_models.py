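import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pondcast.imaging import ProfileImageEncoder
from pondcast.models import (
    FEATURE_COLUMNS,
    AverageValueRegressor,
    ProfileImageRegressor,
    SplitSpec,
    build_feature_table,
    evaluate,
    make_split,
    train_avm,
)


# ----------------------------------------------------------------- evaluate

def test_perfect_predictions():
    m = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert (m.r2, m.rmse, m.mae) == (1.0, 0.0, 0.0)


def test_hand_computed_metrics():
    m = evaluate([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
    assert m.r2 == pytest.approx(0.0)
    assert m.rmse == pytest.approx(np.sqrt(2.0 / 3.0))
    assert m.mae == pytest.approx(2.0 / 3.0)


def _direct_metrics(y, p):
    y, p = np.asarray(y), np.asarray(p)
    ss_res = float(sum((a - b) ** 2 for a, b in zip(y, p)))
    ss_tot = float(sum((a - y.mean()) ** 2 for a in y))
    return (
        1 - ss_res / ss_tot,
        (sum((a - b) ** 2 for a, b in zip(y, p)) / len(y)) ** 0.5,
        sum(abs(a - b) for a, b in zip(y, p)) / len(y),
    )


def test_metrics_match_direct_summation_oracle(rng):
    for _ in range(20):
        y = rng.normal(size=30)
        p = y + rng.normal(scale=0.5, size=30)
        m = evaluate(y, p)
        r2, rmse, mae = _direct_metrics(y, p)
        assert m.r2 == pytest.approx(r2, abs=1e-10)
        assert m.rmse == pytest.approx(rmse, abs=1e-10)
        assert m.mae == pytest.approx(mae, abs=1e-10)


@given(st.integers(0, 1000))
def test_rmse_dominates_mae(seed):
    rng = np.random.default_rng(seed)
    y = rng.normal(size=12)
    p = rng.normal(size=12)
    m = evaluate(y, p)
    assert m.rmse >= m.mae >= 0.0


def test_zero_label_variance_rejected():
    with pytest.raises(ValueError, match="variance"):
        evaluate([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


# ----------------------------------------------------------------- splits

def test_split_disjoint_and_deterministic():
    ids = [f"iv{i}" for i in range(50)]
    a = make_split(ids, seed=5)
    b = make_split(ids, seed=5)
    assert a.train_ids == b.train_ids and a.test_ids == b.test_ids
    assert not set(a.train_ids) & set(a.test_ids)
    assert len(a.subsplits) == 5
    for sub, val in a.subsplits:
        assert not set(sub) & set(val)
        assert set(sub) | set(val) == set(a.train_ids)


def test_grouped_split_covers_groups():
    ids = [f"P{p}:iv{i}" for p in range(4) for i in range(10)]
    groups = [i.split(":")[0] for i in ids]
    split = make_split(ids, seed=1, groups=groups)
    test_groups = {i.split(":")[0] for i in split.test_ids}
    assert test_groups == set(groups)


def test_overlapping_split_rejected():
    with pytest.raises(ValueError):
        SplitSpec(train_ids=["a", "b"], test_ids=["b"], seed=0)


# ----------------------------------------------------------------- features

def test_feature_means(tiny_intervals):
    table = build_feature_table(tiny_intervals)
    assert list(table.columns) == ["interval_id", *FEATURE_COLUMNS, "productivity"]
    iv = tiny_intervals[0]
    row = table.iloc[0]
    for p in ("pH", "T", "DO", "TDS", "PAR"):
        assert row[f"mean_{p}"] == pytest.approx(iv.sensor_windows[p].values.mean())


def test_seven_day_window_mean_over_672_records():
    from tests.test_io_pretreat import _density_frame, _full_streams
    from pondcast.io_pretreat import assemble_intervals

    dens = _density_frame(["harvest_cycle", "harvest_cycle"], step_days=7)
    ivs = assemble_intervals(dens, _full_streams())
    table = build_feature_table(ivs)
    assert len(ivs[0].sensor_windows["T"]) == 672
    assert table.iloc[0]["mean_T"] == pytest.approx(ivs[0].sensor_windows["T"].values.mean())


# ----------------------------------------------------------------- AVM

def _linear_table(n=200, seed=0):
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(
        {
            "interval_id": [f"iv{i}" for i in range(n)],
            "mean_pH": rng.normal(8, 0.3, n),
            "mean_T": rng.normal(25, 2, n),
            "mean_DO": rng.normal(7, 1, n),
            "mean_TDS": rng.normal(30, 2, n),
            "mean_PAR": rng.uniform(200, 600, n),
        }
    )
    table["productivity"] = 0.02 * table["mean_PAR"] + 1.0
    return table


def test_avm_recovers_linear_light_rule():
    table = _linear_table()
    ids = table["interval_id"].tolist()
    split = make_split(ids, seed=0)
    _, m_train, m_test = train_avm(table, split, hpo_trials=15, seed=0)
    assert m_test.r2 >= 0.99


def test_avm_rejects_degenerate_labels():
    table = _linear_table()
    table["productivity"] = 5.0
    split = make_split(table["interval_id"].tolist(), seed=0)
    with pytest.raises(ValueError):
        train_avm(table, split, hpo_trials=3, seed=0)


def test_avm_requires_enough_rows():
    table = _linear_table(n=10)
    split = make_split(table["interval_id"].tolist(), seed=0)
    with pytest.raises(ValueError, match="20"):
        train_avm(table, split, hpo_trials=3, seed=0)


# ----------------------------------------------------------------- IBM

def test_unknown_backbone_rejected():
    model = ProfileImageRegressor(backbone="densenet121")
    with pytest.raises(ValueError, match="backbone"):
        model.fit(np.zeros((10, 1, 16, 16), dtype=np.float32), np.arange(10.0))


def test_ensemble_prediction_is_member_mean(tiny_intervals):
    images = ProfileImageEncoder().transform(tiny_intervals)
    labels = np.array([iv.productivity for iv in tiny_intervals])
    model = ProfileImageRegressor(n_members=3, max_epochs=2, patience=2, random_state=0)
    model.fit(images, labels)
    members = model.predict_members(images)
    np.testing.assert_allclose(model.predict(images), members.mean(axis=0), rtol=1e-12)
    assert members.shape[0] == 3


def test_constant_members_predict_constant():
    model = ProfileImageRegressor(n_members=2, max_epochs=1, patience=1, random_state=0)
    x = np.zeros((8, 1, 16, 16), dtype=np.float32)
    y = np.full(8, 3.0)
    y[0] = 3.0001  # avoid exactly-degenerate standardization
    model.fit(x, y)
    # identical inputs -> every member constant -> ensemble equals that constant
    preds = model.predict_members(x)
    for row in preds:
        np.testing.assert_allclose(row, row[0], rtol=1e-9)
    np.testing.assert_allclose(model.predict(x), preds.mean(axis=0), rtol=1e-12)


def test_too_few_subsplits_rejected():
    model = ProfileImageRegressor(n_members=5)
    x = np.zeros((6, 1, 16, 16), dtype=np.float32)
    with pytest.raises(ValueError, match="subsplit"):
        model.fit(x, np.arange(6.0), subsplits=[(np.arange(4), np.array([4, 5]))])
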