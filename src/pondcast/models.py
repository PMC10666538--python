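"""The two model families compared by the method.

* :class:`AverageValueRegressor` (AVM): a gradient-boosted tree regressor on
  per-interval arithmetic means of the five sensor parameters, tuned by
  Bayesian optimization of 5-fold cross-validated RMSE and refitted on the
  full training set.  Averaging makes the model blind by construction to any
  within-interval dynamics.
* :class:`ProfileImageRegressor` (IBM): an ensemble of five small CNNs on the
  spliced profile images.  The training set is split five times into random
  subtraining/validation partitions; each member early-stops on its own
  validation loss, and the ensemble prediction is the member mean.

Both families share the same test set for a given split seed.  Evaluation is
the (R^2, RMSE, MAE) triple throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import KFold

from . import bayesopt
from .cnn import TinyCNN
from .imaging import ProfileImage, images_to_model_input
from .types import PARAMETERS, GrowthInterval, RegressionMetrics

FEATURE_COLUMNS = [f"mean_{p}" for p in PARAMETERS]


# ---------------------------------------------------------------------------
# Features, splits, metrics
# ---------------------------------------------------------------------------

def build_feature_table(
    intervals: list[GrowthInterval], drop_nonpositive: bool = False
) -> pd.DataFrame:
    """One row per interval: arithmetic parameter means + productivity label.

    Means are taken over exactly the records the image encoder would draw.
    Intervals with an empty parameter window are flagged and excluded.
    """
    rows = []
    for iv in intervals:
        if any(p not in iv.sensor_windows for p in PARAMETERS):
            warnings.warn(f"interval {iv.interval_id} missing a stream; excluded", stacklevel=2)
            continue
        if drop_nonpositive and iv.productivity <= 0:
            continue
        row = {"interval_id": iv.interval_id}
        for p in PARAMETERS:
            row[f"mean_{p}"] = float(np.mean(iv.sensor_windows[p].values))
        row["productivity"] = iv.productivity
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SplitSpec:
    """Shared train/test split plus the five subtrain/validation partitions."""

    train_ids: list[str]
    test_ids: list[str]
    seed: int
    subsplits: list[tuple[list[str], list[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")
        for sub, val in self.subsplits:
            if set(sub) & set(val):
                raise ValueError("subtrain and validation ids overlap")


def make_split(
    ids: list[str],
    seed: int,
    test_frac: float = 0.2,
    n_subsplits: int = 5,
    val_frac: float = 0.2,
    groups: list[str] | None = None,
) -> SplitSpec:
    """Random train/test split plus ``n_subsplits`` random subtrain/val splits.

    When ``groups`` (e.g. pond ids) are given, the test fraction is drawn
    within each group so ponds are represented on both sides.  Subsplits are
    independent random partitions of the train ids, not disjoint folds.
    """
    ids = list(ids)
    rng = np.random.default_rng(seed)
    if groups is not None:
        by_group: dict[str, list[str]] = {}
        for i, g in zip(ids, groups):
            by_group.setdefault(g, []).append(i)
        test: list[str] = []
        for g in sorted(by_group):
            members = by_group[g]
            perm = rng.permutation(len(members))
            n_test = max(1, int(round(test_frac * len(members)))) if len(members) > 1 else 0
            test += [members[k] for k in perm[:n_test]]
    else:
        perm = rng.permutation(len(ids))
        n_test = max(1, int(round(test_frac * len(ids))))
        test = [ids[k] for k in perm[:n_test]]
    test_set = set(test)
    train = [i for i in ids if i not in test_set]

    subsplits = []
    for _ in range(n_subsplits):
        perm = rng.permutation(len(train))
        n_val = max(1, int(round(val_frac * len(train))))
        val = [train[k] for k in perm[:n_val]]
        val_set = set(val)
        subsplits.append(([i for i in train if i not in val_set], val))
    return SplitSpec(train_ids=train, test_ids=test, seed=seed, subsplits=subsplits)


def evaluate(y_true, y_pred) -> RegressionMetrics:
    """(R^2, RMSE, MAE) of predictions against labels.

    R^2 = 1 - SS_res/SS_tot; requires at least two samples and non-zero label
    variance.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("labels and predictions must be equal-length 1-D arrays")
    if len(y_true) < 2:
        raise ValueError("need at least two samples")
    if np.var(y_true) == 0:
        raise ValueError("label variance is zero; R^2 undefined")
    return RegressionMetrics(
        r2=float(r2_score(y_true, y_pred)),
        rmse=float(np.sqrt(mean_squared_error(y_true, y_pred))),
        mae=float(mean_absolute_error(y_true, y_pred)),
    )


# ---------------------------------------------------------------------------
# Average-value model (AVM)
# ---------------------------------------------------------------------------

DEFAULT_AVM_SPACE = {
    "learning_rate": bayesopt.Dimension(0.02, 0.3, "log"),
    "num_leaves": bayesopt.Dimension(4, 64, "int"),
    "n_estimators": bayesopt.Dimension(50, 400, "int"),
    "reg_lambda": bayesopt.Dimension(1e-3, 10.0, "log"),
    "min_child_samples": bayesopt.Dimension(3, 20, "int"),
}


class AverageValueRegressor(BaseEstimator, RegressorMixin):
    """Gradient-boosted regressor on interval-mean features with Bayesian HPO.

    Parameters
    ----------
    n_trials : int
        Bayesian-optimization trials (objective: mean 5-fold CV RMSE).
    cv : int
        Cross-validation folds on the training set.
    random_state : int
        Seeds the HPO, CV shuffling and the booster.
    """

    def __init__(self, n_trials: int = 50, cv: int = 5, random_state: int = 0):
        self.n_trials = n_trials
        self.cv = cv
        self.random_state = random_state

    @staticmethod
    def _matrix(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X[FEATURE_COLUMNS].astype(float).reset_index(drop=True)
        return pd.DataFrame(np.asarray(X, dtype=float), columns=FEATURE_COLUMNS)

    def _booster(self, params: dict):
        from lightgbm import LGBMRegressor

        return LGBMRegressor(
            **params, random_state=self.random_state, n_jobs=1, verbose=-1
        )

    def fit(self, X, y):
        Xm = self._matrix(X)
        y = np.asarray(y, dtype=float)
        if len(Xm) < self.cv:
            raise ValueError("too few training rows for cross-validation")
        if np.var(y) == 0:
            raise ValueError("degenerate label variance")

        kf = KFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)
        folds = list(kf.split(Xm))

        def cv_rmse(params: dict) -> float:
            errs = []
            for tr, va in folds:
                model = self._booster(params)
                model.fit(Xm.iloc[tr], y[tr])
                pred = model.predict(Xm.iloc[va])
                errs.append(np.sqrt(np.mean((pred - y[va]) ** 2)))
            return float(np.mean(errs))

        best, history = bayesopt.minimize(
            cv_rmse, DEFAULT_AVM_SPACE, n_trials=self.n_trials, seed=self.random_state
        )
        self.best_params_ = best
        self.cv_history_ = history
        self.model_ = self._booster(best)
        self.model_.fit(Xm, y)
        return self

    def predict(self, X) -> np.ndarray:
        return self.model_.predict(self._matrix(X))


# ---------------------------------------------------------------------------
# Image-based model (IBM)
# ---------------------------------------------------------------------------

class ProfileImageRegressor(BaseEstimator, RegressorMixin):
    """Ensemble of small CNNs on profile images, averaged for prediction.

    The only backbone implemented is ``"tiny-cnn"``, a four-block
    conv/relu/maxpool network trained from scratch (see :mod:`pondcast.cnn`).
    Transfer learning from a pretrained classification backbone is the
    production-scale option this package does not ship weights for;
    requesting it raises.

    Parameters
    ----------
    backbone : str
        ``"tiny-cnn"`` only.
    n_members : int
        Ensemble size; each member trains on its own subtrain/validation split.
    patience : int
        Early-stopping patience (epochs without validation improvement).
    pool : int
        Mean-pooling factor from image pixels to the CNN working resolution.
    """

    def __init__(
        self,
        backbone: str = "tiny-cnn",
        n_members: int = 5,
        patience: int = 8,
        max_epochs: int = 80,
        batch_size: int = 16,
        lr: float = 3e-3,
        pool: int = 4,
        channels: tuple = (8, 16, 32, 64),
        val_frac: float = 0.2,
        random_state: int = 0,
    ):
        self.backbone = backbone
        self.n_members = n_members
        self.patience = patience
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.lr = lr
        self.pool = pool
        self.channels = channels
        self.val_frac = val_frac
        self.random_state = random_state

    def _to_input(self, X) -> np.ndarray:
        if isinstance(X, np.ndarray):
            arr = X.astype(np.float32)
        else:
            arr = images_to_model_input(list(X), pool=self.pool)
        return arr

    def fit(self, X, y, subsplits: list[tuple[np.ndarray, np.ndarray]] | None = None):
        """Train the ensemble.

        ``subsplits``, when given, are index pairs (subtrain, validation) into
        ``X``; otherwise ``n_members`` random partitions are drawn from
        ``random_state``.
        """
        if self.backbone != "tiny-cnn":
            raise ValueError(
                f"backbone {self.backbone!r} unavailable: only the from-scratch "
                "'tiny-cnn' is shipped"
            )
        arr = self._to_input(X)
        y = np.asarray(y, dtype=float)
        n = len(arr)
        if subsplits is None:
            rng = np.random.default_rng(self.random_state)
            subsplits = []
            n_val = max(1, int(round(self.val_frac * n)))
            for _ in range(self.n_members):
                perm = rng.permutation(n)
                subsplits.append((perm[n_val:], perm[:n_val]))
        if len(subsplits) < self.n_members:
            raise ValueError(f"need {self.n_members} subsplits, got {len(subsplits)}")
        for sub, val in subsplits:
            if len(sub) < 2 or len(val) < 1:
                raise ValueError("subsplit too small")

        self.x_mean_ = float(arr.mean())
        self.x_std_ = float(arr.std()) or 1.0
        self.y_mean_ = float(y.mean())
        self.y_std_ = float(y.std()) or 1.0
        xs = (arr - self.x_mean_) / self.x_std_
        ys = (y - self.y_mean_) / self.y_std_

        self.members_ = []
        self.training_log_ = []
        for m, (sub, val) in enumerate(subsplits[: self.n_members]):
            net = TinyCNN(in_channels=arr.shape[1], channels=self.channels,
                          seed=self.random_state * 1000 + m)
            log = net.fit(
                xs[np.asarray(sub)], ys[np.asarray(sub)],
                xs[np.asarray(val)], ys[np.asarray(val)],
                lr=self.lr, batch_size=self.batch_size,
                max_epochs=self.max_epochs, patience=self.patience,
                seed=self.random_state * 1000 + 500 + m,
            )
            self.members_.append(net)
            self.training_log_.append(log)
        return self

    def predict_members(self, X) -> np.ndarray:
        xs = (self._to_input(X) - self.x_mean_) / self.x_std_
        preds = np.stack([net.predict(xs) for net in self.members_])
        return preds * self.y_std_ + self.y_mean_

    def predict(self, X) -> np.ndarray:
        """Arithmetic mean of the member predictions."""
        return self.predict_members(X).mean(axis=0)

    def gradcam(self, image: ProfileImage | np.ndarray, member: int = 0) -> np.ndarray:
        """Grad-CAM heatmap of one image at the image's pixel resolution."""
        arr = self._to_input([image] if isinstance(image, ProfileImage) else image[None])
        xs = (arr - self.x_mean_) / self.x_std_
        cam = self.members_[member].gradcam(xs[0])
        cam = np.kron(cam, np.ones((self.pool, self.pool)))
        if isinstance(image, ProfileImage):
            h, w = image.pixels.shape[:2]
            full = np.zeros((h, w))
            full[: cam.shape[0], : cam.shape[1]] = cam[:h, :w]
            cam = full
        if cam.max() > 0:
            cam = cam / cam.max()
        return cam


def overlay_heatmap(image: ProfileImage, heatmap: np.ndarray, path) -> None:
    """Write a PNG of the profile image blended with a hot-colored heatmap."""
    from PIL import Image

    h = np.clip(heatmap, 0.0, 1.0)
    # simple "hot" ramp: black -> red -> yellow -> white
    r = np.clip(3 * h, 0, 1)
    g = np.clip(3 * h - 1, 0, 1)
    b = np.clip(3 * h - 2, 0, 1)
    heat = (np.stack([r, g, b], axis=-1) * 255).astype(np.uint8)
    blend = (0.5 * image.pixels + 0.5 * heat).astype(np.uint8)
    Image.fromarray(blend).save(path, format="PNG")


# ---------------------------------------------------------------------------
# Thin training wrappers sharing a SplitSpec
# ---------------------------------------------------------------------------

def _index_of(ids: list[str]) -> dict[str, int]:
    return {i: k for k, i in enumerate(ids)}


def train_avm(
    table: pd.DataFrame,
    split: SplitSpec,
    hpo_trials: int = 50,
    seed: int = 0,
) -> tuple[AverageValueRegressor, RegressionMetrics, RegressionMetrics]:
    """Tune/train the AVM on the split's train ids; report train and test metrics."""
    t = table.set_index("interval_id")
    train, test = t.loc[split.train_ids], t.loc[split.test_ids]
    if len(train) < 20:
        raise ValueError("need at least 20 training rows")
    model = AverageValueRegressor(n_trials=hpo_trials, random_state=seed)
    model.fit(train[FEATURE_COLUMNS], train["productivity"].to_numpy())
    m_train = evaluate(train["productivity"], model.predict(train[FEATURE_COLUMNS]))
    m_test = evaluate(test["productivity"], model.predict(test[FEATURE_COLUMNS]))
    return model, m_train, m_test


def train_ibm(
    images: list[ProfileImage],
    labels: np.ndarray,
    split: SplitSpec,
    seed: int = 0,
    **ibm_params,
) -> tuple[ProfileImageRegressor, RegressionMetrics, RegressionMetrics]:
    """Train the CNN ensemble using the split's subtrain/validation partitions."""
    ids = [im.interval_id for im in images]
    pos = _index_of(ids)
    labels = np.asarray(labels, dtype=float)
    arr = images_to_model_input(images, pool=ibm_params.get("pool", 4))

    tr_idx = np.array([pos[i] for i in split.train_ids])
    te_idx = np.array([pos[i] for i in split.test_ids])
    train_pos = {i: k for k, i in enumerate(split.train_ids)}
    subsplits = [
        (
            np.array([train_pos[i] for i in sub]),
            np.array([train_pos[i] for i in val]),
        )
        for sub, val in split.subsplits
    ]
    model = ProfileImageRegressor(random_state=seed, **ibm_params)
    model.fit(arr[tr_idx], labels[tr_idx], subsplits=subsplits or None)
    m_train = evaluate(labels[tr_idx], model.predict(arr[tr_idx]))
    m_test = evaluate(labels[te_idx], model.predict(arr[te_idx]))
    return model, m_train, m_test


def save_metrics(m_train: RegressionMetrics, m_test: RegressionMetrics, path) -> None:
    with open(path, "w") as fh:
        json.dump({"train": m_train.as_dict(), "test": m_test.as_dict()}, fh, indent=1)


def save_ibm(model: ProfileImageRegressor, out_dir, extra: dict | None = None) -> None:
    """Persist the ensemble: member weights (npz) + a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, net in enumerate(model.members_):
        np.savez(out / f"member_{k}.npz", *net.get_weights())
    manifest = {
        "backbone": model.backbone,
        "channels": list(model.channels),
        "pool": model.pool,
        "n_members": model.n_members,
        "x_mean": model.x_mean_,
        "x_std": model.x_std_,
        "y_mean": model.y_mean_,
        "y_std": model.y_std_,
        "training_log": model.training_log_,
    }
    manifest.update(extra or {})
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
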