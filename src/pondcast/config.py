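"""Run configuration and end-to-end pipeline orchestration.

A :class:`RunConfig` (YAML on disk, strictly validated — unknown keys are
rejected) drives :func:`run_pipeline`, which executes the configured stages
in order::

    simulate -> pretreat -> encode -> train_avm -> train_ibm -> compare -> sensitivity

and writes per-stage outputs plus a ``manifest.json`` (config echo, seed,
record counts, stage outcomes) into the run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

log = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "pretreat",
    "encode",
    "train_avm",
    "train_ibm",
    "compare",
    "sensitivity",
)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    volume_l: float = 1025.0
    area_m2: float = 4.2


class SynthSection(_Strict):
    n_ponds: int = 12
    n_days: int = 58
    cadence_minutes: int = 15
    harvest_interval_days: list[int] = [2, 3, 4, 7]


class PretreatSection(_Strict):
    outlier_removal: bool = True
    max_missing_frac: float = 0.10
    season: str | None = None


class EncodingSection(_Strict):
    size: int = 224
    resolution_minutes: int | None = None

    @field_validator("size")
    @classmethod
    def _check_size(cls, v: int) -> int:
        if v not in (224, 336, 448):
            raise ValueError("size must be one of 224, 336, 448")
        return v


class ModelSection(_Strict):
    backbone: str = "tiny-cnn"
    hpo_trials: int = 25
    patience: int = 8
    max_epochs: int = 80
    test_frac: float = 0.2


class SensitivitySection(_Strict):
    perturb_kind: str = "shrink"
    hrt_days: list[int] = [2, 3, 7]


class RunConfig(_Strict):
    """Validated top-level run configuration."""

    out_dir: str = "run"
    seed: int = 0
    stages: list[str] = list(ALL_STAGES)
    geometry: GeometryConfig = GeometryConfig()
    synth: SynthSection = SynthSection()
    pretreat: PretreatSection = PretreatSection()
    encoding: EncodingSection = EncodingSection()
    model: ModelSection = ModelSection()
    sensitivity: SensitivitySection = SensitivitySection()

    @field_validator("stages")
    @classmethod
    def _check_stages(cls, v: list[str]) -> list[str]:
        unknown = [s for s in v if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}")
        return v

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Any stage failure is recorded in the manifest and re-raised after the
    manifest is written.
    """
    from . import io_pretreat, models, sensitivity as sens
    from .imaging import ProfileImageEncoder
    from .synthetic import SynthConfig, generate_dataset
    from .types import PondGeometry, SEASONS

    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.model_dump(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": {},
        "counts": {},
    }
    geometry = PondGeometry(config.geometry.volume_l, config.geometry.area_m2)
    state: dict = {}
    failure: Exception | None = None

    def record(stage: str, fn) -> bool:
        nonlocal failure
        t0 = time.time()
        try:
            fn()
            manifest["stages"][stage] = {"status": "ok", "seconds": round(time.time() - t0, 2)}
            return True
        except Exception as exc:
            manifest["stages"][stage] = {"status": "error", "error": str(exc)}
            failure = exc
            return False

    def stage_simulate():
        synth = SynthConfig(
            n_ponds=config.synth.n_ponds,
            n_days=config.synth.n_days,
            cadence_minutes=config.synth.cadence_minutes,
            harvest_interval_days=tuple(config.synth.harvest_interval_days),
            seed=config.seed,
            geometry=geometry,
        )
        ds = generate_dataset(synth)
        ds.to_csv(run_dir / "data")
        state["dataset"] = ds
        manifest["counts"]["ponds"] = len(ds.ponds)

    def stage_pretreat():
        series, report = io_pretreat.read_sensor_log(run_dir / "data" / "sensors.csv")
        densities = io_pretreat.read_density_log(run_dir / "data" / "densities.csv")
        manifest["counts"]["sensor_rows"] = report.n_rows
        manifest["counts"]["malformed_rows"] = report.n_malformed
        if config.pretreat.season is not None:
            window = {s.name: s for s in SEASONS}[config.pretreat.season]
            series = {
                k: w for k, s in series.items()
                if (w := io_pretreat.select_season(s, window)) is not None
            }
            densities = io_pretreat.select_season(densities, window)
        if config.pretreat.outlier_removal:
            series = {k: io_pretreat.remove_outliers(s) for k, s in series.items()}
        intervals = io_pretreat.assemble_intervals(
            densities, series, geometry, max_missing_frac=config.pretreat.max_missing_frac
        )
        io_pretreat.interval_table(intervals).to_csv(run_dir / "intervals.csv", index=False)
        state["intervals"] = intervals
        manifest["counts"]["intervals"] = len(intervals)

    def stage_encode():
        enc = ProfileImageEncoder(
            size=config.encoding.size,
            resolution_minutes=config.encoding.resolution_minutes,
        )
        images = enc.transform(state["intervals"])
        img_dir = run_dir / "images"
        img_dir.mkdir(exist_ok=True)
        for k, im in enumerate(images):
            im.save(img_dir / f"interval_{k:04d}.png")
        state["images"] = images
        manifest["counts"]["images"] = len(images)

    def _split():
        if "split" not in state:
            table = models.build_feature_table(state["intervals"])
            ids = table["interval_id"].tolist()
            groups = [i.split(":")[0] for i in ids]
            state["table"] = table
            state["split"] = models.make_split(
                ids, seed=config.seed, test_frac=config.model.test_frac, groups=groups
            )
        return state["split"]

    def stage_train_avm():
        split = _split()
        model, m_train, m_test = models.train_avm(
            state["table"], split, hpo_trials=config.model.hpo_trials, seed=config.seed
        )
        models.save_metrics(m_train, m_test, run_dir / "avm_metrics.json")
        state["avm"] = (model, m_train, m_test)

    def stage_train_ibm():
        split = _split()
        images = state.get("images")
        if images is None:
            stage_encode()
            images = state["images"]
        labels = np.array([iv.productivity for iv in state["intervals"]])
        model, m_train, m_test = models.train_ibm(
            images, labels, split, seed=config.seed,
            backbone=config.model.backbone,
            patience=config.model.patience, max_epochs=config.model.max_epochs,
        )
        models.save_metrics(m_train, m_test, run_dir / "ibm_metrics.json")
        models.save_ibm(model, run_dir / "ibm_model", extra={"split_seed": config.seed})
        state["ibm"] = (model, m_train, m_test)

    def stage_compare():
        if "avm" not in state or "ibm" not in state:
            raise RuntimeError("compare requires both train stages")
        _, _, avm_test = state["avm"]
        _, _, ibm_test = state["ibm"]
        out = {
            "r2_improvement_pct": sens.percent_change(avm_test.r2, ibm_test.r2),
            "rmse_improvement_pct": sens.percent_change(
                avm_test.rmse, ibm_test.rmse, lower_is_better=True
            ),
            "mae_improvement_pct": sens.percent_change(
                avm_test.mae, ibm_test.mae, lower_is_better=True
            ),
        }
        with open(run_dir / "comparison.json", "w") as fh:
            json.dump(out, fh, indent=1)

    def stage_sensitivity():
        model = state["ibm"][0]
        intervals = state["intervals"]
        preds = model.predict(ProfileImageEncoder(size=config.encoding.size).transform(intervals))
        chosen = sens.select_best_predicted(
            intervals, preds, hrt_days=tuple(config.sensitivity.hrt_days)
        )
        result = sens.parameter_sensitivity(
            model, chosen, perturb_kind=config.sensitivity.perturb_kind,
            size=config.encoding.size,
        )
        with open(run_dir / "sensitivity.json", "w") as fh:
            json.dump(
                {
                    "cumulative_error": result.cumulative_error,
                    "cumulative_percent_error": result.cumulative_percent_error,
                    "index": result.index,
                },
                fh, indent=1,
            )

    stage_fns = {
        "simulate": stage_simulate,
        "pretreat": stage_pretreat,
        "encode": stage_encode,
        "train_avm": stage_train_avm,
        "train_ibm": stage_train_ibm,
        "compare": stage_compare,
        "sensitivity": stage_sensitivity,
    }
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        if not record(stage, stage_fns[stage]):
            break

    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=_json_default)
    if failure is not None:
        raise failure
    return run_dir


def _json_default(obj):
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)
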