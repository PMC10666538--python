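"""Desk-scale benchmark study: AVM vs IBM on the heat-excursion scenario.

One study seed generates a ~200-interval synthetic campaign, trains the
average-value baseline and the image-based ensemble on a shared split,
retrains the ensemble at a 240 min monitoring cadence, and (optionally) runs
the perturbation sensitivity analysis on the trained ensemble.  Used by the
comparison workflow and by the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .imaging import ProfileImageEncoder, render_interval_image
from .io_pretreat import assemble_intervals
from .models import build_feature_table, make_split, train_avm, train_ibm
from .sensitivity import parameter_sensitivity, select_best_predicted
from .synthetic import excursion_scenario, generate_dataset, generate_matched_pair


def run_study_seed(
    seed: int,
    hpo_trials: int = 25,
    coarse_minutes: int = 240,
    with_sensitivity: bool = False,
) -> dict:
    """Run the full desk-scale comparison for one seed.

    Returns a dict with interval counts and test metrics for the AVM, the
    base-cadence IBM and the coarse-cadence IBM, plus (optionally) the
    perturbation sensitivity indices of the trained base-cadence ensemble.
    """
    dataset = generate_dataset(excursion_scenario(seed))
    intervals = assemble_intervals(dataset.densities(), dataset.sensor_series())
    table = build_feature_table(intervals)
    ids = table["interval_id"].tolist()
    split = make_split(ids, seed=seed, groups=[i.split(":")[0] for i in ids])
    labels = np.array([iv.productivity for iv in intervals])

    _, avm_train, avm_test = train_avm(table, split, hpo_trials=hpo_trials, seed=seed)

    images = ProfileImageEncoder(size=224).transform(intervals)
    ibm, ibm_train, ibm_test = train_ibm(images, labels, split, seed=seed)

    coarse = ProfileImageEncoder(size=224, resolution_minutes=coarse_minutes).transform(intervals)
    _, coarse_train, coarse_test = train_ibm(coarse, labels, split, seed=seed)

    out = {
        "seed": seed,
        "n_intervals": len(intervals),
        "n_train": len(split.train_ids),
        "n_test": len(split.test_ids),
        "avm_test": avm_test.as_dict(),
        "avm_train": avm_train.as_dict(),
        "ibm_test": ibm_test.as_dict(),
        "ibm_train": ibm_train.as_dict(),
        "ibm_coarse_test": coarse_test.as_dict(),
    }
    if with_sensitivity:
        preds = ibm.predict(images)
        chosen = select_best_predicted(intervals, preds, hrt_days=(2, 3, 7))
        result = parameter_sensitivity(ibm, chosen)
        out["sensitivity_index"] = result.index
    return out


def matched_pair_check(seed: int = 0) -> dict:
    """Structural discriminability check on a mean-matched pond pair.

    Returns the maximum absolute tabular-feature gap, the number of differing
    image pixels, and the ground-truth label gap between the two ponds.
    """
    lo, hi = generate_matched_pair(seed=seed)
    ivs = []
    for pond in (lo, hi):
        series = {(pond.pond_id, p): s for p, s in pond.series.items()}
        ivs += assemble_intervals(pond.densities, series)
    table = build_feature_table(ivs)
    feats = table[[c for c in table.columns if c.startswith("mean_")]].to_numpy()
    images = [render_interval_image(iv) for iv in ivs[:2]]
    return {
        "feature_max_gap": float(np.max(np.abs(feats[0] - feats[1]))),
        "image_pixel_diff": int((images[0].pixels != images[1].pixels).sum()),
        "label_gap": float(abs(ivs[0].productivity - ivs[1].productivity)),
    }
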