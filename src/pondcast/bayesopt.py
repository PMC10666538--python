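"""Seeded Bayesian optimization (Gaussian process + expected improvement).

A compact sequential optimizer for low-dimensional hyperparameter searches:
parameters are mapped to the unit cube (log-scaled where requested), a
Matern-5/2 GP with a white-noise term is fitted to observed objective values,
and the next trial maximizes expected improvement over a random candidate
set.  Deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel


@dataclass(frozen=True)
class Dimension:
    """One search dimension: bounds plus scale/type."""

    low: float
    high: float
    kind: str = "float"  # float | log | int

    def to_unit(self, x: float) -> float:
        if self.kind == "log":
            return (np.log(x) - np.log(self.low)) / (np.log(self.high) - np.log(self.low))
        return (x - self.low) / (self.high - self.low)

    def from_unit(self, u: float):
        u = float(np.clip(u, 0.0, 1.0))
        if self.kind == "log":
            val = float(np.exp(np.log(self.low) + u * (np.log(self.high) - np.log(self.low))))
        else:
            val = self.low + u * (self.high - self.low)
        if self.kind == "int":
            return int(round(val))
        return val


def minimize(
    objective,
    space: dict[str, Dimension],
    n_trials: int = 50,
    seed: int = 0,
    n_init: int = 8,
    n_candidates: int = 256,
) -> tuple[dict, list[tuple[dict, float]]]:
    """Minimize ``objective(params_dict)`` over ``space``.

    Returns ``(best_params, history)`` where history lists every
    ``(params, value)`` trial in order.
    """
    rng = np.random.default_rng(seed)
    names = list(space)
    dims = [space[k] for k in names]
    n_init = min(n_init, n_trials)

    def decode(u: np.ndarray) -> dict:
        return {k: d.from_unit(v) for k, d, v in zip(names, dims, u)}

    xs: list[np.ndarray] = []
    ys: list[float] = []
    history: list[tuple[dict, float]] = []

    for t in range(n_trials):
        if t < n_init:
            u = rng.random(len(dims))
        else:
            gp = GaussianProcessRegressor(
                kernel=ConstantKernel(1.0) * Matern(nu=2.5, length_scale=0.3)
                + WhiteKernel(1e-4),
                normalize_y=True,
                random_state=0,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(np.array(xs), np.array(ys))
            cand = rng.random((n_candidates, len(dims)))
            # densify around the incumbent
            best = xs[int(np.argmin(ys))]
            local = np.clip(best + rng.normal(0, 0.1, (n_candidates // 4, len(dims))), 0, 1)
            cand = np.vstack([cand, local])
            mu, sd = gp.predict(cand, return_std=True)
            sd = np.maximum(sd, 1e-12)
            y_best = min(ys)
            z = (y_best - mu) / sd
            ei = (y_best - mu) * norm.cdf(z) + sd * norm.pdf(z)
            u = cand[int(np.argmax(ei))]
        params = decode(u)
        val = float(objective(params))
        xs.append(u)
        ys.append(val)
        history.append((params, val))

    return history[int(np.argmin(ys))][0], history
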