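"""Regression metrics and desk-scale experiment harnesses.

``compute_metrics`` implements the three evaluation criteria — MAE, RMSE and
the coefficient of determination R² — on whichever target scale the caller
supplies (normalized by default, since the published error magnitudes are
unitless and ≪ 1; fraction/percent scales via flags elsewhere).

``run_comparison`` mirrors the three-model comparison design: a dataset is
repeatedly partitioned 2:6:2 into initialization/training/testing sets, each
model is initialized on the first part, online models stream the second in
chunks, and all are scored on the third; repeats vary the partition shuffle
and the random hidden weights. ``distance_sweep`` mirrors the robustness
experiment: regenerate test sets at fixed reader distances and report the
RMSE per distance (the synthetic noise model degrades SNR with range, so
accuracy falls off with distance).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .adapt import AdaptationConfig
from .exceptions import ConfigurationError, DomainError
from .network import NetworkConfig
from .pipeline import TrainedModel, predict_mc_normalized, train_model
from .preprocessing import partition_dataset
from .rf import (
    AttenuationModel,
    DriftSpec,
    RFLinkParams,
    ScenarioRanges,
    generate_dataset,
)
from .rf import Sample

__all__ = ["MetricReport", "compute_metrics", "run_comparison", "distance_sweep"]


@dataclass
class MetricReport:
    """MAE, RMSE and R² over one prediction/truth pairing.

    ``r_squared`` is ``None`` when the truths have zero variance (R² is then
    undefined); it can be negative for fits worse than the mean predictor.
    """

    mae: float
    rmse: float
    r_squared: float | None
    n: int
    scale: str = "normalized"


def compute_metrics(predictions: np.ndarray, truths: np.ndarray, scale: str = "normalized") -> MetricReport:
    """MAE = mean |ŷ−y|, RMSE = sqrt(mean (ŷ−y)²), R² = 1 − SS_res/SS_tot."""
    pred = np.asarray(predictions, float).reshape(-1)
    true = np.asarray(truths, float).reshape(-1)
    if pred.shape != true.shape or pred.size == 0:
        raise DomainError("predictions and truths must have equal non-zero lengths")
    resid = pred - true
    mae = float(np.mean(np.abs(resid)))
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((true - true.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("zero-variance truths: R^2 undefined", stacklevel=2)
        r2 = None
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return MetricReport(mae=mae, rmse=rmse, r_squared=r2, n=pred.size, scale=scale)


def run_comparison(
    samples: Sequence[Sample],
    model_kinds: Sequence[str] = ("elm", "oselm", "ospelm"),
    n_repeats: int = 25,
    base_seed: int = 0,
    ratio: Sequence[float] = (2, 6, 2),
    chunk_size: int = 40,
    network_config: NetworkConfig | None = None,
    adapt_config: AdaptationConfig | None = AdaptationConfig(),
    elm_hidden: int = 64,
) -> pd.DataFrame:
    """Score each model kind over repeated random 2:6:2 partitions.

    Returns one row per (model, repeat) with MAE/RMSE/R² on the normalized
    target scale plus the wall-clock training time. Fixed ``base_seed`` makes
    the whole table reproducible.
    """
    if n_repeats < 1:
        raise ConfigurationError("n_repeats must be >= 1")
    rows = []
    for rep in range(n_repeats):
        ss = np.random.SeedSequence([base_seed, rep])
        part_rng, weight_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
        init_set, train_set, test_set = partition_dataset(samples, ratio, part_rng)
        for kind in model_kinds:
            t0 = time.perf_counter()
            model = train_model(
                init_set,
                train_set,
                kind=kind,
                network_config=network_config,
                adapt_config=adapt_config if kind == "ospelm" else None,
                elm_hidden=elm_hidden,
                chunk_size=chunk_size,
                rng_seed=np.random.default_rng(weight_rng.integers(2**31)),
            )
            runtime = time.perf_counter() - t0
            pred, true = predict_mc_normalized(model, test_set)
            rep_metrics = compute_metrics(pred, true)
            rows.append(
                {
                    "model": kind,
                    "repeat": rep,
                    "mae": rep_metrics.mae,
                    "rmse": rep_metrics.rmse,
                    "r_squared": rep_metrics.r_squared,
                    "runtime_s": runtime,
                    "n_test": rep_metrics.n,
                }
            )
    return pd.DataFrame(rows)


def distance_sweep(
    distances: Sequence[float],
    model: TrainedModel,
    params: RFLinkParams | None = None,
    attenuation: AttenuationModel | None = None,
    scenario_ranges: ScenarioRanges | None = None,
    n_per_distance: int = 300,
    rng_seed: int | np.random.Generator | None = None,
    n_reads: int = 100,
    noise_halfwidth: float = 1.0,
) -> pd.DataFrame:
    """RMSE of a trained model on fresh test sets at each fixed reader distance.

    Scenario draws vary MC/DBH/humidity as usual but pin the distance to each
    grid value in turn (degenerate range). Returns a distance → MAE/RMSE table
    on the normalized target scale.
    """
    if len(distances) == 0:
        raise ConfigurationError("need at least one distance")
    ranges = scenario_ranges if scenario_ranges is not None else ScenarioRanges()
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    rows = []
    for d in distances:
        test = generate_dataset(
            n_per_distance,
            scenario_ranges=ScenarioRanges(
                mc=ranges.mc, distance=(float(d), float(d)),
                humidity=ranges.humidity, dbh=ranges.dbh,
            ),
            drift_spec=DriftSpec.none(),
            params=params,
            model=attenuation,
            rng_seed=rng,
            n_reads=n_reads,
            noise_halfwidth=noise_halfwidth,
        )
        pred, true = predict_mc_normalized(model, test)
        m = compute_metrics(pred, true)
        rows.append({"distance_m": float(d), "mae": m.mae, "rmse": m.rmse, "n": m.n})
    return pd.DataFrame(rows)
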