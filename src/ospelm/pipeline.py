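"""High-level train/predict pipelines tying normalization, networks and streaming.

A :class:`TrainedModel` bundles a fitted network with the normalization states
of its initialization period, so raw-unit samples can be fed in and MC
predictions come back out on the fraction scale. Three kinds are supported:

``ospelm``
    Parallel network initialized in batch on the init set, then streamed
    through the training set in chunks with RLS updates and (optionally)
    contribution-driven split/merge adaptation.
``oselm``
    64-node single-layer ELM initialized on the init set and streamed through
    the training chunks (no structural adaptation, no parallel grouping).
``elm``
    The same single-layer network fitted in batch on the init set only; it
    never sees the stream (it lacks the online updating stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import baselines
from .adapt import AdaptationConfig, adapt_step
from .baselines import ELMState
from .exceptions import ConfigurationError, DomainError
from .network import NetworkConfig, OSPELMState, init_batch, predict as net_predict
from .online import os_update_forgetting
from .preprocessing import (
    FEATURE_NAMES,
    TARGET_NAME,
    NormalizationState,
    feature_target_arrays,
    fit_minmax,
    normalize,
    denormalize,
)
from .rf import Sample

__all__ = ["TrainedModel", "train_model", "predict_mc", "chunk_iter"]

MODEL_KINDS = ("ospelm", "oselm", "elm")


@dataclass
class TrainedModel:
    """A fitted model plus the scalers needed to apply it to raw samples."""

    kind: str
    state: OSPELMState | ELMState
    feature_norm: NormalizationState
    target_norm: NormalizationState
    chunk_size: int = 40
    mu: float = 1.0
    adaptation: AdaptationConfig | None = None
    adaptation_log: list[dict] = field(default_factory=list)


def chunk_iter(X: np.ndarray, Y: np.ndarray, chunk_size: int):
    """Yield consecutive (X, Y) chunks; the last one may be shorter."""
    if chunk_size < 1:
        raise ConfigurationError("chunk_size must be >= 1")
    for start in range(0, X.shape[0], chunk_size):
        yield X[start : start + chunk_size], Y[start : start + chunk_size]


def _norms_from(X_init: np.ndarray, y_init: np.ndarray):
    feature_norm = fit_minmax(X_init, FEATURE_NAMES)
    target_norm = fit_minmax(y_init[:, None], (TARGET_NAME,))
    return feature_norm, target_norm


def train_model(
    init_samples: Sequence[Sample],
    train_samples: Sequence[Sample],
    kind: str = "ospelm",
    network_config: NetworkConfig | None = None,
    adapt_config: AdaptationConfig | None = None,
    elm_hidden: int = 64,
    elm_activation: str = "relu",
    chunk_size: int = 40,
    mu: float = 1.0,
    rng_seed: int | np.random.Generator | None = None,
    f_window: int | None = None,
) -> TrainedModel:
    """Train one model of the given kind on raw-unit samples.

    Normalization (features and target) is fitted on the initialization set
    and kept fixed through the stream. ``adapt_config=None`` with
    ``kind='ospelm'`` streams with plain RLS updates and no structural change.
    ``f_window`` is the number of most recent samples retained for recomputing
    the RLS matrix (and re-solving the output weights) after a structural
    change; ``None`` retains the full history seen so far, consistent with the
    equal data weighting of the no-forgetting recursion. A bounded window is
    the drift-tracking choice to pair with ``mu < 1``.
    """
    if kind not in MODEL_KINDS:
        raise ConfigurationError(f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")
    X_init_raw, y_init = feature_target_arrays(init_samples)
    if np.isnan(X_init_raw).any():
        raise DomainError("initialization samples contain missing features")
    feature_norm, target_norm = _norms_from(X_init_raw, y_init)
    X0 = normalize(feature_norm, X_init_raw)
    Y0 = normalize(target_norm, y_init[:, None])

    stream = len(train_samples) > 0 and kind in ("ospelm", "oselm")
    if stream:
        X_tr_raw, y_tr = feature_target_arrays(train_samples)
        if np.isnan(X_tr_raw).any():
            raise DomainError("training samples contain missing features")
        Xs = normalize(feature_norm, X_tr_raw)
        Ys = normalize(target_norm, y_tr[:, None])

    log: list[dict] = []
    if kind == "ospelm":
        state = init_batch(X0, Y0, network_config, rng_seed)
        if stream:
            keep = slice(None) if f_window is None else slice(-f_window, None)
            win_X, win_Y = X0[keep], Y0[keep]
            for Xk, Yk in chunk_iter(Xs, Ys, chunk_size):
                if adapt_config is not None:
                    win_X = np.vstack([win_X, Xk])[keep]
                    win_Y = np.vstack([win_Y, Yk])[keep]
                    state, rec = adapt_step(state, Xk, Yk, adapt_config,
                                            window_X=win_X, window_Y=win_Y)
                    log.append(rec)
                else:
                    state = os_update_forgetting(state, Xk, Yk, mu)
    else:
        state = baselines.elm_fit(X0, Y0, elm_hidden, elm_activation, rng_seed)
        if stream:  # oselm only; plain elm never streams
            for Xk, Yk in chunk_iter(Xs, Ys, chunk_size):
                state = baselines.oselm_update(state, Xk, Yk, mu)

    return TrainedModel(
        kind=kind,
        state=state,
        feature_norm=feature_norm,
        target_norm=target_norm,
        chunk_size=chunk_size,
        mu=mu,
        adaptation=adapt_config,
        adaptation_log=log,
    )


def predict_mc(model: TrainedModel, samples: Sequence[Sample]) -> np.ndarray:
    """Predict MC (fraction scale) for raw-unit samples."""
    X_raw, _ = feature_target_arrays(samples)
    if np.isnan(X_raw).any():
        raise DomainError("samples contain missing features")
    Xn = normalize(model.feature_norm, X_raw)
    if model.kind == "ospelm":
        yn = net_predict(model.state, Xn)
    else:
        yn = baselines.elm_predict(model.state, Xn)
    return denormalize(model.target_norm, yn)[:, 0]


def predict_mc_normalized(model: TrainedModel, samples: Sequence[Sample]) -> tuple[np.ndarray, np.ndarray]:
    """Predictions and truths on the normalized target scale (for metrics)."""
    X_raw, y = feature_target_arrays(samples)
    if np.isnan(X_raw).any():
        raise DomainError("samples contain missing features")
    Xn = normalize(model.feature_norm, X_raw)
    if model.kind == "ospelm":
        yn = net_predict(model.state, Xn)
    else:
        yn = baselines.elm_predict(model.state, Xn)
    y_true_n = normalize(model.target_norm, y[:, None])
    return yn[:, 0], y_true_n[:, 0]
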