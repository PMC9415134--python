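"""Contribution-driven structural adaptation: neuron splitting and merging.

During online learning each hidden neuron's *contribution degree* — its share
``beta_i · lambda_i / (y' + y'' + y''')`` of the summed stream output, averaged
in absolute value over the current chunk — is compared against two thresholds.
A neuron above ``C_Hth`` (a multiple of the mean degree, default 2×) is split
into two children that keep the parent's input weights and divide its bias and
output weight by the variation factor Ω and 1−Ω; a neuron below ``C_Lth``
(``min{0.05, 1/(Z1+Z2)}``) is merged into its most similar same-layer
neighbour so the survivor inherits the deleted neuron's contribution at the
operating point. After any structural change the RLS matrix ``F`` no longer
has the right dimensions and is recomputed from the current chunk with a small
ridge.

Adaptation is defined for scalar-output networks (``o = 1``), which is the MC
regression case.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ConfigurationError, DomainError
from .network import OSPELMState, design_matrix, hidden_outputs
from .online import os_update

__all__ = [
    "AdaptationConfig",
    "ContributionReport",
    "contribution_degrees",
    "compute_thresholds",
    "split_neuron",
    "merge_neurons",
    "resize_F",
    "adapt_step",
]

logger = logging.getLogger(__name__)

_LAMBDA_TOL = 1e-12


@dataclass(frozen=True)
class AdaptationConfig:
    """Thresholds and caps for the split/merge rules.

    ``omega_factor`` (Ω) divides a split neuron's bias and output weight
    between its children; the default 0.3 is deliberately asymmetric — Ω = 0.5
    would create two identical children and a rank-deficient design.
    ``c_hth_multiplier`` scales the mean contribution degree into the split
    threshold; ``c_lth_floor`` caps the merge threshold ``min{floor, 1/(Z1+Z2)}``.
    At most one split and one merge fire per step by default, keeping the
    F-recomputation cost bounded and the behaviour reproducible.
    """

    omega_factor: float = 0.3
    c_hth_multiplier: float = 2.0
    c_lth_floor: float = 0.05
    max_neurons_per_layer: int = 60
    min_neurons_per_layer: int = 2
    max_splits_per_step: int = 1
    max_merges_per_step: int = 1
    resize_eps: float = 1e-6

    def __post_init__(self) -> None:
        if not (0 < self.omega_factor < 1):
            raise ConfigurationError(f"omega_factor must be in (0, 1), got {self.omega_factor}")
        if self.min_neurons_per_layer < 1:
            raise ConfigurationError("min_neurons_per_layer must be >= 1")
        if self.max_neurons_per_layer < self.min_neurons_per_layer:
            raise ConfigurationError("max_neurons_per_layer < min_neurons_per_layer")
        if self.max_splits_per_step < 0 or self.max_merges_per_step < 0:
            raise ConfigurationError("per-step caps must be >= 0")
        if self.c_hth_multiplier <= 0 or self.c_lth_floor <= 0:
            raise ConfigurationError("threshold rules must be positive")


@dataclass
class ContributionReport:
    """Per-neuron contribution degrees and mean activations over a chunk.

    ``layer1``/``layer2`` hold the mean absolute per-sample contribution
    degrees; ``layer1_signed``/``layer2_signed`` the mean *signed* degrees
    (whose per-layer sums equal the layer's mean stream share);
    ``lambda1``/``lambda2`` the mean absolute post-activation neuron outputs
    (used by the merge rule); ``stream_shares`` the mean signed share of each
    of the three streams in the total output. Samples whose stream sum is
    numerically zero are excluded from the averages.
    """

    layer1: np.ndarray
    layer2: np.ndarray
    layer1_signed: np.ndarray
    layer2_signed: np.ndarray
    lambda1: np.ndarray
    lambda2: np.ndarray
    stream_shares: np.ndarray
    n_samples: int
    n_excluded: int


def contribution_degrees(state: OSPELMState, chunk_X: np.ndarray) -> ContributionReport:
    """Compute each hidden neuron's contribution degree over a chunk.

    Per sample, neuron ``i`` of layer 1 contributes ``beta1_i·H_i / s`` with
    ``s = y' + y'' + y'''`` the summed stream output; layer-2 neurons
    analogously with ``beta2_j·G_j / s`` (referencing their own stream).
    The report stores the mean of absolute per-sample contributions, so
    consistently active neurons are not hidden by sign cancellation.
    """
    if state.o != 1:
        raise ConfigurationError("contribution degrees are defined for scalar-output networks")
    X = np.atleast_2d(np.asarray(chunk_X, float))
    if X.shape[0] == 0:
        raise DomainError("chunk must be non-empty")
    H, G = hidden_outputs(state, X)
    y1 = H @ state.beta1[:, 0]
    y2 = G @ state.beta2[:, 0]
    y3 = X @ state.omega[:, 0]
    s = y1 + y2 + y3
    keep = np.abs(s) > _LAMBDA_TOL
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.warning("contribution_degrees: excluded %d sample(s) with ~zero stream sum", n_excluded)
    if not keep.any():
        raise DomainError("all samples in the chunk have a numerically zero stream sum")
    Hk, Gk, Xk, sk = H[keep], G[keep], X[keep], s[keep]
    c1_signed = Hk * state.beta1[:, 0][None, :] / sk[:, None]
    c2_signed = Gk * state.beta2[:, 0][None, :] / sk[:, None]
    c1 = np.abs(c1_signed).mean(axis=0)
    c2 = np.abs(c2_signed).mean(axis=0)
    shares = np.stack([y1[keep] / sk, y2[keep] / sk, y3[keep] / sk]).mean(axis=1)
    return ContributionReport(
        layer1=c1,
        layer2=c2,
        layer1_signed=c1_signed.mean(axis=0),
        layer2_signed=c2_signed.mean(axis=0),
        lambda1=np.abs(Hk).mean(axis=0),
        lambda2=np.abs(Gk).mean(axis=0),
        stream_shares=shares,
        n_samples=int(keep.sum()),
        n_excluded=n_excluded,
    )


def compute_thresholds(
    report: ContributionReport,
    z1: int,
    z2: int,
    config: AdaptationConfig | None = None,
) -> tuple[float, float]:
    """Split/merge thresholds: ``C_Hth = mult × mean degree``, ``C_Lth = min{floor, 1/(Z1+Z2)}``."""
    config = config if config is not None else AdaptationConfig()
    all_degrees = np.concatenate([report.layer1, report.layer2])
    c_hth = config.c_hth_multiplier * float(all_degrees.mean())
    c_lth = min(config.c_lth_floor, 1.0 / (z1 + z2))
    return c_hth, c_lth


def _layer_arrays(state: OSPELMState, layer: int):
    if layer == 1:
        return state.rho, state.b1, state.beta1
    if layer == 2:
        return state.phi, state.b2, state.beta2
    raise ConfigurationError(f"layer must be 1 or 2, got {layer}")


def _with_layer(state: OSPELMState, layer: int, W, b, beta) -> OSPELMState:
    if layer == 1:
        return replace(state, rho=W, b1=b, beta1=beta, F=None)
    return replace(state, phi=W, b2=b, beta2=beta, F=None)


def split_neuron(state: OSPELMState, layer: int, index: int, config: AdaptationConfig) -> OSPELMState:
    """Replace one neuron by two children (input weights kept, bias and output
    weight divided Ω / 1−Ω). Skipped (with a log entry) at the layer-size cap.

    The returned state has ``F = None``; recompute it with :func:`resize_F`
    before the next online update.
    """
    W, b, beta = _layer_arrays(state, layer)
    if not (0 <= index < W.shape[0]):
        raise DomainError(f"no neuron {index} in layer {layer}")
    if W.shape[0] >= config.max_neurons_per_layer:
        logger.info("split skipped: layer %d at max size %d", layer, config.max_neurons_per_layer)
        return state
    om = config.omega_factor
    W_new = np.insert(W, index + 1, W[index], axis=0)
    b_new = np.insert(b, index + 1, (1.0 - om) * b[index])
    b_new[index] = om * b[index]
    beta_new = np.insert(beta, index + 1, (1.0 - om) * beta[index], axis=0)
    beta_new[index] = om * beta[index]
    return _with_layer(state, layer, W_new, b_new, beta_new)


def merge_neurons(
    state: OSPELMState,
    layer: int,
    keep_index: int,
    delete_index: int,
    report: ContributionReport,
) -> OSPELMState:
    """Remove ``delete_index`` and fold its contribution into ``keep_index``.

    The survivor's output weight becomes ``beta_keep + beta_del·(λ_del/λ_keep)``
    with λ the chunk-mean absolute activations from ``report``, so the combined
    output at the operating point is conserved. Skipped when the survivor's λ
    is numerically zero. Returned state has ``F = None``.
    """
    W, b, beta = _layer_arrays(state, layer)
    z = W.shape[0]
    if keep_index == delete_index:
        raise DomainError("keep and delete neurons must be distinct")
    for idx in (keep_index, delete_index):
        if not (0 <= idx < z):
            raise DomainError(f"no neuron {idx} in layer {layer}")
    lam = report.lambda1 if layer == 1 else report.lambda2
    if lam.shape[0] != z:
        raise DomainError("report does not match the layer's current size")
    if abs(lam[keep_index]) < _LAMBDA_TOL:
        logger.info("merge skipped: surviving neuron %d has ~zero mean activation", keep_index)
        return state
    beta_new = beta.copy()
    beta_new[keep_index] = beta[keep_index] + beta[delete_index] * (lam[delete_index] / lam[keep_index])
    W_new = np.delete(W, delete_index, axis=0)
    b_new = np.delete(b, delete_index)
    beta_new = np.delete(beta_new, delete_index, axis=0)
    return _with_layer(state, layer, W_new, b_new, beta_new)


def resize_F(state: OSPELMState, window_X: np.ndarray, epsilon: float = 1e-6) -> OSPELMState:
    """Recompute ``F = (A_wᵀA_w + ε'I)⁻¹`` on a retained sample window.

    Used after a structural change, when the old ``F`` no longer matches the
    design-matrix dimensions. The ridge is applied relative to the Gram's own
    scale, ``ε' = ε · trace(A_wᵀA_w)/P``: the design is near-singular whenever
    hidden units are affine over the data region, and an absolute ridge lets
    the near-null directions overfit the window. ε > 0 guarantees a symmetric
    positive definite result even on short windows.
    """
    X = np.atleast_2d(np.asarray(window_X, float))
    if X.shape[0] == 0:
        raise DomainError("window must be non-empty")
    A = design_matrix(state, X)
    M = A.T @ A
    scale = np.trace(M) / M.shape[0]
    M += epsilon * (scale if scale > 0 else 1.0) * np.eye(A.shape[1])
    F = np.linalg.inv(M)
    return replace(state, F=0.5 * (F + F.T))


def _nearest_neighbour(W: np.ndarray, index: int) -> int:
    """Same-layer neuron with the highest cosine similarity of input weights."""
    v = W[index]
    norms = np.linalg.norm(W, axis=1) * max(np.linalg.norm(v), _LAMBDA_TOL)
    sims = W @ v / np.maximum(norms, _LAMBDA_TOL)
    sims[index] = -np.inf
    return int(np.argmax(sims))  # argmax takes the lowest index on ties


def adapt_step(
    state: OSPELMState,
    Xk1: np.ndarray,
    Yk1: np.ndarray,
    config: AdaptationConfig | None = None,
    window_X: np.ndarray | None = None,
    window_Y: np.ndarray | None = None,
) -> tuple[OSPELMState, dict]:
    """One full online step: RLS update, then at most one split and one merge.

    The single highest-contributing neuron above ``C_Hth`` is split and the
    single lowest below ``C_Lth`` is merged into its most similar same-layer
    neighbour, subject to the config caps. After a structural change ``F`` is
    recomputed on the retained sample window (``window_X``, defaulting to the
    current chunk — pass a longer recent-history window so the change does
    not discard the accumulated information), and, when ``window_Y`` is
    supplied, the output weights are re-solved on that window by the same
    ridge least-squares used at initialization: the split/merge weight rules
    deliberately redistribute a neuron's role between survivors, which
    perturbs the network function, and the re-solve absorbs that perturbation
    immediately instead of leaking it into the next predictions.
    Deterministic given state, chunk, and config. Returns the new state and a
    JSON-serializable log record of the step.
    """
    config = config if config is not None else AdaptationConfig()
    state = os_update(state, Xk1, Yk1)
    log: dict = {"z1": state.z1, "z2": state.z2, "actions": []}
    if config.max_splits_per_step == 0 and config.max_merges_per_step == 0:
        return state, log

    report = contribution_degrees(state, Xk1)
    c_hth, c_lth = compute_thresholds(report, state.z1, state.z2, config)
    log.update(
        c_hth=c_hth,
        c_lth=c_lth,
        mean_degree=float(np.concatenate([report.layer1, report.layer2]).mean()),
        n_excluded=report.n_excluded,
    )
    changed = False

    # split the single most extreme neuron above the high threshold
    degrees = np.concatenate([report.layer1, report.layer2])
    top = int(np.argmax(degrees))
    if config.max_splits_per_step >= 1 and degrees[top] > c_hth:
        layer, idx = (1, top) if top < state.z1 else (2, top - state.z1)
        before = (state.z1, state.z2)
        state = split_neuron(state, layer, idx, config)
        if (state.z1, state.z2) != before:
            changed = True
            log["actions"].append({"action": "split", "layer": layer, "index": idx,
                                   "degree": float(degrees[top])})

    # merge the single least-contributing neuron below the low threshold;
    # degrees/report still refer to the pre-split indexing, so recompute if split fired
    rep_m = contribution_degrees(state, Xk1) if changed else report
    degrees_m = np.concatenate([rep_m.layer1, rep_m.layer2])
    low = int(np.argmin(degrees_m))
    if config.max_merges_per_step >= 1 and degrees_m[low] < c_lth:
        layer, idx = (1, low) if low < state.z1 else (2, low - state.z1)
        W = state.rho if layer == 1 else state.phi
        if W.shape[0] > config.min_neurons_per_layer:
            keep = _nearest_neighbour(W, idx)
            before = (state.z1, state.z2)
            state = merge_neurons(state, layer, keep, idx, rep_m)
            if (state.z1, state.z2) != before:
                changed = True
                log["actions"].append({"action": "merge", "layer": layer, "deleted": idx,
                                       "kept": keep, "degree": float(degrees_m[low])})

    if changed:
        Xw = Xk1 if window_X is None else window_X
        state = resize_F(state, Xw, config.resize_eps)
        if window_Y is not None:
            A_w = design_matrix(state, np.atleast_2d(np.asarray(Xw, float)))
            Yw = np.asarray(window_Y, float)
            if Yw.ndim == 1:
                Yw = Yw[:, None]
            state = state.with_stacked_beta(state.F @ (A_w.T @ Yw))
    log["z1"], log["z2"] = state.z1, state.z2
    return state, log
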