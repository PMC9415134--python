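"""Single-hidden-layer ELM and OS-ELM ablation baselines.

These are the two condensed comparison models: plain ELM (batch least squares
on random hidden features, no online updating, no parallel structure) and
OS-ELM (the same network with chunk-wise RLS updates). Both consume the full
unsplit 5-feature vector — the feature grouping is the parallel model's
novelty — and default to 64 ReLU hidden nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ConfigurationError, DomainError, NumericError
from .network import activation

__all__ = ["ELMState", "elm_fit", "elm_predict", "oselm_update"]


@dataclass
class ELMState:
    """Random hidden layer (``w (L, n)``, ``b (L,)``) plus solved output weights.

    ``F`` is the inverse Gram matrix of the hidden-activation design; it is
    only needed for online (OS-ELM) use.
    """

    w: np.ndarray
    b: np.ndarray
    beta: np.ndarray
    activation_id: str
    F: np.ndarray | None = None
    leaky_alpha: float = 0.01

    @property
    def hidden_size(self) -> int:
        return self.w.shape[0]


def _hidden(state: ELMState, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != state.w.shape[1]:
        raise DomainError(f"expected {state.w.shape[1]} features, got {X.shape[1]}")
    return activation(state.activation_id, X @ state.w.T + state.b, alpha=state.leaky_alpha)


def elm_fit(
    X: np.ndarray,
    Y: np.ndarray,
    hidden_size: int = 64,
    activation_id: str = "relu",
    rng_seed: int | np.random.Generator | None = None,
    eps: float | None = None,
) -> ELMState:
    """Fit an ELM: random uniform [−1, 1] hidden layer, least-squares output weights.

    Mirrors the parallel model's initialization: ``F = (HᵀH + εI)⁻¹`` is kept
    so the state can subsequently be streamed with :func:`oselm_update`.
    """
    if hidden_size < 1:
        raise ConfigurationError("hidden_size must be >= 1")
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise DomainError("X and Y row counts differ")
    if X.shape[0] < 2:
        raise DomainError("need at least 2 samples")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    state = ELMState(
        w=rng.uniform(-1, 1, (hidden_size, X.shape[1])),
        b=rng.uniform(-1, 1, hidden_size),
        beta=np.zeros((hidden_size, Y.shape[1])),
        activation_id=activation_id,
    )
    H = _hidden(state, X)
    M = H.T @ H
    if eps is None:
        eps = 0.0 if np.linalg.cond(M) < 1e12 else 1e-8
    if eps > 0:
        F = np.linalg.inv(M + eps * np.eye(M.shape[0]))
        beta = F @ (H.T @ Y)
    else:
        if np.linalg.cond(M) > 1e14:
            warnings.warn("singular H'H with eps=0: falling back to pseudoinverse", stacklevel=2)
            F = np.linalg.pinv(M, hermitian=True)
            beta = np.linalg.pinv(H) @ Y
        else:
            F = np.linalg.inv(M)
            beta = F @ (H.T @ Y)
    state.F = 0.5 * (F + F.T)
    state.beta = beta
    return state


def elm_predict(state: ELMState, X: np.ndarray) -> np.ndarray:
    """Network output for a batch, shape (N, o)."""
    return _hidden(state, X) @ state.beta


def oselm_update(state: ELMState, Xk: np.ndarray, Yk: np.ndarray, mu: float = 1.0) -> ELMState:
    """Chunk-wise RLS update of an ELM's output weights (the OS-ELM step).

    Identical recursion to the parallel model's online update, restricted to
    the single hidden-activation block.
    """
    if not (0 < mu <= 1):
        raise ConfigurationError(f"forgetting factor mu must be in (0, 1], got {mu}")
    if state.F is None:
        raise NumericError("ELM state has no F matrix; fit with elm_fit first")
    Xk = np.atleast_2d(np.asarray(Xk, float))
    Yk = np.asarray(Yk, float)
    if Yk.ndim == 1:
        Yk = Yk[:, None]
    if Xk.shape[0] == 0:
        raise DomainError("chunk must be non-empty")
    H = _hidden(state, Xk)
    F = state.F
    FH = F @ H.T
    S = mu * np.eye(H.shape[0]) + H @ FH
    try:
        U = np.linalg.solve(S, FH.T)
    except np.linalg.LinAlgError as exc:
        raise NumericError(f"singular innovation matrix in OS-ELM update: {exc}") from exc
    F_new = (F - FH @ U) / mu
    F_new = 0.5 * (F_new + F_new.T)
    beta_new = state.beta + F_new @ (H.T @ (Yk - H @ state.beta))
    if not np.all(np.isfinite(beta_new)):
        raise NumericError("non-finite output weights after OS-ELM update")
    return replace(state, beta=beta_new, F=F_new)
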