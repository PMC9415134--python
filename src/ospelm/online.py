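"""Chunk-wise recursive-least-squares update of the stacked output weights.

Each arriving chunk of normalized samples updates only the output-weight block
``[beta1; beta2; omega]`` and the inverse Gram matrix ``F``; the random hidden
weights and layer sizes are untouched. With no forgetting (``mu = 1``) the
recursion is algebraically identical to the batch least-squares solution on
all data seen so far — the key correctness oracle for this module.

The optional exponential forgetting factor ``mu < 1`` down-weights old chunks
geometrically (standard exponentially-weighted RLS), honouring the notion of
gradually discarding stale data under drift; it is off by default because the
plain recursion carries no forgetting term.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .exceptions import ConfigurationError, DomainError, NumericError
from .network import OSPELMState, design_matrix

__all__ = ["os_update", "os_update_forgetting"]


def os_update_forgetting(
    state: OSPELMState,
    Xk1: np.ndarray,
    Yk1: np.ndarray,
    mu: float,
) -> OSPELMState:
    """One exponentially-weighted RLS step on a chunk; ``mu = 1`` is plain RLS.

    Updates, with ``A`` the chunk design matrix ``[H | G | X]``:

        F  <-  (F - F Aᵀ (mu·I + A F Aᵀ)⁻¹ A F) / mu
        β  <-  β + F_new Aᵀ (Y - A β)

    The inner inverse is computed via a linear solve, never explicitly.
    """
    if not (0 < mu <= 1):
        raise ConfigurationError(f"forgetting factor mu must be in (0, 1], got {mu}")
    if state.F is None:
        raise NumericError("state has no F matrix (recompute it after a structural change)")
    Xk1 = np.atleast_2d(np.asarray(Xk1, float))
    Yk1 = np.asarray(Yk1, float)
    if Yk1.ndim == 1:
        Yk1 = Yk1[:, None]
    if Xk1.shape[0] == 0:
        raise DomainError("chunk must be non-empty")
    if Xk1.shape[0] != Yk1.shape[0]:
        raise DomainError("chunk X and Y row counts differ")

    A = design_matrix(state, Xk1)
    F = state.F
    FA = F @ A.T                                 # (P, N)
    S = mu * np.eye(A.shape[0]) + A @ FA         # (N, N), SPD when F is PD
    try:
        U = np.linalg.solve(S, FA.T)             # (N, P)
    except np.linalg.LinAlgError as exc:
        raise NumericError(f"singular innovation matrix in RLS update: {exc}") from exc
    F_new = (F - FA @ U) / mu
    F_new = 0.5 * (F_new + F_new.T)

    beta = state.stacked_beta
    beta_new = beta + F_new @ (A.T @ (Yk1 - A @ beta))
    if not np.all(np.isfinite(beta_new)):
        raise NumericError("non-finite output weights after RLS update")

    out = state.with_stacked_beta(beta_new)
    out.F = F_new
    return out


def os_update(state: OSPELMState, Xk1: np.ndarray, Yk1: np.ndarray) -> OSPELMState:
    """Plain online-sequential update on a chunk (no forgetting)."""
    return os_update_forgetting(state, Xk1, Yk1, 1.0)
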