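"""Parallel ELM forward pass and batch least-squares initialization.

The network has two hidden layers fed *in parallel* by different feature
groups — layer 1 (size ``Z1``, activation ``h``) sees the zero-padded system
features, layer 2 (size ``Z2``, activation ``g``) the zero-padded environment
features — plus a direct linear input–output path ``omega``. The three stream
outputs are summed and passed through the output activation ``f``:

    y = f( beta1·h(rho·x_sys + b1) + beta2·g(phi·x_env + b2) + omega·x )

Hidden input weights and biases are drawn once, uniformly on [−1, 1], and
never trained; only the stacked output weights ``[beta1; beta2; omega]`` are
solved, by least-norm least squares over the combined design matrix
``A = [H | G | X]``. The inverse Gram matrix ``F = (AᵀA)⁻¹`` is retained for
the recursive online updates (see :mod:`ospelm.online`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigurationError, DomainError, NumericError
from .preprocessing import FeatureGrouping, split_groups_zero_pad

__all__ = [
    "ACTIVATIONS",
    "activation",
    "NetworkConfig",
    "OSPELMState",
    "ForwardTrace",
    "hidden_outputs",
    "design_matrix",
    "forward",
    "predict",
    "init_batch",
]

ACTIVATIONS = ("identity", "relu", "leaky_relu", "maxout")

#: affine pieces (a, b) of the default maxout unit, max_k(a_k z + b_k) = |z|
DEFAULT_MAXOUT_PIECES = ((1.0, 0.0), (-1.0, 0.0))


def activation(
    kind: str,
    z: np.ndarray,
    alpha: float = 0.01,
    pieces: tuple[tuple[float, float], ...] = DEFAULT_MAXOUT_PIECES,
) -> np.ndarray:
    """Evaluate an activation function elementwise.

    ``relu``: max(0, z); ``leaky_relu``: z for z>0 else alpha·z; ``maxout``:
    max over the configured affine pieces a·z+b; ``identity``: z.
    """
    z = np.asarray(z, float)
    if kind == "identity":
        return z
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "leaky_relu":
        return np.where(z > 0, z, alpha * z)
    if kind == "maxout":
        return np.max(np.stack([a * z + b for a, b in pieces]), axis=0)
    raise ConfigurationError(f"unknown activation {kind!r}; choose from {ACTIVATIONS}")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and initialization settings.

    Defaults follow the reference configuration: ``Z1 = 10`` and ``Z2 = 18``
    hidden neurons, ReLU / Leaky ReLU hidden activations. The output
    activation defaults to identity — the target is unbounded regression on
    the normalized MC, and a maxout over the single scalar stream-sum
    degenerates; maxout remains available via ``f``.
    """

    z1: int = 10
    z2: int = 18
    h: str = "relu"
    g: str = "leaky_relu"
    f: str = "identity"
    leaky_alpha: float = 0.01
    n_outputs: int = 1
    grouping: FeatureGrouping = field(default_factory=FeatureGrouping)
    ridge_eps: float = 1e-8
    cond_threshold: float = 1e12

    def __post_init__(self) -> None:
        if self.z1 < 1 or self.z2 < 1:
            raise ConfigurationError("z1 and z2 must be >= 1")
        for kind in (self.h, self.g, self.f):
            if kind not in ACTIVATIONS:
                raise ConfigurationError(f"unknown activation {kind!r}")
        if self.n_outputs < 1:
            raise ConfigurationError("n_outputs must be >= 1")


@dataclass
class OSPELMState:
    """All trainable and fixed parameters of the network plus the RLS matrix.

    Shapes: ``rho (Z1, n)``, ``phi (Z2, n)``, ``b1 (Z1,)``, ``b2 (Z2,)``,
    ``beta1 (Z1, o)``, ``beta2 (Z2, o)``, ``omega (n, o)``,
    ``F (Z1+Z2+n, Z1+Z2+n)`` (``None`` after a structural change until
    recomputed by ``resize_F``).
    """

    rho: np.ndarray
    phi: np.ndarray
    b1: np.ndarray
    b2: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    omega: np.ndarray
    h_id: str
    g_id: str
    f_id: str
    F: np.ndarray | None
    grouping: FeatureGrouping
    leaky_alpha: float = 0.01

    @property
    def z1(self) -> int:
        return self.rho.shape[0]

    @property
    def z2(self) -> int:
        return self.phi.shape[0]

    @property
    def n(self) -> int:
        return self.rho.shape[1]

    @property
    def o(self) -> int:
        return self.beta1.shape[1]

    @property
    def n_params(self) -> int:
        return self.z1 + self.z2 + self.n

    @property
    def stacked_beta(self) -> np.ndarray:
        """Output weights stacked as ``[beta1; beta2; omega]``, shape (P, o)."""
        return np.vstack([self.beta1, self.beta2, self.omega])

    def with_stacked_beta(self, beta: np.ndarray) -> "OSPELMState":
        beta = np.asarray(beta, float).reshape(self.n_params, self.o)
        return replace(
            self,
            beta1=beta[: self.z1].copy(),
            beta2=beta[self.z1 : self.z1 + self.z2].copy(),
            omega=beta[self.z1 + self.z2 :].copy(),
        )

    def validate(self) -> None:
        for name in ("rho", "phi", "b1", "b2", "beta1", "beta2", "omega"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise NumericError(f"non-finite entries in {name}")
        if self.F is not None:
            if self.F.shape != (self.n_params, self.n_params):
                raise ConfigurationError("F has inconsistent dimensions")
            scale = max(np.abs(self.F).max(), 1e-300)
            if np.abs(self.F - self.F.T).max() > 1e-8 * scale:
                raise NumericError("F is not symmetric")


@dataclass
class ForwardTrace:
    """Intermediate quantities of one forward pass.

    ``y_prime``/``y_double_prime``/``y_triple_prime`` are the hidden-layer-1,
    hidden-layer-2 and direct-linear stream outputs; ``y = f(y' + y'' + y''')``.
    """

    H_row: np.ndarray
    G_row: np.ndarray
    y_prime: np.ndarray
    y_double_prime: np.ndarray
    y_triple_prime: np.ndarray
    y: np.ndarray


def hidden_outputs(state: OSPELMState, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hidden activation matrices ``H (N, Z1)`` and ``G (N, Z2)`` for a batch.

    ``X`` holds full (unsplit) normalized feature rows; the system/environment
    zero-padding is applied internally before each layer's affine map.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != state.n:
        raise DomainError(f"expected {state.n} features, got {X.shape[1]}")
    X_sys, X_env = split_groups_zero_pad(state.grouping, X)
    H = activation(state.h_id, X_sys @ state.rho.T + state.b1, alpha=state.leaky_alpha)
    G = activation(state.g_id, X_env @ state.phi.T + state.b2, alpha=state.leaky_alpha)
    return H, G


def design_matrix(state: OSPELMState, X: np.ndarray) -> np.ndarray:
    """Combined design matrix ``A = [H | G | X]``, shape (N, Z1+Z2+n)."""
    X = np.atleast_2d(np.asarray(X, float))
    H, G = hidden_outputs(state, X)
    return np.hstack([H, G, X])


def forward(state: OSPELMState, x: np.ndarray) -> ForwardTrace:
    """Forward pass for one normalized input vector, keeping stream outputs."""
    x = np.asarray(x, float).reshape(-1)
    if x.shape[0] != state.n:
        raise DomainError(f"expected {state.n} features, got {x.shape[0]}")
    H, G = hidden_outputs(state, x[None, :])
    y1 = H[0] @ state.beta1
    y2 = G[0] @ state.beta2
    y3 = x @ state.omega
    total = y1 + y2 + y3
    if not np.all(np.isfinite(total)):
        raise NumericError(f"non-finite stream sum for input {x!r}")
    y = activation(state.f_id, total, alpha=state.leaky_alpha)
    return ForwardTrace(H_row=H[0], G_row=G[0], y_prime=y1, y_double_prime=y2,
                        y_triple_prime=y3, y=y)


def predict(state: OSPELMState, X: np.ndarray) -> np.ndarray:
    """Batch network output, shape (N, o)."""
    A = design_matrix(state, X)
    return activation(state.f_id, A @ state.stacked_beta, alpha=state.leaky_alpha)


def init_batch(
    X0: np.ndarray,
    Y0: np.ndarray,
    config: NetworkConfig | None = None,
    rng_seed: int | np.random.Generator | None = None,
    eps: float | None = None,
) -> OSPELMState:
    """Draw random hidden weights and solve the initial output weights in batch.

    Hidden input weights and biases are uniform on [−1, 1]. The stacked output
    weights solve the normal equations ``[β1; β2; ω] = (A0ᵀA0 + εI)⁻¹ A0ᵀ Y0``
    with ``A0 = [H | G | X]``; ``F = (A0ᵀA0 + εI)⁻¹`` seeds the recursion.
    ``eps=None`` selects ε automatically: 0 when ``A0ᵀA0`` is well conditioned,
    ``config.ridge_eps`` otherwise. With an explicit ``eps=0`` on a singular
    Gram matrix the solver falls back to the pseudoinverse with a warning.
    """
    config = config if config is not None else NetworkConfig()
    X0 = np.atleast_2d(np.asarray(X0, float))
    Y0 = np.asarray(Y0, float)
    if Y0.ndim == 1:
        Y0 = Y0[:, None]
    if X0.shape[0] < 2:
        raise DomainError("initialization needs at least 2 samples")
    if X0.shape[0] != Y0.shape[0]:
        raise DomainError("X0 and Y0 row counts differ")
    n = X0.shape[1]
    if n != config.grouping.n:
        raise ConfigurationError(f"grouping expects n={config.grouping.n}, data has {n}")

    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    state = OSPELMState(
        rho=rng.uniform(-1, 1, (config.z1, n)),
        phi=rng.uniform(-1, 1, (config.z2, n)),
        b1=rng.uniform(-1, 1, config.z1),
        b2=rng.uniform(-1, 1, config.z2),
        beta1=np.zeros((config.z1, config.n_outputs)),
        beta2=np.zeros((config.z2, config.n_outputs)),
        omega=np.zeros((n, config.n_outputs)),
        h_id=config.h,
        g_id=config.g,
        f_id=config.f,
        F=None,
        grouping=config.grouping,
        leaky_alpha=config.leaky_alpha,
    )

    A0 = design_matrix(state, X0)
    M = A0.T @ A0
    if eps is None:
        cond = np.linalg.cond(M)
        eps = 0.0 if cond < config.cond_threshold else config.ridge_eps

    if eps > 0:
        F = np.linalg.inv(M + eps * np.eye(M.shape[0]))
        beta = F @ (A0.T @ Y0)
    else:
        if np.linalg.cond(M) > 1e14:
            warnings.warn("singular A0'A0 with eps=0: falling back to pseudoinverse", stacklevel=2)
            F = np.linalg.pinv(M, hermitian=True)
            beta = np.linalg.pinv(A0) @ Y0
        else:
            F = np.linalg.inv(M)
            beta = F @ (A0.T @ Y0)
    F = 0.5 * (F + F.T)
    state = state.with_stacked_beta(beta)
    state.F = F
    state.validate()
    return state
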