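"""Min–max normalization, feature grouping with zero padding, dataset partition.

Feature order is fixed as ``[distance, rssi_control, rssi_sensing, dbh,
humidity]``: the first three are *system-dependent* parameters (reader
geometry and the two tag RSSIs) routed to hidden layer 1, the last two are
*environment-dependent* parameters (DBH, air humidity) routed to hidden
layer 2. Both group vectors are zero-padded back to full length so the two
hidden layers share one input dimensionality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError, DomainError
from .rf import Sample

__all__ = [
    "FEATURE_NAMES",
    "TARGET_NAME",
    "NormalizationState",
    "FeatureGrouping",
    "fit_minmax",
    "normalize",
    "denormalize",
    "split_groups_zero_pad",
    "partition_indices",
    "partition_dataset",
    "feature_target_arrays",
]

FEATURE_NAMES: tuple[str, ...] = (
    "distance_m",
    "rssi_control_dbm",
    "rssi_sensing_dbm",
    "dbh_m",
    "humidity_percent",
)
TARGET_NAME = "mc_fraction"


def feature_target_arrays(samples: Sequence[Sample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into a raw feature matrix (N, 5) and MC-fraction targets (N,).

    Missing control RSSI becomes NaN (such rows cannot feed the network).
    """
    X = np.array(
        [
            [
                s.scenario.distance,
                np.nan if s.rssi_control is None else s.rssi_control,
                s.rssi_sensing,
                s.scenario.dbh,
                s.scenario.humidity,
            ]
            for s in samples
        ],
        dtype=float,
    )
    y = np.array([s.scenario.mc for s in samples], dtype=float)
    return X, y


@dataclass
class NormalizationState:
    """Per-column min/max recorded over a fitted period.

    Columns where ``x_min == x_max`` (constant features) are flagged; they are
    mapped to 0 on transform because they carry no information and would
    otherwise divide by zero.
    """

    columns: tuple[str, ...]
    x_min: np.ndarray
    x_max: np.ndarray

    def __post_init__(self) -> None:
        self.x_min = np.asarray(self.x_min, float)
        self.x_max = np.asarray(self.x_max, float)
        if self.x_min.shape != self.x_max.shape or self.x_min.shape != (len(self.columns),):
            raise ConfigurationError("NormalizationState: inconsistent shapes")
        if np.any(self.x_max < self.x_min):
            raise ConfigurationError("NormalizationState: x_max < x_min")

    @property
    def constant_mask(self) -> np.ndarray:
        return self.x_max == self.x_min


def fit_minmax(X: np.ndarray, columns: Sequence[str] | None = None) -> NormalizationState:
    """Record column-wise min/max over the provided period only.

    Warns on constant columns (they will normalize to 0).
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] < 2:
        raise DomainError("fit_minmax needs at least 2 samples")
    if columns is None:
        columns = tuple(f"x{i}" for i in range(X.shape[1]))
    if len(columns) != X.shape[1]:
        raise ConfigurationError("column names do not match data width")
    x_min = X.min(axis=0)
    x_max = X.max(axis=0)
    state = NormalizationState(columns=tuple(columns), x_min=x_min, x_max=x_max)
    if state.constant_mask.any():
        names = [c for c, m in zip(state.columns, state.constant_mask) if m]
        warnings.warn(f"constant column(s) {names}: will normalize to 0", stacklevel=2)
    return state


def normalize(state: NormalizationState, x: np.ndarray) -> np.ndarray:
    """Affine per-feature map sending the fitted min to 0 and max to 1.

    Streaming values outside the fitted period are *not* clipped, so the map
    stays affine and invertible; out-of-range inputs land outside [0, 1].
    """
    x = np.asarray(x, float)
    if x.shape[-1] != len(state.columns):
        raise DomainError(f"expected {len(state.columns)} features, got {x.shape[-1]}")
    span = np.where(state.constant_mask, 1.0, state.x_max - state.x_min)
    out = (x - state.x_min) / span
    return np.where(state.constant_mask, 0.0, out)


def denormalize(state: NormalizationState, x_norm: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize` (constant columns map back to their value)."""
    x_norm = np.asarray(x_norm, float)
    if x_norm.shape[-1] != len(state.columns):
        raise DomainError(f"expected {len(state.columns)} features, got {x_norm.shape[-1]}")
    span = np.where(state.constant_mask, 0.0, state.x_max - state.x_min)
    return state.x_min + x_norm * span


@dataclass(frozen=True)
class FeatureGrouping:
    """Disjoint system/environment index groups covering all ``n`` features.

    Default: 5 features, of which the first ``m = 3`` (distance, control RSSI,
    sensing RSSI) form the system group and the remaining two (DBH, humidity)
    the environment group.
    """

    n: int = 5
    m: int = 3

    def __post_init__(self) -> None:
        if not (1 <= self.m < self.n):
            raise ConfigurationError(f"need 1 <= m < n, got m={self.m}, n={self.n}")

    @property
    def system_indices(self) -> tuple[int, ...]:
        return tuple(range(self.m))

    @property
    def environment_indices(self) -> tuple[int, ...]:
        return tuple(range(self.m, self.n))


def split_groups_zero_pad(grouping: FeatureGrouping, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a vector (or batch) into zero-padded system/environment parts.

    Both outputs have the full length ``n``; the system part keeps entries at
    system indices and zeros elsewhere, the environment part is complementary,
    so their elementwise sum reassembles the input exactly.
    """
    x = np.asarray(x, float)
    if x.shape[-1] != grouping.n:
        raise DomainError(f"expected {grouping.n} features, got {x.shape[-1]}")
    sys_mask = np.zeros(grouping.n)
    sys_mask[list(grouping.system_indices)] = 1.0
    x_sys = x * sys_mask
    x_env = x * (1.0 - sys_mask)
    return x_sys, x_env


def partition_indices(
    n: int,
    ratio: Sequence[float] = (2, 6, 2),
    rng_seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, ...]:
    """Random disjoint exhaustive index partition with largest-remainder sizes."""
    if n < len(ratio):
        raise ConfigurationError(f"need at least {len(ratio)} samples, got {n}")
    ratio = np.asarray(ratio, float)
    if np.any(ratio <= 0) or not np.all(np.isfinite(ratio)):
        raise ConfigurationError(f"ratio entries must be positive, got {ratio!r}")
    exact = n * ratio / ratio.sum()
    sizes = np.floor(exact).astype(int)
    remainder = exact - sizes
    # distribute leftover slots to the largest fractional parts (ties: lower index)
    for idx in np.argsort(-remainder, kind="stable")[: n - sizes.sum()]:
        sizes[idx] += 1
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    perm = rng.permutation(n)
    bounds = np.cumsum(sizes)[:-1]
    return tuple(np.sort(part) for part in np.split(perm, bounds))


def partition_dataset(
    samples: Sequence,
    ratio: Sequence[float] = (2, 6, 2),
    rng_seed: int | np.random.Generator | None = None,
) -> tuple[list, ...]:
    """Randomly split samples into init/train/test parts proportional to ``ratio``.

    The parts are disjoint, exhaustive, and reproducible under a seed; within
    each part the original stream order is preserved.
    """
    parts = partition_indices(len(samples), ratio, rng_seed)
    return tuple([samples[i] for i in idx] for idx in parts)
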