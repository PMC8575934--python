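"""Leave-one-out cross-validation, latent-variable selection and error metrics.

Preprocessing is refit inside every fold (no leakage): the pipeline factory
builds a fresh estimator per fold and per candidate k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np

from .errors import DegenerateInputError, DimensionError
from .preprocessing import MultiBlockDataset, concatenate


class Estimator(Protocol):
    def fit(self, dataset: MultiBlockDataset) -> "Estimator": ...

    def predict(self, blocks) -> np.ndarray: ...


def rmse(Y: np.ndarray, Y_hat: np.ndarray) -> float:
    """Root mean squared error over all sample-channel cells (mM)."""
    Y = np.asarray(Y, float)
    Y_hat = np.asarray(Y_hat, float)
    if Y.shape != Y_hat.shape:
        raise DimensionError(f"shape mismatch {Y.shape} vs {Y_hat.shape}")
    return float(np.sqrt(np.mean((Y - Y_hat) ** 2)))


def r2(Y: np.ndarray, Y_hat: np.ndarray) -> float:
    """Per-channel 1 - SSE/SST, averaged over channels.

    Channels with zero variance in Y are excluded with a warning.
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    Y_hat = np.atleast_2d(np.asarray(Y_hat, float))
    if Y.ndim == 1:
        Y, Y_hat = Y[:, None], Y_hat[:, None]
    if Y.shape != Y_hat.shape:
        raise DimensionError(f"shape mismatch {Y.shape} vs {Y_hat.shape}")
    vals = []
    for c in range(Y.shape[1]):
        sst = float(np.sum((Y[:, c] - Y[:, c].mean()) ** 2))
        if sst == 0:
            warnings.warn(f"channel {c} has zero variance; excluded from R^2", stacklevel=2)
            continue
        sse = float(np.sum((Y[:, c] - Y_hat[:, c]) ** 2))
        vals.append(1.0 - sse / sst)
    if not vals:
        raise DegenerateInputError("all channels have zero variance; R^2 undefined")
    return float(np.mean(vals))


_TIE_RTOL = 1e-6


def select_k(rmse_per_k: np.ndarray) -> int:
    """Smallest k whose RMSE is within (1 + 1e-6) of the minimum (1-based)."""
    rmse_per_k = np.asarray(rmse_per_k, float)
    if rmse_per_k.size == 0:
        raise DegenerateInputError("empty rmse_per_k")
    best = float(np.min(rmse_per_k))
    for k, v in enumerate(rmse_per_k, start=1):
        if v <= best * (1 + _TIE_RTOL):
            return k
    return int(np.argmin(rmse_per_k)) + 1  # unreachable


@dataclass
class CVResult:
    method: str
    rmse_per_k: np.ndarray  # index 0 -> k=1
    selected_k: int
    duplicate_rows: bool = False
    per_channel_rmse: dict[int, np.ndarray] = field(default_factory=dict)

    def to_rows(self) -> list[tuple[int, float]]:
        return [(k + 1, float(v)) for k, v in enumerate(self.rmse_per_k)]


def loocv(
    make_pipeline: Callable[[int], Estimator],
    dataset: MultiBlockDataset,
    k_max: int,
    method: str = "",
) -> CVResult:
    """LOOCV RMSE for k = 1..k_max latent variables/components.

    For each left-out sample the full pipeline (preprocessing included) is
    refit on the remaining rows. Duplicated spectral rows are flagged — the
    twin of a left-out row stays in the training fold, which makes the RMSE
    optimistic — but not rejected.
    """
    n = dataset.n_samples
    if n < 3:
        raise DegenerateInputError("LOOCV needs at least 3 training samples")
    if k_max > n - 2:
        raise DimensionError(f"k_max must be <= n_train - 2 = {n - 2}, got {k_max}")
    X, _ = concatenate(dataset.blocks)
    duplicate = bool(len(np.unique(X.round(12), axis=0)) < n)

    m = dataset.Y.shape[1]
    errors = np.zeros((k_max, n, m))
    order = np.arange(n)
    for i in order:
        keep = [j for j in range(n) if j != i]
        train = dataset.subset(keep)
        held = dataset.subset([i])
        for k in range(1, k_max + 1):
            est = make_pipeline(k)
            est.fit(train)
            pred = est.predict(held.blocks)
            errors[k - 1, i] = pred[0] - dataset.Y[i]
    rmse_per_k = np.sqrt(np.mean(errors**2, axis=(1, 2)))
    per_channel = {
        k + 1: np.sqrt(np.mean(errors[k] ** 2, axis=0)) for k in range(k_max)
    }
    return CVResult(
        method=method,
        rmse_per_k=rmse_per_k,
        selected_k=select_k(rmse_per_k),
        duplicate_rows=duplicate,
        per_channel_rmse=per_channel,
    )
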