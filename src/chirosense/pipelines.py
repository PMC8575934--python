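"""End-to-end regression pipelines: preprocessing + estimator behind one fit/predict.

Methods: pcr, pls, mbpls, mbpca-ols, lasso-pcr, lasso-pls.
Scaling: center | uv (unit variance) | hard | soft (block scaling on top of uv).
All fitted pipelines reduce to an affine map on the concatenated raw matrix,
which is what gets serialized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import chemometrics as cm
from . import multiblock as mb
from .errors import ConfigurationError, ConvergenceError
from .preprocessing import MultiBlockDataset, Preprocessor, SpectralBlock, concatenate

METHODS = ("pcr", "pls", "mbpls", "mbpca-ols", "lasso-pcr", "lasso-pls")
SCALINGS = ("center", "uv", "hard", "soft")


@dataclass
class PipelineConfig:
    method: str = "pcr"
    scaling: str = "uv"
    k: int = 4  # components / latent variables
    lasso_lambda: float | None = None  # None -> LOOCV grid selection at fit time

    def __post_init__(self):
        if self.method not in METHODS:
            raise ConfigurationError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.scaling not in SCALINGS:
            raise ConfigurationError(f"scaling must be one of {SCALINGS}, got {self.scaling!r}")


@dataclass
class Pipeline:
    """Fit on a MultiBlockDataset, predict per-enantiomer concentrations (mM)."""

    config: PipelineConfig
    preprocessor: Preprocessor | None = None
    model: object | None = None
    selected_vars: np.ndarray | None = None  # LASSO-selected columns
    channel_names: list[tuple[str, str]] = field(default_factory=list)
    lasso_lambda_: float | None = None

    def fit(self, dataset: MultiBlockDataset) -> "Pipeline":
        cfg = self.config
        self.channel_names = list(dataset.channel_names)
        self.preprocessor = Preprocessor(scaling=cfg.scaling)
        blocks = self.preprocessor.fit_transform(dataset.blocks)
        Y = dataset.Y
        X, _ = concatenate(blocks)

        if cfg.method.startswith("lasso-"):
            lam = cfg.lasso_lambda
            if lam is None:
                lam = _select_lasso_lambda(X, Y)
            self.lasso_lambda_ = lam
            self.selected_vars = cm.lasso_select(X, Y, lam)
            if self.selected_vars.size == 0:
                raise ConfigurationError(
                    f"LASSO at lambda={lam:g} selected no variables; lower the penalty"
                )
            X = X[:, self.selected_vars]

        if cfg.method in ("pcr", "lasso-pcr"):
            k = min(cfg.k, min(X.shape[0] - 1, X.shape[1]))
            self.model = cm.pcr_fit(X, Y, k)
        elif cfg.method in ("pls", "lasso-pls"):
            k = min(cfg.k, min(X.shape[0] - 1, X.shape[1]))
            self.model = cm.pls_fit(X, Y, k)
        elif cfg.method == "mbpls":
            self.model = mb.mbpls_fit(blocks, Y, cfg.k)
        elif cfg.method == "mbpca-ols":
            mbpca = mb.mbpca_fit(blocks, cfg.k)
            scores = mbpca.super_scores
            coef = cm.ols_fit(scores, Y)
            self.model = (mbpca, coef)
        return self

    def predict(self, blocks: Sequence[SpectralBlock]) -> np.ndarray:
        if self.model is None or self.preprocessor is None:
            raise ConfigurationError("pipeline not fitted")
        cfg = self.config
        pre = self.preprocessor.transform(blocks)
        if cfg.method == "mbpls":
            return mb.mbpls_predict(self.model, pre)
        if cfg.method == "mbpca-ols":
            mbpca, coef = self.model
            scores = mb.mbpca_transform(mbpca, pre)
            return cm.ols_predict(coef, scores)
        X, _ = concatenate(pre)
        if self.selected_vars is not None:
            X = X[:, self.selected_vars]
        if cfg.method in ("pcr", "lasso-pcr"):
            return cm.pcr_predict(self.model, X)
        return cm.pls_predict(self.model, X)

    # -- serialization: every fitted pipeline is affine on the raw fused matrix

    def _affine(self) -> tuple[np.ndarray, np.ndarray]:
        """Effective (coef, intercept) of the fitted pipeline on preprocessed X."""
        cfg = self.config
        if cfg.method in ("pcr", "lasso-pcr"):
            m: cm.PCRModel = self.model
            if m.n_pc == 0:
                p = m.pca.mean_.size
                return np.zeros((p, m.coef.shape[1])), m.coef[0]
            B = m.pca.components_ @ m.coef[1:]
            b0 = m.coef[0] - m.pca.mean_ @ B
            return B, b0
        if cfg.method in ("pls", "lasso-pls"):
            m: cm.PLSModel = self.model
            return m.B, m.y_mean - m.x_mean @ m.B
        if cfg.method == "mbpls":
            pls = self.model.pls
            return pls.B, pls.y_mean - pls.x_mean @ pls.B
        mbpca, coef = self.model
        # sequential deflation projection is affine: t = (x - mean) @ G
        p = mbpca.mean_.size
        G = np.zeros((p, mbpca.n_pc))
        D = np.eye(p)
        for a in range(mbpca.n_pc):
            p_a = mbpca.concat_loadings[:, a]
            g = D @ p_a / (p_a @ p_a)
            G[:, a] = g
            D = D - np.outer(g, p_a)
        B = G @ coef[1:]
        b0 = coef[0] + (0 - mbpca.mean_) @ B
        return B, b0

    def to_dict(self) -> dict:
        B, b0 = self._affine()
        d = {
            "config": {
                "method": self.config.method,
                "scaling": self.config.scaling,
                "k": self.config.k,
                "lasso_lambda": self.lasso_lambda_ or self.config.lasso_lambda,
            },
            "preprocessor": self.preprocessor.to_dict(),
            "channel_names": [list(c) for c in self.channel_names],
            "selected_vars": None
            if self.selected_vars is None
            else self.selected_vars.tolist(),
            "coef": B.tolist(),
            "intercept": np.asarray(b0, float).tolist(),
        }
        if self.config.method == "mbpls":
            d["block_importance"] = self.model.block_importance_.tolist()
            d["block_names"] = [list(n) for n in self.model.block_names]
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "FrozenPipeline":
        return FrozenPipeline.from_dict(json.loads(Path(path).read_text()))


@dataclass
class FrozenPipeline:
    """Deserialized pipeline: frozen preprocessing + affine predictor."""

    config: PipelineConfig
    preprocessor: Preprocessor
    coef: np.ndarray
    intercept: np.ndarray
    channel_names: list[tuple[str, str]]
    selected_vars: np.ndarray | None = None
    block_importance: np.ndarray | None = None
    block_names: list[tuple[str, str]] | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "FrozenPipeline":
        cfg = PipelineConfig(
            method=d["config"]["method"],
            scaling=d["config"]["scaling"],
            k=d["config"]["k"],
            lasso_lambda=d["config"]["lasso_lambda"],
        )
        return cls(
            config=cfg,
            preprocessor=Preprocessor.from_dict(d["preprocessor"]),
            coef=np.array(d["coef"], float),
            intercept=np.array(d["intercept"], float),
            channel_names=[tuple(c) for c in d["channel_names"]],
            selected_vars=None
            if d.get("selected_vars") is None
            else np.array(d["selected_vars"], int),
            block_importance=None
            if d.get("block_importance") is None
            else np.array(d["block_importance"], float),
            block_names=None
            if d.get("block_names") is None
            else [tuple(n) for n in d["block_names"]],
        )

    def predict(self, blocks: Sequence[SpectralBlock]) -> np.ndarray:
        pre = self.preprocessor.transform(blocks)
        X, _ = concatenate(pre)
        if self.selected_vars is not None:
            X = X[:, self.selected_vars]
        return X @ self.coef + self.intercept


def _select_lasso_lambda(X: np.ndarray, Y: np.ndarray, n_points: int = 20) -> float:
    """LOOCV grid search for the LASSO penalty (averaged over channels).

    Fits follow a descending-lambda path with warm starts per fold/channel.
    """
    grid = np.sort(cm.lasso_lambda_grid(X, Y, n_points))[::-1]
    Y2 = np.asarray(Y, float)
    Y2 = Y2[:, None] if Y2.ndim == 1 else Y2
    n = X.shape[0]
    sq = np.zeros(len(grid))
    # penalties whose coordinate descent hits the sweep limit are unusable;
    # the path runs lambda-descending, so everything smaller is pruned too
    n_usable = len(grid)
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        Xk = X[keep]
        for c in range(Y2.shape[1]):
            beta = None
            for g in range(n_usable):
                try:
                    model = cm.lasso_fit(Xk, Y2[keep, c], grid[g], beta0=beta)
                except ConvergenceError:
                    n_usable = g
                    break
                beta = model.coef
                pred = cm.lasso_predict(model, X[i: i + 1])[0]
                sq[g] += (pred - Y2[i, c]) ** 2
    if n_usable == 0:
        raise ConvergenceError("no LASSO penalty in the grid converged")
    err = np.sqrt(sq[:n_usable] / (n * Y2.shape[1]))
    # smallest-complexity (largest lambda) within the usual near-tie tolerance
    best = float(np.min(err))
    for g in range(n_usable):
        if err[g] <= best * (1 + 1e-6):
            return float(grid[g])
    return float(grid[int(np.argmin(err))])


def make_loocv_factory(config: PipelineConfig):
    """Factory for model_selection.loocv: k -> fresh pipeline with that k."""

    def factory(k: int) -> Pipeline:
        cfg = PipelineConfig(
            method=config.method,
            scaling=config.scaling,
            k=k,
            lasso_lambda=config.lasso_lambda,
        )
        return Pipeline(cfg)

    return factory
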