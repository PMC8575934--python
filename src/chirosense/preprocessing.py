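"""Centering, variable scaling, block scaling and concatenation.

Every transform returns a :class:`ScalingRecord` so it can be applied frozen to
test rows and inverted exactly. Column variance uses ddof=1. Zero-variance
columns keep divisor 1 (and emit a warning) so wavelength indexing stays stable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import AlignmentError, ConfigurationError, DegenerateInputError
from .spectra_io import WavelengthGrid


@dataclass
class SpectralBlock:
    """samples x wavelengths response matrix for one (modality, solvent) pair."""

    name: tuple[str, str]
    matrix: np.ndarray
    grid: WavelengthGrid
    sample_ids: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise AlignmentError("block matrix must be 2-D")
        if self.matrix.shape[0] != len(self.sample_ids):
            raise AlignmentError(
                f"block {self.name}: {self.matrix.shape[0]} rows but "
                f"{len(self.sample_ids)} sample ids"
            )
        if self.matrix.shape[1] != len(self.grid):
            raise AlignmentError(f"block {self.name}: column count does not match grid")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_variables(self) -> int:
        return self.matrix.shape[1]

    def subset(self, indices: Sequence[int]) -> "SpectralBlock":
        idx = list(indices)
        return SpectralBlock(
            name=self.name,
            matrix=self.matrix[idx],
            grid=self.grid,
            sample_ids=[self.sample_ids[i] for i in idx],
        )


@dataclass
class MultiBlockDataset:
    """Aligned spectral blocks plus the per-enantiomer concentration responses (mM)."""

    blocks: list[SpectralBlock]
    Y: np.ndarray
    channel_names: list[tuple[str, str]]  # (analyte, enantiomer-label)
    roles: list[str] | None = None  # optional train/test tag per sample

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        if not self.blocks:
            raise ConfigurationError("dataset needs at least one block")
        ids = self.blocks[0].sample_ids
        for b in self.blocks:
            if b.sample_ids != ids:
                raise AlignmentError("all blocks must share sample ids and ordering")
        if self.Y.shape != (len(ids), len(self.channel_names)):
            raise AlignmentError("Y shape must be (n_samples, n_channels)")
        if self.roles is not None and len(self.roles) != len(ids):
            raise AlignmentError("roles length must match sample count")

    @property
    def sample_ids(self) -> list[str]:
        return self.blocks[0].sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, indices: Sequence[int]) -> "MultiBlockDataset":
        idx = list(indices)
        return MultiBlockDataset(
            blocks=[b.subset(idx) for b in self.blocks],
            Y=self.Y[idx],
            channel_names=list(self.channel_names),
            roles=[self.roles[i] for i in idx] if self.roles is not None else None,
        )

    def split(self) -> tuple["MultiBlockDataset", "MultiBlockDataset"]:
        """Split into (train, test) by the per-sample roles."""
        if self.roles is None:
            raise ConfigurationError("dataset has no roles; cannot split")
        train = [i for i, r in enumerate(self.roles) if r == "train"]
        test = [i for i, r in enumerate(self.roles) if r == "test"]
        return self.subset(train), self.subset(test)


@dataclass
class ScalingRecord:
    """Frozen parameters of one transform: per-column means/divisors + block divisor."""

    method: str  # center_only | unit_variance | hard_block | soft_block | none
    means: np.ndarray
    scales: np.ndarray
    block_divisor: float = 1.0

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        if np.any(self.scales <= 0) or self.block_divisor <= 0:
            raise ConfigurationError("scaling divisors must be positive")

    def apply(self, matrix: np.ndarray) -> np.ndarray:
        return (np.asarray(matrix, float) - self.means) / self.scales / self.block_divisor

    def invert(self, matrix: np.ndarray) -> np.ndarray:
        return np.asarray(matrix, float) * self.block_divisor * self.scales + self.means

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "block_divisor": self.block_divisor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingRecord":
        return cls(
            method=d["method"],
            means=np.array(d["means"], float),
            scales=np.array(d["scales"], float),
            block_divisor=float(d["block_divisor"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "ScalingRecord":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _with_matrix(block: SpectralBlock, matrix: np.ndarray) -> SpectralBlock:
    return replace(block, matrix=matrix)


def mean_center(block: SpectralBlock) -> tuple[SpectralBlock, ScalingRecord]:
    """Subtract column means; needs at least two samples."""
    if block.n_samples < 2:
        raise DegenerateInputError("mean centering needs >= 2 samples")
    means = block.matrix.mean(axis=0)
    record = ScalingRecord(method="center_only", means=means, scales=np.ones_like(means))
    return _with_matrix(block, block.matrix - means), record


def unit_variance_scale(block: SpectralBlock) -> tuple[SpectralBlock, ScalingRecord]:
    """Divide each (already centered) column by its sd (ddof=1).

    Zero-variance columns are passed through with divisor 1 and a warning.
    """
    sd = block.matrix.std(axis=0, ddof=1)
    degenerate = sd <= 0
    if np.any(degenerate):
        warnings.warn(
            f"block {block.name}: {int(degenerate.sum())} zero-variance columns "
            "passed through unscaled",
            stacklevel=2,
        )
    scales = np.where(degenerate, 1.0, sd)
    record = ScalingRecord(method="unit_variance", means=np.zeros_like(sd), scales=scales)
    return _with_matrix(block, block.matrix / scales), record


_BLOCK_EXPONENT = {"hard": 0.5, "soft": 0.25, "none": 0.0}


def block_scale(
    blocks: Sequence[SpectralBlock], method: str = "hard"
) -> tuple[list[SpectralBlock], list[ScalingRecord]]:
    """Divide each block by p_b^(1/2) (hard) or p_b^(1/4) (soft); p_b = variable count."""
    if not blocks:
        raise ConfigurationError("block_scale needs at least one block")
    if method not in _BLOCK_EXPONENT:
        raise ConfigurationError(f"unknown block scaling method {method!r}")
    exponent = _BLOCK_EXPONENT[method]
    out_blocks, records = [], []
    for b in blocks:
        divisor = float(b.n_variables) ** exponent
        rec = ScalingRecord(
            method=f"{method}_block" if method != "none" else "none",
            means=np.zeros(b.n_variables),
            scales=np.ones(b.n_variables),
            block_divisor=divisor,
        )
        out_blocks.append(_with_matrix(b, b.matrix / divisor))
        records.append(rec)
    return out_blocks, records


def concatenate(
    blocks: Sequence[SpectralBlock],
) -> tuple[np.ndarray, dict[tuple[str, str], tuple[int, int]]]:
    """Column-wise concatenation; returns the fused matrix and [start, end) spans."""
    if not blocks:
        raise ConfigurationError("concatenate needs at least one block")
    ids = blocks[0].sample_ids
    for b in blocks:
        if b.sample_ids != ids:
            raise AlignmentError("mismatched sample ids across blocks")
    spans: dict[tuple[str, str], tuple[int, int]] = {}
    start = 0
    for b in blocks:
        spans[b.name] = (start, start + b.n_variables)
        start += b.n_variables
    return np.hstack([b.matrix for b in blocks]), spans


@dataclass
class Preprocessor:
    """Composable center -> variable scale -> block scale chain with frozen records.

    ``scaling``: 'center' (mean centering only), 'uv' (+ unit variance),
    'hard' / 'soft' (+ block scaling after unit variance).
    """

    scaling: str = "uv"
    records: dict[tuple[str, str], list[ScalingRecord]] = field(default_factory=dict)
    block_names: list[tuple[str, str]] = field(default_factory=list)

    _VALID = ("center", "uv", "hard", "soft")

    def fit(self, blocks: Sequence[SpectralBlock]) -> "Preprocessor":
        if self.scaling not in self._VALID:
            raise ConfigurationError(f"scaling must be one of {self._VALID}")
        self.records = {}
        self.block_names = [b.name for b in blocks]
        staged = []
        for b in blocks:
            chain: list[ScalingRecord] = []
            b, rec = mean_center(b)
            chain.append(rec)
            if self.scaling in ("uv", "hard", "soft"):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    b, rec = unit_variance_scale(b)
                chain.append(rec)
            self.records[b.name] = chain
            staged.append(b)
        if self.scaling in ("hard", "soft"):
            staged, recs = block_scale(staged, method=self.scaling)
            for b, rec in zip(staged, recs):
                self.records[b.name].append(rec)
        return self

    def transform(self, blocks: Sequence[SpectralBlock]) -> list[SpectralBlock]:
        if not self.records:
            raise ConfigurationError("Preprocessor not fitted")
        out = []
        for b in blocks:
            if b.name not in self.records:
                raise AlignmentError(f"no scaling record for block {b.name}")
            m = b.matrix
            for rec in self.records[b.name]:
                m = rec.apply(m)
            out.append(_with_matrix(b, m))
        return out

    def fit_transform(self, blocks: Sequence[SpectralBlock]) -> list[SpectralBlock]:
        return self.fit(blocks).transform(blocks)

    def inverse_transform(self, blocks: Sequence[SpectralBlock]) -> list[SpectralBlock]:
        out = []
        for b in blocks:
            m = b.matrix
            for rec in reversed(self.records[b.name]):
                m = rec.invert(m)
            out.append(_with_matrix(b, m))
        return out

    def to_dict(self) -> dict:
        return {
            "scaling": self.scaling,
            "block_names": [list(n) for n in self.block_names],
            "records": {
                "|".join(name): [r.to_dict() for r in chain]
                for name, chain in self.records.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Preprocessor":
        pp = cls(scaling=d["scaling"])
        pp.block_names = [tuple(n) for n in d["block_names"]]
        pp.records = {
            tuple(k.split("|")): [ScalingRecord.from_dict(r) for r in chain]
            for k, chain in d["records"].items()
        }
        return pp
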