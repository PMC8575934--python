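"""Spectrum and manifest I/O plus the wavelength-grid conventions shared by all modules.

Conventions: CD intensities are stored in millidegrees, UV in absorbance units,
concentrations in mM. The canonical grid spans 250-450 nm at 1 nm (201 points).
Spectrum CSV files are comma-separated with ``#``-prefixed metadata header lines.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .errors import (
    AlignmentError,
    DataError,
    FormatError,
    RangeError,
    UnsupportedDialectError,
)

MODALITIES = ("CD", "UV")
SOLVENTS = ("DCE", "MeOH")

#: (modality, solvent) keys in canonical block order.
BLOCK_KEYS = (("CD", "DCE"), ("CD", "MeOH"), ("UV", "DCE"), ("UV", "MeOH"))

_WAVELENGTH_MIN = 200.0
_WAVELENGTH_MAX = 600.0


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nm, confined to [200, 600]."""

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size == 0:
            raise DataError("wavelength grid must be a non-empty 1-D array")
        if np.any(np.diff(values) <= 0):
            raise DataError("wavelength grid must be strictly increasing")
        if values[0] < _WAVELENGTH_MIN or values[-1] > _WAVELENGTH_MAX:
            raise DataError(
                f"wavelengths must lie within [{_WAVELENGTH_MIN:g}, {_WAVELENGTH_MAX:g}] nm"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other) -> bool:
        return isinstance(other, WavelengthGrid) and np.array_equal(self.values, other.values)

    def index_of(self, wavelength_nm: float) -> int:
        """Index of an exact grid wavelength; RangeError if absent."""
        idx = np.nonzero(np.isclose(self.values, wavelength_nm, rtol=0, atol=1e-9))[0]
        if idx.size == 0:
            raise RangeError(f"{wavelength_nm} nm is not on the grid")
        return int(idx[0])


def default_grid() -> WavelengthGrid:
    """Canonical 250-450 nm grid at 1 nm spacing (201 points)."""
    return WavelengthGrid(np.arange(250.0, 451.0, 1.0))


@dataclass
class Spectrum:
    """One measurement trace on a wavelength grid.

    ``intensities`` are mdeg for CD and absorbance units for UV; CD values may
    be negative, both must be finite.
    """

    grid: WavelengthGrid
    intensities: np.ndarray
    modality: str
    solvent: str
    sample_id: str = ""

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.grid),):
            raise DataError("intensity vector length must match the grid")
        if not np.all(np.isfinite(self.intensities)):
            raise DataError("intensities must be finite")
        if self.modality not in MODALITIES:
            raise DataError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.solvent not in SOLVENTS:
            raise DataError(f"solvent must be one of {SOLVENTS}, got {self.solvent!r}")

    def value_at(self, wavelength_nm: float) -> float:
        return float(self.intensities[self.grid.index_of(wavelength_nm)])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Spectrum)
            and self.grid == other.grid
            and np.array_equal(self.intensities, other.intensities)
            and self.modality == other.modality
            and self.solvent == other.solvent
            and self.sample_id == other.sample_id
        )


# ---------------------------------------------------------------------------
# Spectrum CSV
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("modality", "solvent", "sample_id")


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as CSV with a ``#`` metadata header.

    Values are printed with 10 significant digits so a read/write round trip is
    lossless at that precision.
    """
    path = Path(path)
    lines = [
        f"# modality: {spectrum.modality}",
        f"# solvent: {spectrum.solvent}",
        f"# sample_id: {spectrum.sample_id}",
        "wavelength_nm,value",
    ]
    for wl, v in zip(spectrum.grid.values, spectrum.intensities):
        lines.append(f"{wl:.10g},{v:.10g}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum_csv(path: str | Path) -> Spectrum:
    """Parse a spectrum CSV; rows are sorted by wavelength, duplicates rejected."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*(\w+)\s*:\s*(.*)", line)
            if m:
                meta[m.group(1)] = m.group(2).strip()
            continue
        if line.lower().startswith("wavelength"):
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise FormatError(f"expected two columns, got {line!r}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise FormatError(f"non-numeric row {line!r}") from exc
    missing = [k for k in _HEADER_KEYS if k not in meta]
    if missing:
        raise FormatError(f"missing metadata header keys: {missing}")
    if not rows:
        raise DataError(f"no data rows in {path}")
    rows.sort(key=lambda r: r[0])
    wl = np.array([r[0] for r in rows])
    if np.any(np.diff(wl) == 0):
        raise DataError("duplicate wavelengths")
    vals = np.array([r[1] for r in rows])
    return Spectrum(
        grid=WavelengthGrid(wl),
        intensities=vals,
        modality=meta["modality"],
        solvent=meta["solvent"],
        sample_id=meta["sample_id"],
    )


def resample(spectrum: Spectrum, grid: WavelengthGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (no extrapolation)."""
    src = spectrum.grid.values
    if grid.values[0] < src[0] or grid.values[-1] > src[-1]:
        raise RangeError(
            f"requested grid [{grid.values[0]:g}, {grid.values[-1]:g}] exceeds data "
            f"range [{src[0]:g}, {src[-1]:g}]"
        )
    vals = np.interp(grid.values, src, spectrum.intensities)
    return Spectrum(
        grid=grid,
        intensities=vals,
        modality=spectrum.modality,
        solvent=spectrum.solvent,
        sample_id=spectrum.sample_id,
    )


# ---------------------------------------------------------------------------
# Minimal JCAMP-DX reader
# ---------------------------------------------------------------------------


def read_jcamp(path: str | Path, modality: str = "UV", solvent: str = "DCE") -> Spectrum:
    """Read a minimal JCAMP-DX file: ``##XYDATA=(X++(Y..Y))`` with AFFN values.

    Anything outside this subset (compression schemes, NTUPLES, PEAK TABLE)
    raises :class:`UnsupportedDialectError`.
    """
    path = Path(path)
    text = path.read_text()
    labels: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key in ("NTUPLES", "PEAKTABLE", "XYPOINTS"):
                raise UnsupportedDialectError(f"unsupported JCAMP record ##{key}")
            if key == "XYDATA":
                if value.replace(" ", "") != "(X++(Y..Y))":
                    raise UnsupportedDialectError(f"unsupported XYDATA form {value!r}")
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            labels[key] = value
            continue
        if in_data:
            data_lines.append(line)
    if not data_lines:
        raise DataError(f"no XYDATA in {path}")
    for key in ("FIRSTX", "LASTX", "NPOINTS"):
        if key not in labels:
            raise FormatError(f"missing JCAMP label ##{key}")
    if any(c in "".join(data_lines) for c in "ABCDEFGHIJKLMNOPQRSjklmnopqrs%@"):
        raise UnsupportedDialectError("compressed (non-AFFN) JCAMP data")
    first_x = float(labels["FIRSTX"])
    last_x = float(labels["LASTX"])
    npoints = int(labels["NPOINTS"])
    yfactor = float(labels.get("YFACTOR", "1"))
    ys: list[float] = []
    for line in data_lines:
        nums = [float(t) for t in re.split(r"[,\s]+", line) if t]
        ys.extend(nums[1:])  # first number per line is the X check value
    if len(ys) != npoints:
        raise DataError(f"expected {npoints} Y values, got {len(ys)}")
    wl = np.linspace(first_x, last_x, npoints)
    order = np.argsort(wl)
    return Spectrum(
        grid=WavelengthGrid(wl[order]),
        intensities=np.array(ys)[order] * yfactor,
        modality=modality,
        solvent=solvent,
        sample_id=labels.get("TITLE", ""),
    )


# ---------------------------------------------------------------------------
# Dataset manifest
# ---------------------------------------------------------------------------


@dataclass
class ManifestEntry:
    sample_id: str
    role: str  # "train" | "test"
    files: dict[str, str]  # block key "CD_DCE" -> relative path
    composition: dict[str, dict[str, float]] | None = None  # analyte -> {R_mM, S_mM}

    def __post_init__(self):
        if self.role not in ("train", "test"):
            raise DataError(f"role must be train|test, got {self.role!r}")


@dataclass
class DatasetManifest:
    """Maps samples to spectra files and (for training rows) known compositions."""

    samples: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.samples:
            return
        block_keys = set(self.samples[0].files)
        for entry in self.samples:
            if set(entry.files) != block_keys:
                raise AlignmentError(
                    f"sample {entry.sample_id!r} references blocks {sorted(entry.files)} "
                    f"but expected {sorted(block_keys)}"
                )
            if entry.role == "train" and not entry.composition:
                raise DataError(f"training sample {entry.sample_id!r} lacks a composition")

    @property
    def block_keys(self) -> list[str]:
        return sorted(self.samples[0].files) if self.samples else []

    def to_dict(self) -> dict:
        out = {"samples": []}
        for e in self.samples:
            d = {"id": e.sample_id, "role": e.role, "files": dict(e.files)}
            if e.composition is not None:
                d["composition"] = {a: dict(v) for a, v in e.composition.items()}
            out["samples"].append(d)
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "DatasetManifest":
        entries = []
        for d in data.get("samples", []):
            entries.append(
                ManifestEntry(
                    sample_id=str(d["id"]),
                    role=d["role"],
                    files={k: str(v) for k, v in d["files"].items()},
                    composition=d.get("composition"),
                )
            )
        return cls(samples=entries)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)
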