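"""Bridge between on-disk artifacts (spectrum CSVs + manifest) and in-memory datasets."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import AlignmentError, DataError
from .preprocessing import MultiBlockDataset, SpectralBlock
from .spectra_io import (
    BLOCK_KEYS,
    DatasetManifest,
    ManifestEntry,
    Spectrum,
    read_spectrum_csv,
    write_spectrum_csv,
)
from .synthetic import ENANTIOMER_LABELS


def _block_key_str(name: tuple[str, str]) -> str:
    return f"{name[0]}_{name[1]}"


def write_dataset(dataset: MultiBlockDataset, out_dir: str | Path) -> Path:
    """Write per-sample spectrum CSVs and a JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, sid in enumerate(dataset.sample_ids):
        files = {}
        for block in dataset.blocks:
            key = _block_key_str(block.name)
            fname = f"{sid}_{key}.csv"
            spectrum = Spectrum(
                grid=block.grid,
                intensities=block.matrix[i],
                modality=block.name[0],
                solvent=block.name[1],
                sample_id=sid,
            )
            write_spectrum_csv(spectrum, out_dir / fname)
            files[key] = fname
        composition: dict[str, dict[str, float]] = {}
        for j, (analyte, label) in enumerate(dataset.channel_names):
            entry = composition.setdefault(analyte, {})
            kind = "R_mM" if label == ENANTIOMER_LABELS[analyte][0] else "S_mM"
            entry[kind] = float(dataset.Y[i, j])
        role = dataset.roles[i] if dataset.roles is not None else "train"
        entries.append(
            ManifestEntry(sample_id=sid, role=role, files=files, composition=composition)
        )
    manifest = DatasetManifest(samples=entries)
    manifest_path = out_dir / "manifest.json"
    manifest.save(manifest_path)
    return manifest_path


def load_dataset(manifest_path: str | Path) -> MultiBlockDataset:
    """Assemble a MultiBlockDataset from a manifest and its spectrum CSVs.

    Blocks follow canonical order (CD before UV, DCE before MeOH); only blocks
    present in the manifest are loaded. Test rows without a composition get
    NaN responses.
    """
    manifest_path = Path(manifest_path)
    manifest = DatasetManifest.load(manifest_path)
    base = manifest_path.parent
    if not manifest.samples:
        raise DataError("empty manifest")

    keys = [k for k in BLOCK_KEYS if _block_key_str(k) in manifest.samples[0].files]
    if not keys:
        raise DataError("manifest references no recognized (modality, solvent) blocks")

    analytes = []
    for e in manifest.samples:
        if e.composition:
            analytes = list(e.composition)
            break
    if not analytes:
        raise DataError("no sample with a known composition; cannot define channels")
    channels = []
    for a in analytes:
        lab_r, lab_s = ENANTIOMER_LABELS.get(a, ("R", "S"))
        channels.append((a, lab_r))
        channels.append((a, lab_s))

    sample_ids = [e.sample_id for e in manifest.samples]
    matrices: dict[tuple[str, str], list[np.ndarray]] = {k: [] for k in keys}
    grid = None
    for e in manifest.samples:
        for key in keys:
            spectrum = read_spectrum_csv(base / e.files[_block_key_str(key)])
            if (spectrum.modality, spectrum.solvent) != key:
                raise AlignmentError(
                    f"file for {e.sample_id}/{key} declares "
                    f"({spectrum.modality}, {spectrum.solvent})"
                )
            if grid is None:
                grid = spectrum.grid
            elif spectrum.grid != grid:
                raise AlignmentError("all spectra must share one wavelength grid")
            matrices[key].append(spectrum.intensities)

    blocks = [
        SpectralBlock(name=k, matrix=np.asarray(matrices[k]), grid=grid, sample_ids=sample_ids)
        for k in keys
    ]
    Y = np.full((len(sample_ids), len(channels)), np.nan)
    for i, e in enumerate(manifest.samples):
        if not e.composition:
            continue
        for j, (analyte, label) in enumerate(channels):
            comp = e.composition.get(analyte)
            if comp is None:
                raise DataError(f"sample {e.sample_id} lacks composition for {analyte}")
            kind = "R_mM" if label == ENANTIOMER_LABELS.get(analyte, ("R", "S"))[0] else "S_mM"
            Y[i, j] = float(comp[kind])
    roles = [e.role for e in manifest.samples]
    return MultiBlockDataset(blocks=blocks, Y=Y, channel_names=channels, roles=roles)
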