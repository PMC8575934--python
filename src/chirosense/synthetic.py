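"""Synthetic forward model: Gaussian band bases, linear mixture spectra, noise,
and the quaternary/octonary campaign designs.

The model is strictly additive: UV responds to total analyte concentration,
CD responds to the R-S concentration difference, and the S-enantiomer CD basis
is exactly the negated R basis. Band parameters are fixed presets chosen to
honour the qualitative constraints of the sensing chemistry (zero crossings,
silent wavelengths, solvent dependence); they are presets, not fits.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError, IllPosedDesignError, PresetLookupError
from .preprocessing import MultiBlockDataset, SpectralBlock
from .spectra_io import SOLVENTS, Spectrum, WavelengthGrid, default_grid

_FOUR_LN2 = 4.0 * np.log(2.0)

ANALYTES = ("PEA", "PMP", "PGL", "PPA")

#: Configuration labels per analyte: (label of the + convention, label of the -).
ENANTIOMER_LABELS = {
    "PEA": ("R", "S"),
    "PMP": ("R", "S"),
    "PGL": ("R", "S"),
    "PPA": ("1R,2S", "1S,2R"),
}


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian band: response-per-mM amplitude at the band centre."""

    center_nm: float
    fwhm_nm: float
    amplitude: float

    def __post_init__(self):
        if self.fwhm_nm <= 0:
            raise DataError("fwhm must be positive")
        if not 230.0 <= self.center_nm <= 470.0:
            raise DataError("band centre must lie within [230, 470] nm")


def gaussian_band(grid: WavelengthGrid, band: BandSpec) -> np.ndarray:
    """v(l) = amplitude * exp(-4 ln2 (l - center)^2 / fwhm^2)."""
    d = grid.values - band.center_nm
    return band.amplitude * np.exp(-_FOUR_LN2 * d * d / band.fwhm_nm**2)


@dataclass
class ComponentBasis:
    """Per-solvent UV and CD band sets for one analyte.

    ``cd_bands`` describe the R-convention adduct (for PPA, the (1R,2S)
    diastereomer); the S basis is its exact negation and UV is shared.
    """

    analyte: str
    uv_bands: dict[str, list[BandSpec]]  # solvent -> bands, amplitudes >= 0
    cd_bands: dict[str, list[BandSpec]]  # solvent -> bands, signed

    def __post_init__(self):
        for solvent, bands in self.uv_bands.items():
            if any(b.amplitude < 0 for b in bands):
                raise DataError(f"UV band amplitudes must be >= 0 ({self.analyte}/{solvent})")

    def uv(self, grid: WavelengthGrid, solvent: str) -> np.ndarray:
        """Molar UV response epsilon(l) per mM total; identical for both enantiomers."""
        return sum((gaussian_band(grid, b) for b in self.uv_bands[solvent]), np.zeros(len(grid)))

    def cd(self, grid: WavelengthGrid, solvent: str, enantiomer: str = "R") -> np.ndarray:
        """Molar CD response per mM for one enantiomer; S = -R by convention."""
        base = sum((gaussian_band(grid, b) for b in self.cd_bands[solvent]), np.zeros(len(grid)))
        if enantiomer == "R":
            return base
        if enantiomer == "S":
            return -base
        raise DataError(f"enantiomer must be 'R' or 'S', got {enantiomer!r}")


# Preset band tables. CD amplitudes in mdeg per mM of (c_R - c_S); UV in AU per
# mM total. Constraints honoured on the canonical grid:
#   * PMP CD (DCE) crosses zero at 340 nm (symmetric +/- band pair), strong at 400 nm
#   * PEA CD (DCE) is silent at 400 nm but strong at 340 nm
#   * PMP CD nearly solvent-independent; PEA/PPA CD change markedly with solvent
#   * band mass concentrated in 270-320 / 360-430 nm (CD), 270-330 / 400-450 nm (UV)
_PRESETS: dict[str, dict[str, dict[str, list[tuple[float, float, float]]]]] = {
    "PEA": {
        "cd": {
            "DCE": [(288, 36, 22.0), (332, 40, -18.0)],
            "MeOH": [(295, 40, 10.0), (345, 45, 16.0)],
        },
        "uv": {
            "DCE": [(272, 34, 1.30), (412, 38, 0.85)],
            "MeOH": [(280, 38, 1.15), (408, 42, 0.78)],
        },
    },
    "PMP": {
        "cd": {
            "DCE": [(300, 46, 28.0), (380, 46, -28.0)],
            "MeOH": [(302, 46, 26.0), (378, 46, -27.0)],
        },
        "uv": {
            "DCE": [(318, 38, 1.05), (443, 30, 0.95)],
            "MeOH": [(320, 38, 1.00), (441, 32, 0.90)],
        },
    },
    "PGL": {
        "cd": {
            "DCE": [(285, 38, 14.0), (368, 50, 9.0)],
            "MeOH": [(290, 40, 8.0), (372, 52, -10.0)],
        },
        "uv": {
            # solvent-sensitive aromatic band pattern, distinct in DCE
            "DCE": [(284, 28, 1.20), (400, 28, 0.70)],
            "MeOH": [(292, 40, 1.00), (424, 42, 0.60)],
        },
    },
    "PPA": {
        "cd": {
            "DCE": [(272, 34, -12.0), (352, 42, 16.0)],
            "MeOH": [(283, 40, 9.0), (368, 48, 13.0)],
        },
        "uv": {
            # strikingly different from PEA in DCE, similar to PEA in MeOH
            "DCE": [(302, 32, 1.10), (438, 32, 0.75)],
            "MeOH": [(283, 40, 1.10), (410, 44, 0.75)],
        },
    },
}


def make_preset_basis(analyte: str) -> ComponentBasis:
    """Return the fixed-parameter basis for one of PEA, PMP, PGL, PPA."""
    if analyte not in _PRESETS:
        raise PresetLookupError(analyte)
    p = _PRESETS[analyte]
    return ComponentBasis(
        analyte=analyte,
        uv_bands={s: [BandSpec(*b) for b in p["uv"][s]] for s in SOLVENTS},
        cd_bands={s: [BandSpec(*b) for b in p["cd"][s]] for s in SOLVENTS},
    )


@dataclass(frozen=True)
class MixtureComposition:
    """Per-analyte (c_R, c_S) concentrations in mM."""

    concentrations: dict[str, tuple[float, float]]

    def __post_init__(self):
        for analyte, (c_r, c_s) in self.concentrations.items():
            if not (np.isfinite(c_r) and np.isfinite(c_s)):
                raise DataError(f"non-finite concentration for {analyte}")
            if c_r < 0 or c_s < 0:
                raise DataError(f"negative concentration for {analyte}")

    @property
    def analytes(self) -> list[str]:
        return list(self.concentrations)

    def total(self, analyte: str) -> float:
        c_r, c_s = self.concentrations[analyte]
        return c_r + c_s

    def diff(self, analyte: str) -> float:
        c_r, c_s = self.concentrations[analyte]
        return c_r - c_s

    def mirrored(self) -> "MixtureComposition":
        """Swap R and S for every analyte."""
        return MixtureComposition({a: (s, r) for a, (r, s) in self.concentrations.items()})


@dataclass(frozen=True)
class NoiseModel:
    """Instrument noise: y -> y*(1 + N(0, mult_sd)) + N(0, add_sd).

    ``additive_sd_fraction`` is a fraction of the dataset-wide max |signal|
    of the modality the noise is applied to.
    """

    multiplicative_sd: float = 0.01
    additive_sd_fraction: float = 0.003
    seed: int = 0

    def __post_init__(self):
        if self.multiplicative_sd < 0 or self.additive_sd_fraction < 0:
            raise DataError("noise standard deviations must be >= 0")

    def apply(self, signal: np.ndarray, scale: float, rng: np.random.Generator) -> np.ndarray:
        mult = rng.normal(0.0, self.multiplicative_sd, size=signal.shape)
        add = rng.normal(0.0, self.additive_sd_fraction * scale, size=signal.shape)
        return signal * (1.0 + mult) + add


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    """Per-sample stream via stable hashing so added samples never reshuffle others."""
    digest = hashlib.sha256(f"{seed}:{sample_id}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def simulate_mixture(
    bases: list[ComponentBasis],
    comp: MixtureComposition,
    solvent: str,
    noise: NoiseModel | None = None,
    grid: WavelengthGrid | None = None,
    sample_id: str = "sample",
    rng: np.random.Generator | None = None,
    additive_scales: dict[str, float] | None = None,
) -> tuple[Spectrum, Spectrum]:
    """Noiseless-linear (optionally noised) CD and UV spectra of a mixture.

    CD(l) = sum_i diff_i * cd_i(l); UV(l) = sum_i total_i * uv_i(l).
    When ``additive_scales`` is not given, the additive noise scale defaults to
    this sample's own max |signal| per modality.
    """
    grid = grid or default_grid()
    basis_map = {b.analyte: b for b in bases}
    missing = [a for a in comp.analytes if a not in basis_map]
    if missing:
        raise ConfigurationError(f"no basis provided for analytes {missing}")
    cd = np.zeros(len(grid))
    uv = np.zeros(len(grid))
    for analyte in comp.analytes:
        basis = basis_map[analyte]
        cd += comp.diff(analyte) * basis.cd(grid, solvent)
        uv += comp.total(analyte) * basis.uv(grid, solvent)
    if noise is not None:
        rng = rng if rng is not None else _sample_rng(noise.seed, sample_id)
        scales = additive_scales or {
            "CD": float(np.max(np.abs(cd))),
            "UV": float(np.max(np.abs(uv))),
        }
        cd = noise.apply(cd, scales["CD"], rng)
        uv = noise.apply(uv, scales["UV"], rng)
    return (
        Spectrum(grid=grid, intensities=cd, modality="CD", solvent=solvent, sample_id=sample_id),
        Spectrum(grid=grid, intensities=uv, modality="UV", solvent=solvent, sample_id=sample_id),
    )


DESIGNS = {
    "quaternary": {"analytes": ("PEA", "PMP"), "solvents": ("DCE",)},
    "octonary": {"analytes": ("PEA", "PMP", "PGL", "PPA"), "solvents": ("DCE", "MeOH")},
}

DEFAULT_CONC_RANGE = {"quaternary": (0.0, 13.0), "octonary": (0.0, 5.0)}


def design_channels(design: str) -> list[tuple[str, str]]:
    """(analyte, enantiomer-label) channel names in canonical order."""
    spec = DESIGNS[design]
    channels = []
    for analyte in spec["analytes"]:
        lab_r, lab_s = ENANTIOMER_LABELS[analyte]
        channels.append((analyte, lab_r))
        channels.append((analyte, lab_s))
    return channels


def simulate_design(
    design: str,
    n_train: int,
    n_test: int,
    conc_range: tuple[float, float] | None = None,
    seed: int = 0,
    noise: NoiseModel | None = None,
    grid: WavelengthGrid | None = None,
) -> MultiBlockDataset:
    """Generate a full campaign: train + test mixtures, all blocks, Y matrix.

    quaternary: blocks (CD,DCE),(UV,DCE) over PEA+PMP, 4 response channels;
    octonary: four blocks over PEA+PMP+PGL+PPA, 8 channels. Per-enantiomer
    concentrations are drawn uniformly on ``conc_range``. Reproducible under
    ``seed``; per-sample streams are derived by stable hashing.
    """
    if design not in DESIGNS:
        raise ConfigurationError(f"design must be one of {sorted(DESIGNS)}")
    spec = DESIGNS[design]
    analytes = spec["analytes"]
    solvents = spec["solvents"]
    channels = design_channels(design)
    if n_train < len(channels):
        raise IllPosedDesignError(
            f"{design} design needs n_train >= {len(channels)}, got {n_train}"
        )
    if n_test < 0:
        raise ConfigurationError("n_test must be >= 0")
    lo, hi = conc_range if conc_range is not None else DEFAULT_CONC_RANGE[design]
    grid = grid or default_grid()
    bases = [make_preset_basis(a) for a in analytes]

    sample_ids = [f"train-{i + 1:02d}" for i in range(n_train)] + [
        f"test-{i + 1:02d}" for i in range(n_test)
    ]
    roles = ["train"] * n_train + ["test"] * n_test

    comps = []
    for sid in sample_ids:
        rng = _sample_rng(seed, f"comp:{sid}")
        comps.append(
            MixtureComposition(
                {a: (rng.uniform(lo, hi), rng.uniform(lo, hi)) for a in analytes}
            )
        )

    # Noiseless signals first: additive noise scales with the dataset-wide
    # max |signal| per modality, which must not depend on the noise draws.
    clean: dict[tuple[str, str], list[np.ndarray]] = {
        ("CD", s): [] for s in solvents
    } | {("UV", s): [] for s in solvents}
    for sid, comp in zip(sample_ids, comps):
        for solvent in solvents:
            cd, uv = simulate_mixture(bases, comp, solvent, noise=None, grid=grid, sample_id=sid)
            clean[("CD", solvent)].append(cd.intensities)
            clean[("UV", solvent)].append(uv.intensities)

    scales = {
        mod: max(
            float(np.max(np.abs(np.asarray(clean[(mod, s)])))) for s in solvents
        )
        for mod in ("CD", "UV")
    }

    blocks = []
    block_order = [(m, s) for m in ("CD", "UV") for s in solvents]
    noisy: dict[tuple[str, str], list[np.ndarray]] = {k: [] for k in block_order}
    for i, sid in enumerate(sample_ids):
        if noise is None:
            for key in block_order:
                noisy[key].append(clean[key][i])
        else:
            rng = _sample_rng(noise.seed + seed, f"noise:{sid}")
            for key in block_order:
                mod = key[0]
                noisy[key].append(noise.apply(clean[key][i], scales[mod], rng))
    for key in block_order:
        blocks.append(
            SpectralBlock(
                name=key,
                matrix=np.asarray(noisy[key]),
                grid=grid,
                sample_ids=list(sample_ids),
            )
        )

    Y = np.zeros((len(sample_ids), len(channels)))
    for i, comp in enumerate(comps):
        for j, (analyte, label) in enumerate(channels):
            c_r, c_s = comp.concentrations[analyte]
            Y[i, j] = c_r if label == ENANTIOMER_LABELS[analyte][0] else c_s

    return MultiBlockDataset(blocks=blocks, Y=Y, channel_names=channels, roles=roles)
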