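"""Chemistry-facing outputs: total concentration, er, ee, absolute configuration,
the univariate complementary-wavelength er mode, and campaign evaluation reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CalibrationError, DataError
from .model_selection import r2 as _r2
from .model_selection import rmse as _rmse
from .pipelines import Pipeline, PipelineConfig
from .preprocessing import MultiBlockDataset
from .synthetic import ENANTIOMER_LABELS

#: |ee| below this is reported as racemic.
RACEMATE_EE_THRESHOLD = 0.01

#: Default complementary readout wavelengths (nm): PEA read where PMP crosses
#: zero; PMP read where PEA is silent.
COMPLEMENTARY_WAVELENGTHS = {"PEA": 340.0, "PMP": 400.0}


@dataclass
class ChiralityEntry:
    analyte: str
    total_mM: float
    er: tuple[float, float]  # (major, minor), one decimal, sums to 100
    ee: float
    major: str  # configuration label, "rac", or "undefined"
    er_defined: bool = True


def derive_chirality(
    c_R: float, c_S: float, analyte: str = "", clip: bool = False
) -> ChiralityEntry:
    """Total, er (major:minor to one decimal), ee and major configuration.

    Negative inputs are kept raw unless ``clip`` is set. A non-positive total
    yields an undefined-er entry with the total still reported.
    """
    if not (np.isfinite(c_R) and np.isfinite(c_S)):
        raise DataError("concentrations must be finite")
    if clip:
        c_R, c_S = max(c_R, 0.0), max(c_S, 0.0)
    total = c_R + c_S
    label_r, label_s = ENANTIOMER_LABELS.get(analyte, ("R", "S"))
    if total <= 0:
        return ChiralityEntry(
            analyte=analyte,
            total_mM=total,
            er=(float("nan"), float("nan")),
            ee=float("nan"),
            major="undefined",
            er_defined=False,
        )
    major_c, minor_c = (c_R, c_S) if c_R >= c_S else (c_S, c_R)
    major_pct = round(100.0 * major_c / total, 1)
    er = (major_pct, round(100.0 - major_pct, 1))
    ee = (er[0] - er[1]) / 100.0
    if abs(c_R - c_S) / total < RACEMATE_EE_THRESHOLD:
        major = "rac"
    else:
        major = label_r if c_R > c_S else label_s
    return ChiralityEntry(
        analyte=analyte, total_mM=total, er=er, ee=ee, major=major
    )


def chirality_results(
    Y_pred: np.ndarray,
    channel_names: list[tuple[str, str]],
    clip: bool = False,
) -> list[list[ChiralityEntry]]:
    """Per-sample chirality entries from a predicted concentration matrix."""
    Y_pred = np.atleast_2d(np.asarray(Y_pred, float))
    analytes: list[str] = []
    for analyte, _ in channel_names:
        if analyte not in analytes:
            analytes.append(analyte)
    out = []
    for row in Y_pred:
        entries = []
        for analyte in analytes:
            lab_r = ENANTIOMER_LABELS.get(analyte, ("R", "S"))[0]
            c_r = c_s = 0.0
            for j, (a, label) in enumerate(channel_names):
                if a != analyte:
                    continue
                if label == lab_r:
                    c_r = float(row[j])
                else:
                    c_s = float(row[j])
            entries.append(derive_chirality(c_r, c_s, analyte=analyte, clip=clip))
        out.append(entries)
    return out


# ---------------------------------------------------------------------------
# Univariate complementary-wavelength mode
# ---------------------------------------------------------------------------


@dataclass
class UnivariateCalibration:
    analyte: str
    wavelength_nm: float
    slope: float  # mdeg per (ee * mM), i.e. per (c_R - c_S)
    intercept: float


def univariate_calibrate(
    points: list[tuple[float, float]], analyte: str, wavelength_nm: float
) -> UnivariateCalibration:
    """OLS line through (signed composition c_R - c_S, CD value at wavelength).

    ``points`` are (cd_value, c_R - c_S) pairs from samples of known composition.
    """
    if len(points) < 3:
        raise CalibrationError("need at least 3 calibration points")
    cd = np.array([p[0] for p in points], float)
    x = np.array([p[1] for p in points], float)
    if np.ptp(x) == 0:
        raise CalibrationError("degenerate calibration design: all compositions equal")
    slope, intercept = np.polyfit(x, cd, 1)
    if slope == 0:
        raise CalibrationError("zero calibration slope")
    return UnivariateCalibration(
        analyte=analyte, wavelength_nm=wavelength_nm, slope=float(slope), intercept=float(intercept)
    )


def univariate_predict_er(
    cal: UnivariateCalibration, cd_value: float, total_mM: float
) -> ChiralityEntry:
    """Invert the calibration line; requires the total concentration to be known."""
    if total_mM <= 0:
        raise DataError("total concentration must be positive")
    diff = (cd_value - cal.intercept) / cal.slope
    ee_signed = diff / total_mM
    if abs(ee_signed) > 1:
        warnings.warn(
            f"predicted |ee| = {abs(ee_signed):.3f} > 1; clipped to 1", stacklevel=2
        )
        ee_signed = float(np.clip(ee_signed, -1.0, 1.0))
    c_r = total_mM * (1 + ee_signed) / 2
    c_s = total_mM * (1 - ee_signed) / 2
    return derive_chirality(c_r, c_s, analyte=cal.analyte)


# ---------------------------------------------------------------------------
# Campaign evaluation
# ---------------------------------------------------------------------------

#: Left-closed absolute-error bins in mM, mirroring the green -> yellow heat map.
ERROR_BINS = ((0.0, 0.5, "green"), (0.5, 1.5, "yellow"), (1.5, float("inf"), "red"))


def bin_error(abs_error_mM: float) -> str:
    for lo, hi, label in ERROR_BINS:
        if lo <= abs_error_mM < hi:
            return label
    return ERROR_BINS[-1][2]


@dataclass
class CampaignReport:
    config: PipelineConfig
    channel_names: list[tuple[str, str]]
    test_sample_ids: list[str]
    Y_true: np.ndarray
    Y_pred: np.ndarray
    abs_errors: np.ndarray
    bins: list[list[str]]
    test_rmse: float
    test_r2: float
    cv_rmse: float | None = None
    cv_r2: float | None = None
    extras: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, sid in enumerate(self.test_sample_ids):
            for j, (analyte, label) in enumerate(self.channel_names):
                rows.append(
                    {
                        "sample_id": sid,
                        "analyte": analyte,
                        "enantiomer": label,
                        "actual_mM": self.Y_true[i, j],
                        "predicted_mM": self.Y_pred[i, j],
                        "abs_error_mM": self.abs_errors[i, j],
                        "bin": self.bins[i][j],
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "method": self.config.method,
            "scaling": self.config.scaling,
            "k": self.config.k,
            "test_rmse_mM": self.test_rmse,
            "test_r2": self.test_r2,
            "cv_rmse_mM": self.cv_rmse,
            "cv_r2": self.cv_r2,
            "cells": self.to_frame().to_dict(orient="records"),
        }


def evaluate_campaign(
    dataset: MultiBlockDataset,
    config: PipelineConfig,
    cv_rmse: float | None = None,
) -> CampaignReport:
    """Fit on train rows, predict test rows, bin absolute errors heat-map style."""
    train, test = dataset.split()
    if test.n_samples == 0:
        raise DataError("dataset has no test samples")
    if not np.all(np.isfinite(test.Y)):
        raise DataError("test compositions must be known for evaluation")
    pipeline = Pipeline(config).fit(train)
    Y_pred = pipeline.predict(test.blocks)
    abs_err = np.abs(Y_pred - test.Y)
    bins = [[bin_error(e) for e in row] for row in abs_err]
    return CampaignReport(
        config=config,
        channel_names=list(dataset.channel_names),
        test_sample_ids=test.sample_ids,
        Y_true=test.Y,
        Y_pred=Y_pred,
        abs_errors=abs_err,
        bins=bins,
        test_rmse=_rmse(test.Y, Y_pred),
        test_r2=_r2(test.Y, Y_pred),
        cv_rmse=cv_rmse,
    )
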