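"""Band integration, inverse calibration and test-set prediction.

The quantitative response is the trapezoidal area of the preprocessed
spectrum over the adenine ring-breathing window (715-750 cm^-1 by
default).  Calibration is *inverse*: concentration is regressed on the
response, ``c = b0 + b1 * area``, so predictions come straight from the
fitted line.  A model is suitable when r^2 >= 0.6 and the overall-
regression F-test p-value is <= 0.01; unsuitable models predict nothing
(the laboratory's experiment is rejected).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .spectra import ADENINE_WINDOW, Dataset, MethodId, Spectrum

__all__ = [
    "CalibrationModel",
    "PredictionRecord",
    "band_area",
    "sample_response",
    "fit_inverse_calibration",
    "predict",
    "run_experiment",
    "R2_THRESHOLD",
    "F_PVALUE_THRESHOLD",
]

R2_THRESHOLD = 0.6
F_PVALUE_THRESHOLD = 0.01


@dataclass(frozen=True)
class CalibrationModel:
    """Inverse-regression line with its suitability statistics."""

    intercept: float  # b0, uM
    slope: float  # b1, uM per area unit
    r_squared: float
    f_statistic: float
    f_pvalue: float
    n_points: int
    cal_range: tuple[float, float]  # (min, max) reference concentration, uM
    suitable: bool
    reasons: tuple[str, ...] = ()  # non-empty iff not suitable

    @property
    def cal_width(self) -> float:
        return self.cal_range[1] - self.cal_range[0]


@dataclass(frozen=True)
class PredictionRecord:
    """One test sample: reference vs predicted concentration."""

    lab_id: str
    method: MethodId
    level_id: str
    reference_uM: float
    predicted_uM: float
    flags: tuple[str, ...] = ()

    @property
    def residual(self) -> float:
        """predicted - reference, uM."""
        return self.predicted_uM - self.reference_uM


def band_area(s: Spectrum, lo: float = ADENINE_WINDOW[0], hi: float = ADENINE_WINDOW[1]) -> float:
    """Trapezoidal integral of intensity over the closed window [lo, hi]."""
    if not s.covers(lo, hi):
        raise ValueError(
            f"axis [{s.wavenumber[0]}, {s.wavenumber[-1]}] does not cover [{lo}, {hi}]"
        )
    mask = (s.wavenumber >= lo) & (s.wavenumber <= hi)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 grid points inside the band window")
    return float(np.trapezoid(s.intensity[mask], s.wavenumber[mask]))


def sample_response(spectra: Sequence[Spectrum], lo: float = ADENINE_WINDOW[0], hi: float = ADENINE_WINDOW[1]) -> float:
    """Arithmetic mean band area over a sample's replicates."""
    if not spectra:
        raise ValueError("sample_response needs >= 1 replicate")
    return float(np.mean([band_area(s, lo, hi) for s in spectra]))


def fit_inverse_calibration(pairs: Sequence[tuple[float, float]]) -> CalibrationModel:
    """OLS of concentration on band area over (area, concentration) pairs.

    Computes r^2 and the overall-regression F statistic (for simple
    linear regression F = t^2 of the slope) with its p-value, and sets
    the suitability flag: r^2 >= 0.6 and F p-value <= 0.01.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (area, concentration) tuples")
    x, y = arr[:, 0], arr[:, 1]
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 calibration points for the F-test")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all areas equal")

    sxx = float(np.sum((x - x.mean()) ** 2))
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    syy = float(np.sum((y - y.mean()) ** 2))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    ssr = slope * sxy  # regression sum of squares
    sse = max(syy - ssr, 0.0)
    r2 = 1.0 if syy == 0 else ssr / syy
    dof = n - 2
    if sse <= 0 or dof == 0:
        f_stat, f_p = np.inf, 0.0
    else:
        f_stat = ssr / (sse / dof)
        f_p = float(stats.f.sf(f_stat, 1, dof))

    reasons = []
    if r2 < R2_THRESHOLD:
        reasons.append(f"r2 below {R2_THRESHOLD}")
    if f_p > F_PVALUE_THRESHOLD:
        reasons.append(f"F p-value above {F_PVALUE_THRESHOLD}")
    return CalibrationModel(
        intercept=intercept,
        slope=slope,
        r_squared=float(r2),
        f_statistic=float(f_stat),
        f_pvalue=f_p,
        n_points=n,
        cal_range=(float(y.min()), float(y.max())),
        suitable=not reasons,
        reasons=tuple(reasons),
    )


def predict(model: CalibrationModel, area: float, allow_unsuitable: bool = False) -> float:
    """Predicted concentration b0 + b1*area (uM); never clipped."""
    if not model.suitable and not allow_unsuitable:
        raise ValueError(f"model not suitable ({'; '.join(model.reasons)})")
    return model.intercept + model.slope * area


def run_experiment(
    ds: Dataset,
    band_window: tuple[float, float] = ADENINE_WINDOW,
    replicate_handling: str = "mean",
) -> tuple[CalibrationModel, list[PredictionRecord]]:
    """Single-experiment validation: calibrate, then predict the test set.

    Calibration samples are grouped by level; by default the replicate
    band areas are averaged into one response per standard
    (``replicate_handling="mean"``); ``"all"`` instead fits every
    replicate as its own point.  An unsuitable model yields an empty
    record list (the reasons live on the returned model).
    """
    if replicate_handling not in ("mean", "all"):
        raise ValueError("replicate_handling must be 'mean' or 'all'")

    by_level: dict[str, list[Spectrum]] = {}
    for s in ds.calibration_spectra:
        by_level.setdefault(s.meta.level_id, []).append(s)
    pairs: list[tuple[float, float]] = []
    for level in sorted(by_level):
        reps = by_level[level]
        conc = reps[0].meta.concentration_uM
        if replicate_handling == "mean":
            pairs.append((sample_response(reps, *band_window), conc))
        else:
            pairs.extend((band_area(s, *band_window), conc) for s in reps)
    model = fit_inverse_calibration(pairs)
    if not model.suitable:
        ds.log(f"calibration rejected: {'; '.join(model.reasons)}")
        return model, []

    records: list[PredictionRecord] = []
    test_by_level: dict[str, list[Spectrum]] = {}
    for s in ds.test_spectra:
        test_by_level.setdefault(s.meta.level_id, []).append(s)
    for level in sorted(test_by_level):
        reps = test_by_level[level]
        ref = reps[0].meta.concentration_uM
        pred = predict(model, sample_response(reps, *band_window))
        flags = []
        if not model.cal_range[0] <= pred <= model.cal_range[1]:
            flags.append("outside calibration range")
        if pred < 0:
            flags.append("negative prediction")
        records.append(
            PredictionRecord(ds.lab_id, ds.method, level, float(ref), float(pred), tuple(flags))
        )
    return model, records
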