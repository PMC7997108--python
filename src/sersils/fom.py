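"""ISO 5725-style figures of merit from pooled prediction residuals.

For residuals ``e_i = predicted_i - reference_i`` (i = 1..n):

* ``BIAS = mean(e)``                       — trueness (systematic error)
* ``RMSEP = sqrt(mean(e^2))``              — accuracy (total error)
* ``SEP = sqrt(sum((e - BIAS)^2)/(n-1))``  — reproducibility (spread)

With these denominators the decomposition is the exact algebraic
identity ``RMSEP^2 = BIAS^2 + SEP^2 * (n-1)/n`` (the familiar
``RMSEP^2 ~ SEP^2 + BIAS^2`` holds approximately for large n).  The
n-1 convention for SEP is what makes published method tables in which
SEP exceeds RMSEP arithmetically possible.

FoMs from methods calibrated over different concentration ranges are
compared after dividing by the calibration reference range; the
reciprocal of the normalized SEP classifies a method (1/SEP > 4:
screening, > 10: quality control, > 15: quantification, strict
inequalities).  Outlying residuals are never removed from the FoMs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FoMSet",
    "compute_foms",
    "normalize_foms",
    "bias_test",
    "iso_identity_check",
    "quality_class",
    "QUALITY_THRESHOLDS",
]

#: strict lower thresholds on 1/SEP_norm for each acceptability class
QUALITY_THRESHOLDS = (("quantification", 15.0), ("quality-control", 10.0), ("screening", 4.0))

BIAS_ALPHA = 0.01  # t-test on the mean residual, 99% confidence


@dataclass(frozen=True)
class FoMSet:
    """Raw and (optionally) range-normalized figures of merit."""

    n: int
    rmsep: float
    sep: float
    bias: float  # signed
    bias_t: float
    bias_p: float
    bias_significant: bool  # two-sided, alpha = 0.01
    # filled by normalize_foms:
    rmsep_norm: float | None = None  # fractions of the normalization range
    sep_norm: float | None = None
    bias_norm: float | None = None
    inv_sep_norm: float | None = None
    quality_class: str | None = None


def compute_foms(residuals: Sequence[float]) -> FoMSet:
    """Figures of merit of a pooled residual vector (n >= 2).

    Outliers are deliberately not screened out: removing them would only
    flatter the numbers without preventing future outlying results.
    """
    e = np.asarray(residuals, dtype=float)
    if e.ndim != 1 or e.size < 2:
        raise ValueError("need a 1-D residual vector with n >= 2")
    n = e.size
    bias = float(e.mean())
    rmsep = float(np.sqrt(np.mean(e**2)))
    sep = float(np.sqrt(np.sum((e - bias) ** 2) / (n - 1)))
    t, p, sig = bias_test(e)
    return FoMSet(n=n, rmsep=rmsep, sep=sep, bias=bias, bias_t=t, bias_p=p, bias_significant=sig)


def quality_class(inv_sep_norm: float) -> str:
    for label, threshold in QUALITY_THRESHOLDS:
        if inv_sep_norm > threshold:
            return label
    return "none"


def normalize_foms(f: FoMSet, ref_range: tuple[float, float]) -> FoMSet:
    """Divide RMSEP/SEP/BIAS by the calibration reference range width.

    Also derives ``1/SEP_norm`` and the acceptability class.
    """
    lo, hi = ref_range
    width = hi - lo
    if width <= 0:
        raise ValueError("normalization range must have positive width")
    sep_norm = f.sep / width
    inv = math.inf if sep_norm == 0 else 1.0 / sep_norm
    return replace(
        f,
        rmsep_norm=f.rmsep / width,
        sep_norm=sep_norm,
        bias_norm=f.bias / width,
        inv_sep_norm=inv,
        quality_class=quality_class(inv),
    )


def bias_test(residuals: Sequence[float], alpha: float = BIAS_ALPHA) -> tuple[float, float, bool]:
    """Two-sided one-sample t-test of mean residual = 0.

    Returns ``(t, p, significant)`` with significance at ``p < alpha``
    (99% confidence by default).  A zero-variance vector with nonzero
    mean is flagged significant with infinite t.
    """
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        raise ValueError("bias test needs n >= 2")
    if np.ptp(e) == 0:
        if e[0] == 0:
            return 0.0, 1.0, False
        return math.copysign(math.inf, e[0]), 0.0, True
    res = stats.ttest_1samp(e, 0.0)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


def iso_identity_check(f: FoMSet, tol: float = 1e-12) -> bool:
    """Verify RMSEP^2 = BIAS^2 + SEP^2*(n-1)/n to relative tolerance.

    This is an exact algebraic identity for the denominators used here;
    the looser textbook form RMSEP^2 ~ SEP^2 + BIAS^2 is only asymptotic.
    """
    lhs = f.rmsep**2
    rhs = f.bias**2 + f.sep**2 * (f.n - 1) / f.n
    scale = max(lhs, rhs, 1e-300)
    return abs(lhs - rhs) <= tol * scale
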