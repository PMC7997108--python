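"""Spectral preprocessing chain for quantitative SERS.

Stage order is fixed by the data-analysis protocol: Savitzky-Golay
smoothing, down-sampling onto a common axis, spectral-range selection,
baseline correction, and EMSC normalization against a per-dataset
reference.

EMSC (extended multiplicative signal correction) models each spectrum as
a multiplicative rescaling of a reference plus a smooth additive
polynomial, ``s(v) ~ b*ref(v) + sum_k a_k P_k(v)``, and returns
``(s - sum_k a_k P_k)/b``.  When the goal is quantification, the
coefficients must be estimated on spectral regions that do not vary with
analyte concentration, otherwise the analyte signal itself is absorbed
into ``b`` and normalized away; :func:`run_preprocess` therefore excludes
a window around the adenine band from the EMSC fit (the correction is
still applied to the full axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from numpy.polynomial import legendre
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from .spectra import Dataset, Spectrum

__all__ = [
    "PreprocessConfig",
    "smooth",
    "resample",
    "crop",
    "baseline_correct",
    "baseline_als",
    "baseline_arpls",
    "baseline_modpoly",
    "emsc",
    "median_reference",
    "run_preprocess",
]


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    Defaults follow common chemometrics practice for 1 cm^-1-resolved
    Raman spectra; every value is exposed so a protocol's own settings
    can be substituted verbatim.
    """

    smooth_window: int = 9
    smooth_polyorder: int = 2
    target_axis: tuple[float, float, float] | None = (400.0, 1800.0, 1.0)
    range_keep: tuple[float, float] = (400.0, 1800.0)
    baseline_method: str = "arpls"  # "arpls" | "als" | "iterative-polynomial"
    baseline_params: dict = field(default_factory=dict)
    baseline_shared_weights: bool = True
    emsc_poly_degree: int = 2
    emsc_reference: str = "median-of-calibration"  # or "supplied"
    emsc_exclude_band: tuple[float, float] | None = (660.0, 800.0)

    def __post_init__(self) -> None:
        if self.smooth_window % 2 == 0 or self.smooth_polyorder >= self.smooth_window:
            raise ValueError("smoothing window must be odd and > polyorder")
        if self.emsc_poly_degree < 0:
            raise ValueError("emsc_poly_degree must be >= 0")
        if self.target_axis is not None:
            lo, hi, step = self.target_axis
            if step <= 0 or hi <= lo:
                raise ValueError("target_axis must satisfy start < stop, step > 0")
            if not (lo <= self.range_keep[0] and self.range_keep[1] <= hi):
                raise ValueError("range_keep must lie within target_axis span")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        d = dict(d)
        for key in ("target_axis", "range_keep", "emsc_exclude_band"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def smooth(s: Spectrum, window: int = 9, polyorder: int = 2) -> Spectrum:
    """Savitzky-Golay least-squares polynomial smoothing; axis unchanged."""
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and > polyorder")
    if window > len(s):
        raise ValueError("smoothing window exceeds spectrum length")
    return s.with_intensity(savgol_filter(s.intensity, window, polyorder))


def resample(s: Spectrum, target_axis: np.ndarray | tuple[float, float, float]) -> Spectrum:
    """Linear interpolation onto a new axis; extrapolation is refused."""
    if isinstance(target_axis, tuple):
        lo, hi, step = target_axis
        axis = np.arange(lo, hi + step / 2, step)
    else:
        axis = np.asarray(target_axis, dtype=float)
    if axis[0] < s.wavenumber[0] - 1e-9 or axis[-1] > s.wavenumber[-1] + 1e-9:
        raise ValueError(
            f"target axis [{axis[0]}, {axis[-1]}] extends beyond source "
            f"[{s.wavenumber[0]}, {s.wavenumber[-1]}] (no extrapolation)"
        )
    return s.with_intensity(np.interp(axis, s.wavenumber, s.intensity), axis)


def crop(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep points with lo <= v <= hi (closed interval)."""
    mask = (s.wavenumber >= lo) & (s.wavenumber <= hi)
    if mask.sum() < 2:
        raise ValueError(f"crop to [{lo}, {hi}] leaves fewer than 2 points")
    return s.with_intensity(s.intensity[mask], s.wavenumber[mask])


# ---------------------------------------------------------------------------
# baselines


def _whittaker_solve(weights: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    # solve (W + lam * D2'D2) z = W y with a symmetric banded solver
    n = y.size
    d0 = np.full(n, 6.0)
    d0[[0, -1]] = 1.0
    d0[[1, -2]] = 5.0
    d1 = np.full(n - 1, -4.0)
    d1[[0, -1]] = -2.0
    d2 = np.ones(n - 2)
    ab = np.zeros((3, n))
    ab[0, 2:] = lam * d2
    ab[1, 1:] = lam * d1
    ab[2, :] = lam * d0 + weights
    return solveh_banded(ab, weights * y)


def _als_iterate(y: np.ndarray, lam: float = 1e5, p: float = 0.01, max_iter: int = 50):
    n = y.size
    if n < 5:
        raise ValueError("spectrum too short for ALS baseline")
    w = np.ones(n)
    z = np.zeros(n)
    for _ in range(max_iter):
        z = _whittaker_solve(w, y, lam)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z, w


def baseline_als(y: np.ndarray, lam: float = 1e5, p: float = 0.01, max_iter: int = 50) -> np.ndarray:
    """Asymmetric-least-squares (Whittaker) baseline estimate.

    Penalized least squares with asymmetric weights: points above the
    current baseline get weight ``p`` (peaks), points below get ``1-p``.
    Iterates until the weight pattern stops changing.
    """
    return _als_iterate(y, lam, p, max_iter)[0]


def _arpls_iterate(y: np.ndarray, lam: float = 1e6, max_iter: int = 50, ratio: float = 1e-6):
    n = y.size
    if n < 5:
        raise ValueError("spectrum too short for arPLS baseline")
    w = np.ones(n)
    for _ in range(max_iter):
        z = _whittaker_solve(w, y, lam)
        d = y - z
        neg = d[d < 0]
        if neg.size < 2:
            break
        m, s = neg.mean(), neg.std()
        # floor the noise-scale estimate: keeps the logistic gradient
        # bounded on (near-)noiseless spectra, where s -> 0 would make
        # the weights chaotically sensitive to rounding noise
        s = max(s, 1e-6 * (np.abs(y).max() + 1e-300))
        with np.errstate(over="ignore"):
            w_new = 1.0 / (1.0 + np.exp(np.clip(2.0 * (d - (2 * s - m)) / s, -500, 500)))
        if w_new.sum() < 2:
            break
        if np.linalg.norm(w - w_new) / max(np.linalg.norm(w), 1e-300) < ratio:
            w = w_new
            break
        w = w_new
    return _whittaker_solve(w, y, lam), w


def baseline_arpls(y: np.ndarray, lam: float = 1e6, max_iter: int = 50, ratio: float = 1e-6) -> np.ndarray:
    """Asymmetrically reweighted penalized least-squares baseline.

    Like ALS, but the asymmetric weights are derived from the noise
    statistics of the points below the current baseline: residuals far
    above the noise band get weight ~ 0, residuals within it weight ~ 1
    (logistic transition).  Unlike fixed-p ALS, the estimate carries no
    peak-height-proportional bias — on a peaks-on-flat-background
    spectrum the converged baseline ignores the peaks entirely — which
    keeps band areas linear in analyte amount.
    """
    return _arpls_iterate(y, lam, max_iter, ratio)[0]


def converged_baseline_weights(y: np.ndarray, method: str = "arpls", **params) -> np.ndarray:
    """Converged Whittaker weight pattern of an ALS/arPLS baseline fit."""
    if method == "arpls":
        return _arpls_iterate(y, **params)[1]
    if method == "als":
        return _als_iterate(y, **params)[1]
    raise ValueError(f"no weight pattern for baseline method {method!r}")


def baseline_modpoly(
    y: np.ndarray,
    x: np.ndarray,
    degree: int = 3,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> np.ndarray:
    """Iterative (modified) polynomial baseline: fit, clip above, refit."""
    u = _scaled_axis(x)
    work = y.astype(float).copy()
    fit = np.zeros_like(work)
    for _ in range(max_iter):
        coef = np.polynomial.polynomial.polyfit(u, work, degree)
        fit = np.polynomial.polynomial.polyval(u, coef)
        clipped = np.minimum(work, fit)
        if np.max(np.abs(clipped - work)) < tol * (np.max(np.abs(y)) + 1e-300):
            work = clipped
            break
        work = clipped
    return fit


def baseline_correct(
    s: Spectrum,
    method: str = "arpls",
    **params,
) -> tuple[Spectrum, Spectrum]:
    """Estimate and subtract a smooth baseline.

    Returns ``(corrected, baseline)``.  Methods: ``"arpls"`` (default;
    ``lam``, ``max_iter``, ``ratio``), ``"als"`` (``lam``, ``p``,
    ``max_iter``) or ``"iterative-polynomial"`` (``degree``,
    ``max_iter``, ``tol``).
    """
    if method == "arpls":
        base = baseline_arpls(s.intensity, **params)
    elif method == "als":
        base = baseline_als(s.intensity, **params)
    elif method == "iterative-polynomial":
        base = baseline_modpoly(s.intensity, s.wavenumber, **params)
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return s.with_intensity(s.intensity - base), s.with_intensity(base)


# ---------------------------------------------------------------------------
# EMSC


def _scaled_axis(x: np.ndarray) -> np.ndarray:
    lo, hi = x[0], x[-1]
    return (2.0 * x - (lo + hi)) / (hi - lo)


def emsc(
    s: Spectrum,
    reference: Spectrum,
    poly_degree: int = 2,
    fit_mask: np.ndarray | None = None,
    retain: Sequence[np.ndarray] | None = None,
) -> tuple[Spectrum, np.ndarray]:
    """Extended multiplicative signal correction against a reference.

    Least-squares fit ``s ~ b*ref + sum_j h_j R_j + sum_k a_k P_k`` with
    Legendre polynomials ``P_k`` on the axis mapped to [-1, 1] and
    optional *retained* components ``R_j``; returns
    ``((s - sum a_k P_k)/b, [b, h_1..h_m, a_0..a_d])``.

    ``fit_mask`` restricts the rows used for coefficient estimation (the
    correction is always applied to the full axis); by default all
    points are used.  ``retain`` components take part in the fit — so
    their variation cannot leak into the multiplicative coefficient —
    but are *not* subtracted from the corrected spectrum.  Passing the
    analyte signature here is what makes the correction safe for
    quantification: without it, the analyte's own intensity is partly
    absorbed into ``b`` and normalized away.
    """
    if s.wavenumber.shape != reference.wavenumber.shape or not np.allclose(
        s.wavenumber, reference.wavenumber
    ):
        raise ValueError("spectrum and reference must share one axis")
    ref = reference.intensity
    if np.ptp(ref) == 0:
        raise ValueError("EMSC reference must not be constant")
    u = _scaled_axis(s.wavenumber)
    P = legendre.legvander(u, poly_degree)  # (n, d+1)
    retained = [np.asarray(r, dtype=float) for r in (retain or [])]
    design = np.column_stack([ref, *retained, P])
    if fit_mask is None:
        rows = slice(None)
    else:
        fit_mask = np.asarray(fit_mask, dtype=bool)
        if fit_mask.sum() < design.shape[1] + 1:
            raise ValueError("EMSC fit mask leaves too few points")
        rows = fit_mask
    coef, *_ = np.linalg.lstsq(design[rows], s.intensity[rows], rcond=None)
    b = coef[0]
    scale = np.sqrt(np.mean(s.intensity**2)) / np.sqrt(np.mean(ref**2))
    if abs(b) < 1e-9 * max(scale, 1e-300):
        raise ValueError("degenerate EMSC: spectrum orthogonal to reference (|b| ~ 0)")
    additive = P @ coef[1 + len(retained):]
    corrected = (s.intensity - additive) / b
    return s.with_intensity(corrected), coef


def _emsc_fit_mask(axis: np.ndarray, exclude: tuple[float, float] | None) -> np.ndarray | None:
    if exclude is None:
        return None
    lo, hi = exclude
    return ~((axis >= lo) & (axis <= hi))


def median_reference(spectra: Sequence[Spectrum], fit_mask: np.ndarray | None = None) -> Spectrum:
    """Pointwise-median reference, normalized to unit mean on the fit region.

    The median is robust to outlying spectra; normalizing the reference
    scale makes EMSC-corrected spectra comparable across datasets (the
    per-spectrum gain ends up entirely in ``b``).
    """
    stack = np.stack([s.intensity for s in spectra])
    med = np.median(stack, axis=0)
    region = med if fit_mask is None else med[fit_mask]
    norm = float(np.mean(region))
    if abs(norm) < 1e-12 * (np.abs(med).max() + 1e-300):
        norm = float(np.sqrt(np.mean(region**2))) or 1.0
    return spectra[0].with_intensity(med / norm)


def run_preprocess(
    ds: Dataset,
    cfg: PreprocessConfig | None = None,
    emsc_reference: Spectrum | None = None,
) -> Dataset:
    """Apply smooth -> resample -> crop -> baseline -> EMSC to a dataset.

    The EMSC reference is the pointwise median of the dataset's own
    baseline-corrected calibration spectra unless ``cfg.emsc_reference``
    is ``"supplied"`` and a spectrum is passed.  Metadata is never
    altered; each stage is logged in the returned dataset's provenance.
    """
    cfg = cfg or PreprocessConfig()

    def stages(s: Spectrum) -> Spectrum:
        out = smooth(s, cfg.smooth_window, cfg.smooth_polyorder)
        if cfg.target_axis is not None:
            out = resample(out, cfg.target_axis)
        return crop(out, *cfg.range_keep)

    cal = [stages(s) for s in ds.calibration_spectra]
    tst = [stages(s) for s in ds.test_spectra]

    shared = cfg.baseline_shared_weights and cfg.baseline_method in ("arpls", "als")
    if shared and cal:
        # Converge the peak/background weight pattern once, on the
        # pointwise median of the dataset, then apply the same weighted
        # Whittaker smoother to every spectrum.  Peak positions are
        # shared within a dataset, and a fixed weight pattern makes
        # baseline removal a linear operator: band areas stay exactly
        # proportional to analyte signal instead of inheriting an
        # amplitude-dependent baseline bias.
        stack = np.stack([s.intensity for s in cal + tst])
        rep = np.median(stack, axis=0)
        # normalize, then quantize to float32, before converging the
        # weights: the pattern then depends only on spectral shape (not
        # on overall intensity scale), and datasets whose shapes agree
        # to rounding noise get bit-identical patterns instead of
        # feeding 1e-15 differences through the reweighting iteration
        rep_scale = np.mean(np.abs(rep)) or 1.0
        rep_q = np.asarray(np.asarray(rep / rep_scale, dtype=np.float32), dtype=float)
        w = converged_baseline_weights(rep_q, cfg.baseline_method, **cfg.baseline_params)
        lam = cfg.baseline_params.get("lam", 1e6 if cfg.baseline_method == "arpls" else 1e5)
        cal = [s.with_intensity(s.intensity - _whittaker_solve(w, s.intensity, lam)) for s in cal]
        tst = [s.with_intensity(s.intensity - _whittaker_solve(w, s.intensity, lam)) for s in tst]
    else:
        cal = [baseline_correct(s, cfg.baseline_method, **cfg.baseline_params)[0] for s in cal]
        tst = [baseline_correct(s, cfg.baseline_method, **cfg.baseline_params)[0] for s in tst]
    axis = cal[0].wavenumber if cal else tst[0].wavenumber
    mask = _emsc_fit_mask(axis, cfg.emsc_exclude_band)

    if cfg.emsc_reference == "supplied":
        if emsc_reference is None:
            raise ValueError("emsc_reference policy 'supplied' needs a spectrum")
        ref = emsc_reference
        if ref.wavenumber.shape != axis.shape or not np.allclose(ref.wavenumber, axis):
            ref = resample(ref, axis)
    else:
        if not cal:
            raise ValueError("median-of-calibration EMSC needs calibration spectra")
        ref = median_reference(cal, mask)

    # Data-driven analyte signature: difference between the pointwise
    # medians of the highest- and lowest-concentration calibration
    # levels.  Included as a retained EMSC component so concentration
    # variation cannot bias the multiplicative coefficient.
    retain: list[np.ndarray] = []
    if cal:
        by_conc: dict[float, list[Spectrum]] = {}
        for s in cal:
            by_conc.setdefault(s.meta.concentration_uM, []).append(s)
        concs = sorted(by_conc)
        if len(concs) >= 2:
            top = np.median(np.stack([s.intensity for s in by_conc[concs[-1]]]), axis=0)
            bot = np.median(np.stack([s.intensity for s in by_conc[concs[0]]]), axis=0)
            d = top - bot
            d_norm = np.linalg.norm(d)
            if d_norm > 1e-10 * np.linalg.norm(ref.intensity):
                retain.append(d / d_norm)

    cal = [emsc(s, ref, cfg.emsc_poly_degree, mask, retain)[0] for s in cal]
    tst = [emsc(s, ref, cfg.emsc_poly_degree, mask, retain)[0] for s in tst]

    out = Dataset(ds.lab_id, ds.method, cal, tst, list(ds.provenance))
    out.log(
        "preprocess: savgol(window=%d, polyorder=%d) -> resample(%s) -> "
        "crop[%g, %g] -> baseline(%s) -> emsc(degree=%d, ref=%s, exclude=%s)"
        % (
            cfg.smooth_window,
            cfg.smooth_polyorder,
            cfg.target_axis,
            *cfg.range_keep,
            cfg.baseline_method,
            cfg.emsc_poly_degree,
            cfg.emsc_reference,
            cfg.emsc_exclude_band,
        )
    )
    return out
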