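"""Seeded synthetic interlaboratory SERS collections.

The generator emulates the statistical structure a multi-laboratory
quantification study assumes: one adenine ring-breathing band near
733 cm^-1 whose area grows with concentration (optionally saturating),
concentration-independent background ("matrix") bands such as citrate
features, a smooth fluorescence baseline, a per-laboratory multiplicative
gain, per-replicate enhancement variability, and additive detector noise
with an optional concentration-proportional part.

Model per spectrum::

    I(v) = g_lab * [ baseline(v) + M(v) + (1 + d_rep) * A(c) * V(v; center, fwhm) ]
         + eps(v)

with ``A(c) = amplitude * c * K/(K + c)`` (linear when K is infinite),
``V`` a unit-area 50/50 pseudo-Voigt profile, ``M`` the fixed matrix
bands, ``g_lab ~ N(1, lab_gain_sd)``, ``d_rep ~ N(0, replicate_sd)``
applied to the analyte band only (an enhancement fluctuation, which the
multiplicative EMSC correction cannot remove), and
``eps ~ N(0, noise_sd_additive + noise_sd_proportional * A(c))``.

The laboratory gain multiplies the whole optical signal — fluorescence
baseline, matrix bands and analyte band alike — as a detector/optics
throughput factor does; only the detector noise sits outside it.

The matrix bands share the laboratory gain: they are what anchors the
EMSC scale estimate, exactly as concentration-invariant background
features do in measured SERS spectra.  Without them a normalization
against the dataset's own median would absorb the analyte amplitude into
the multiplicative coefficient and erase the calibration signal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .spectra import DEFAULT_METHODS, Dataset, MethodId, Spectrum, SpectrumMeta

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "pseudo_voigt",
    "generate_collection",
    "study_scale_config",
    "noise_free_config",
]


def pseudo_voigt(axis: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-area 50/50 Gaussian-Lorentzian profile."""
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    gamma = fwhm / 2.0
    gauss = np.exp(-0.5 * ((axis - center) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
    lorentz = (gamma / math.pi) / ((axis - center) ** 2 + gamma**2)
    return 0.5 * gauss + 0.5 * lorentz


@dataclass
class SyntheticConfig:
    """Everything needed to generate one synthetic study collection."""

    methods: tuple[MethodId, ...] = DEFAULT_METHODS
    labs_per_method: int = 8
    cal_concentrations: tuple[float, ...] = ()  # uM, >= 2 levels
    test_concentrations: tuple[float, ...] = ()  # uM
    band_center: float = 733.0  # cm^-1
    band_fwhm: float = 14.0  # cm^-1
    response_amplitude: float = 30.0  # band-area counts*cm^-1 per uM
    saturation_K: float = math.inf  # uM; inf = linear response
    lab_gain_sd: float = 0.0  # fraction
    replicate_sd: float = 0.0  # fraction, analyte band only
    noise_sd_additive: float = 0.0  # counts
    noise_sd_proportional: float = 0.0  # fraction of A(c)
    baseline_poly_coeffs: tuple[float, ...] = (0.0,)  # in u = (v - lo)/(hi - lo)
    matrix_bands: tuple[tuple[float, float, float], ...] = (
        # (center cm^-1, fwhm cm^-1, area counts*cm^-1)
        (960.0, 20.0, 3500.0),
        (1090.0, 18.0, 2500.0),
        (1395.0, 25.0, 4000.0),
        (1580.0, 22.0, 2000.0),
    )
    contaminant_prob: float = 0.0
    contaminant_bands: tuple[tuple[float, float, float], ...] = (
        (741.0, 10.0, 6000.0),  # inside the analyte window
        (1296.0, 16.0, 9000.0),  # outside it
    )
    axis: tuple[float, float, float] = (400.0, 1800.0, 1.0)  # start, stop, step
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lab_gain_sd", "replicate_sd", "noise_sd_additive", "noise_sd_proportional"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.cal_concentrations:
            raise ValueError("cal_concentrations must be non-empty")
        if any(c < 0 for c in self.cal_concentrations + self.test_concentrations):
            raise ValueError("concentrations must be >= 0")
        if len(set(self.cal_concentrations)) < 2:
            raise ValueError("need >= 2 distinct calibration levels")
        if not 0 <= self.contaminant_prob <= 1:
            raise ValueError("contaminant_prob must be in [0, 1]")
        if self.axis[2] <= 0 or self.axis[1] <= self.axis[0]:
            raise ValueError("axis must satisfy start < stop, step > 0")
        if self.labs_per_method < 1:
            raise ValueError("labs_per_method must be >= 1")
        if self.saturation_K <= 0:
            raise ValueError("saturation_K must be positive (or inf)")

    def wavenumber_axis(self) -> np.ndarray:
        lo, hi, step = self.axis
        return np.arange(lo, hi + step / 2, step)

    def response(self, c: float) -> float:
        """Expected analyte band area A(c), counts*cm^-1."""
        if math.isinf(self.saturation_K):
            return self.response_amplitude * c
        return self.response_amplitude * c * self.saturation_K / (self.saturation_K + c)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = [str(m) for m in self.methods]
        d["saturation_K"] = None if math.isinf(self.saturation_K) else self.saturation_K
        return d


@dataclass
class TruthRecord:
    """Ground truth for recovery tests, reproducible from (config, seed)."""

    lab_gains: dict  # "lab|method" -> gain
    spectrum_truth: dict  # "lab|method" -> list of per-spectrum dicts
    test_concentrations: dict  # level_id -> uM
    window_fraction: float  # share of unit-area profile inside the band window
    config: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _band_window_fraction(cfg: SyntheticConfig, lo: float = 715.0, hi: float = 750.0) -> float:
    # fine-grid trapezoid of the unit-area profile over the closed window
    grid = np.linspace(lo, hi, 20001)
    return float(np.trapezoid(pseudo_voigt(grid, cfg.band_center, cfg.band_fwhm), grid))


def _dataset_rng(cfg: SyntheticConfig, method_index: int, lab_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(method_index, lab_index))
    return np.random.Generator(np.random.PCG64(ss))


def generate_collection(cfg: SyntheticConfig) -> tuple[list[Dataset], TruthRecord]:
    """Generate one Dataset per method x lab, plus the ground truth.

    Each dataset draws from its own random stream keyed by (seed,
    method index, lab index), so results are independent of generation
    order and bit-reproducible for a fixed config.
    """
    axis = cfg.wavenumber_axis()
    u = (axis - cfg.axis[0]) / (cfg.axis[1] - cfg.axis[0])
    baseline = np.polynomial.polynomial.polyval(u, np.asarray(cfg.baseline_poly_coeffs, float))
    profile = pseudo_voigt(axis, cfg.band_center, cfg.band_fwhm)
    matrix = np.zeros_like(axis)
    for center, fwhm, area in cfg.matrix_bands:
        matrix += area * pseudo_voigt(axis, center, fwhm)
    contaminant = np.zeros_like(axis)
    for center, fwhm, area in cfg.contaminant_bands:
        contaminant += area * pseudo_voigt(axis, center, fwhm)
    frac = _band_window_fraction(cfg)

    cal_levels = [(f"C{i}", float(c)) for i, c in enumerate(cfg.cal_concentrations)]
    test_levels = [(f"X{i + 1}", float(c)) for i, c in enumerate(cfg.test_concentrations)]

    datasets: list[Dataset] = []
    gains: dict = {}
    truth: dict = {}
    for mi, method in enumerate(cfg.methods):
        n_rep = method.replicates_per_sample
        for li in range(cfg.labs_per_method):
            lab = f"L{li + 1:02d}"
            rng = _dataset_rng(cfg, mi, li)
            g = 1.0 + cfg.lab_gain_sd * rng.standard_normal() if cfg.lab_gain_sd else 1.0
            contaminated = rng.random() < cfg.contaminant_prob
            key = f"{lab}|{method}"
            gains[key] = g
            truth[key] = []
            cal_spectra: list[Spectrum] = []
            test_spectra: list[Spectrum] = []
            for role, levels, sink in (
                ("calibration", cal_levels, cal_spectra),
                ("test", test_levels, test_spectra),
            ):
                for level_id, conc in levels:
                    a_c = cfg.response(conc)
                    for rep in range(1, n_rep + 1):
                        d_rep = cfg.replicate_sd * rng.standard_normal() if cfg.replicate_sd else 0.0
                        noise_sd = cfg.noise_sd_additive + cfg.noise_sd_proportional * a_c
                        eps = noise_sd * rng.standard_normal(axis.size) if noise_sd else 0.0
                        analyte_area = g * (1.0 + d_rep) * a_c
                        signal = g * (baseline + matrix) + analyte_area * profile + eps
                        if contaminated:
                            signal = signal + g * contaminant
                        meta = SpectrumMeta(lab, method, role, level_id, conc, rep)
                        sink.append(Spectrum(axis, signal, meta))
                        truth[key].append(
                            {
                                "role": role,
                                "level": level_id,
                                "replicate": rep,
                                "concentration_uM": conc,
                                "true_band_area": analyte_area * frac,
                            }
                        )
            ds = Dataset(lab, method, cal_spectra, test_spectra, [])
            ds.log(f"synthetic: seed={cfg.seed} gain={g:.6f} contaminated={contaminated}")
            datasets.append(ds)

    record = TruthRecord(
        lab_gains=gains,
        spectrum_truth=truth,
        test_concentrations=dict(test_levels),
        window_fraction=frac,
        config=cfg.to_dict(),
    )
    return datasets, record


def study_scale_config(seed: int = 0) -> SyntheticConfig:
    """Default configuration at the scale of the collaborative trial.

    Six methods x 8 laboratories; nine calibration levels C0-C8
    log-spaced over 1-100 uM and five test levels X1-X5 interleaved
    inside the calibration range; realistic lab gain spread, replicate
    enhancement variability, mild saturation and detector noise.
    """
    return SyntheticConfig(
        methods=DEFAULT_METHODS,
        labs_per_method=8,
        cal_concentrations=tuple(np.geomspace(1.0, 100.0, 9)),
        test_concentrations=tuple(np.geomspace(2.0, 80.0, 5)),
        saturation_K=400.0,
        lab_gain_sd=0.15,
        replicate_sd=0.25,
        noise_sd_additive=2.0,
        noise_sd_proportional=0.01,
        baseline_poly_coeffs=(250.0, -120.0, 60.0),
        contaminant_prob=0.0,
        seed=seed,
    )


def noise_free_config(seed: int = 0) -> SyntheticConfig:
    """Ideal linear configuration: every stochastic term and nuisance off.

    All SDs zero, infinite saturation constant (linear response), zero
    fluorescence baseline, no contaminants.  The matrix bands stay: they
    are deterministic structure, and the normalization step needs
    concentration-invariant features to be identifiable.
    """
    cfg = study_scale_config(seed)
    return SyntheticConfig(
        **{
            **{f: getattr(cfg, f) for f in cfg.__dataclass_fields__},
            "saturation_K": math.inf,
            "lab_gain_sd": 0.0,
            "replicate_sd": 0.0,
            "noise_sd_additive": 0.0,
            "noise_sd_proportional": 0.0,
            "baseline_poly_coeffs": (0.0,),
            "contaminant_prob": 0.0,
        }
    )
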