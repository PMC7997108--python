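"""Spectral data containers and I/O for an interlaboratory SERS study.

A study collection is organized as one :class:`Dataset` per laboratory ×
method combination, each holding calibration spectra (known adenine
concentrations) and test spectra (concentrations to be predicted).
Spectra travel as two-column delimited text files plus a CSV manifest.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MethodId",
    "SpectrumMeta",
    "Spectrum",
    "Dataset",
    "IntegrityReport",
    "DEFAULT_METHODS",
    "ADENINE_WINDOW",
    "read_spectrum_table",
    "write_spectrum_table",
    "load_ils_collection",
    "write_ils_collection",
    "integrity_check",
]

#: Integration window of the adenine ring-breathing band (cm^-1, closed).
ADENINE_WINDOW = (715.0, 750.0)

_METHOD_RE = re.compile(r"^([cs])(Ag|Au)@(\d+(?:\.\d+)?)(?:\s*nm)?$")


@dataclass(frozen=True, order=True)
class MethodId:
    """A SERS method: substrate form x metal x laser excitation.

    Canonical rendering follows the field shorthand, e.g. ``cAg@785`` for
    colloidal silver excited at 785 nm, ``sAu@532`` for a solid gold
    substrate at 532 nm.
    """

    substrate_form: str  # "colloidal" | "solid"
    metal: str  # "Ag" | "Au"
    excitation_nm: float

    def __post_init__(self) -> None:
        if self.substrate_form not in ("colloidal", "solid"):
            raise ValueError(f"unknown substrate form {self.substrate_form!r}")
        if self.metal not in ("Ag", "Au"):
            raise ValueError(f"unknown metal {self.metal!r}")
        if not self.excitation_nm > 0:
            raise ValueError("excitation wavelength must be positive")

    @property
    def replicates_per_sample(self) -> int:
        """3 colloid batches, or 3 spots x 3 solid substrates = 9."""
        return 3 if self.substrate_form == "colloidal" else 9

    def __str__(self) -> str:
        prefix = "c" if self.substrate_form == "colloidal" else "s"
        exc = self.excitation_nm
        exc_s = f"{exc:g}"
        return f"{prefix}{self.metal}@{exc_s}"

    @classmethod
    def parse(cls, code: str, strict: bool = True) -> "MethodId":
        """Parse a method code like ``"cAg@785"`` (optionally ``"... nm"``).

        With ``strict=True`` (default) only the six method codes used in
        the collaborative trial are accepted; pass ``strict=False`` to
        allow any well-formed combination.
        """
        m = _METHOD_RE.match(code.strip())
        if not m:
            raise ValueError(f"cannot parse method code {code!r}")
        form = "colloidal" if m.group(1) == "c" else "solid"
        method = cls(form, m.group(2), float(m.group(3)))
        if strict and method not in DEFAULT_METHODS:
            raise ValueError(
                f"{method} is not one of the default study methods; "
                "use strict=False to accept it"
            )
        return method


#: The six methods of the collaborative trial.
DEFAULT_METHODS: tuple[MethodId, ...] = (
    MethodId("colloidal", "Ag", 532.0),
    MethodId("colloidal", "Ag", 785.0),
    MethodId("colloidal", "Au", 785.0),
    MethodId("solid", "Ag", 532.0),
    MethodId("solid", "Ag", 785.0),
    MethodId("solid", "Au", 785.0),
)


@dataclass(frozen=True)
class SpectrumMeta:
    """Acquisition metadata attached to a single spectrum."""

    lab_id: str
    method: MethodId
    role: str  # "calibration" | "test"
    level_id: str  # e.g. "C0".."C8" (calibration) or "X1".."X5" (test)
    concentration_uM: float | None  # None only allowed for test spectra
    replicate_id: int = 1

    def __post_init__(self) -> None:
        if self.role not in ("calibration", "test"):
            raise ValueError(f"role must be calibration|test, got {self.role!r}")
        if self.role == "calibration" and self.concentration_uM is None:
            raise ValueError("calibration spectra require a known concentration")
        if self.concentration_uM is not None and self.concentration_uM < 0:
            raise ValueError("concentration must be non-negative")
        if self.replicate_id < 1:
            raise ValueError("replicate_id must be >= 1")


@dataclass(frozen=True)
class Spectrum:
    """One wavenumber/intensity trace.

    Invariants: strictly increasing axis, equal lengths, finite values,
    at least two points.
    """

    wavenumber: np.ndarray  # cm^-1, strictly increasing
    intensity: np.ndarray  # detector counts (a.u.)
    meta: SpectrumMeta

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumber, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "wavenumber", wn)
        object.__setattr__(self, "intensity", it)
        if wn.ndim != 1 or it.ndim != 1:
            raise ValueError("axis and intensity must be 1-D")
        if wn.size != it.size:
            raise ValueError("axis and intensity lengths differ")
        if wn.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not (np.all(np.isfinite(wn)) and np.all(np.isfinite(it))):
            raise ValueError("non-finite value in spectrum")
        if np.any(np.diff(wn) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")

    def __len__(self) -> int:
        return int(self.wavenumber.size)

    def with_intensity(self, intensity: np.ndarray, wavenumber: np.ndarray | None = None) -> "Spectrum":
        """Copy with new intensities (and optionally a new axis); metadata kept."""
        wn = self.wavenumber if wavenumber is None else wavenumber
        return Spectrum(wn, np.asarray(intensity, dtype=float), self.meta)

    def covers(self, lo: float, hi: float) -> bool:
        return self.wavenumber[0] <= lo and self.wavenumber[-1] >= hi


@dataclass
class Dataset:
    """All spectra of one laboratory running one method."""

    lab_id: str
    method: MethodId
    calibration_spectra: list[Spectrum] = field(default_factory=list)
    test_spectra: list[Spectrum] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.calibration_spectra + self.test_spectra:
            if s.meta.lab_id != self.lab_id or s.meta.method != self.method:
                raise ValueError(
                    f"spectrum metadata ({s.meta.lab_id}, {s.meta.method}) "
                    f"inconsistent with dataset ({self.lab_id}, {self.method})"
                )
        levels = {s.meta.concentration_uM for s in self.calibration_spectra}
        if self.calibration_spectra and len(levels) < 2:
            raise ValueError("need >= 2 distinct calibration concentration levels")

    @property
    def spectra(self) -> list[Spectrum]:
        return self.calibration_spectra + self.test_spectra

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def cal_levels(self) -> dict[str, float]:
        """Mapping level_id -> concentration for the calibration set."""
        out: dict[str, float] = {}
        for s in self.calibration_spectra:
            out.setdefault(s.meta.level_id, s.meta.concentration_uM)
        return out


# ---------------------------------------------------------------------------
# text I/O


def _read_two_column(path: Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for k, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "%", "//")):
                continue
            parts = re.split(r"[,;\t]|\s+", line)
            parts = [p for p in parts if p]
            if len(parts) != 2:
                raise ValueError(f"{path}: expected 2 columns at row {k}, got {len(parts)}")
            try:
                wn, it = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric value at row {k}") from exc
            if not (np.isfinite(wn) and np.isfinite(it)):
                raise ValueError(f"{path}: non-finite value at row {k}")
            rows.append((wn, it))
    if len(rows) < 2:
        raise ValueError(f"{path}: fewer than 2 data points")
    return np.asarray(rows, dtype=float)


def read_spectrum_table(path: str | Path, meta: SpectrumMeta) -> Spectrum:
    """Read a two-column (wavenumber, intensity) delimited text file.

    The delimiter is auto-detected among comma / tab / semicolon /
    whitespace; ``#`` lines are comments.  A descending axis is re-sorted
    ascending with intensities permuted accordingly; duplicated
    wavenumbers are an error.
    """
    data = _read_two_column(Path(path))
    order = np.argsort(data[:, 0], kind="stable")
    data = data[order]
    if np.any(np.diff(data[:, 0]) == 0):
        raise ValueError(f"{path}: duplicated wavenumbers")
    return Spectrum(data[:, 0], data[:, 1], meta)


def write_spectrum_table(path: str | Path, s: Spectrum) -> None:
    """Write a spectrum as comma-separated text at full float precision."""
    with open(path, "w") as fh:
        fh.write("# wavenumber_cm-1,intensity\n")
        for wn, it in zip(s.wavenumber, s.intensity):
            fh.write(f"{float(wn)!r},{float(it)!r}\n")


MANIFEST_COLUMNS = ("file", "lab", "method", "role", "level", "replicate", "concentration_uM")


def load_ils_collection(
    root: str | Path,
    manifest: str | Path | pd.DataFrame,
    strict_methods: bool = True,
) -> list[Dataset]:
    """Load a study collection from spectrum files plus a CSV manifest.

    The manifest has columns ``file, lab, method, role, level, replicate,
    concentration_uM`` (concentration may be empty for test samples).
    Spectra are grouped into one :class:`Dataset` per (lab, method);
    missing or extra replicates relative to the method's replicate scheme
    are recorded in the dataset provenance without failing.
    """
    root = Path(root)
    if isinstance(manifest, (str, Path)):
        manifest = pd.read_csv(manifest, dtype={"lab": str, "level": str})
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")

    seen: dict[str, tuple] = {}
    groups: dict[tuple[str, MethodId], Dataset] = {}
    # deterministic grouping independent of manifest row order
    df = manifest.copy()
    df["method_id"] = df["method"].map(lambda m: MethodId.parse(m, strict=strict_methods))
    df = df.sort_values(["lab", "method", "role", "level", "replicate"], kind="stable")

    for row in df.itertuples(index=False):
        conc = None if pd.isna(row.concentration_uM) else float(row.concentration_uM)
        meta = SpectrumMeta(
            lab_id=str(row.lab),
            method=row.method_id,
            role=str(row.role),
            level_id=str(row.level),
            concentration_uM=conc,
            replicate_id=int(row.replicate),
        )
        key_meta = (meta.lab_id, str(meta.method), meta.role, meta.level_id, meta.replicate_id)
        fname = str(row.file)
        if fname in seen and seen[fname] != key_meta:
            raise ValueError(f"conflicting manifest metadata for file {fname}")
        seen[fname] = key_meta
        fpath = root / fname
        if not fpath.exists():
            raise FileNotFoundError(f"manifest references missing file {fpath}")
        spec = read_spectrum_table(fpath, meta)
        gkey = (meta.lab_id, meta.method)
        ds = groups.get(gkey)
        if ds is None:
            ds = Dataset(meta.lab_id, meta.method, [], [], [])
            groups[gkey] = ds
        (ds.calibration_spectra if meta.role == "calibration" else ds.test_spectra).append(spec)

    out = []
    for (lab, method), ds in sorted(groups.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
        ds = Dataset(lab, method, ds.calibration_spectra, ds.test_spectra, ds.provenance)
        _note_replicate_gaps(ds)
        out.append(ds)
    return out


def _note_replicate_gaps(ds: Dataset) -> None:
    expected = ds.method.replicates_per_sample
    for role, spectra in (("calibration", ds.calibration_spectra), ("test", ds.test_spectra)):
        counts: dict[str, int] = {}
        for s in spectra:
            counts[s.meta.level_id] = counts.get(s.meta.level_id, 0) + 1
        for level in sorted(counts):
            n = counts[level]
            if n < expected:
                ds.log(f"{role} level {level}: {expected - n} replicate(s) missing ({n}/{expected})")
            elif n > expected:
                ds.log(f"{role} level {level}: {n - expected} extra replicate(s) ({n}/{expected})")


def write_ils_collection(root: str | Path, collection: Iterable[Dataset]) -> Path:
    """Write each spectrum as a text file plus a ``manifest.csv`` under root."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for ds in collection:
        for s in ds.spectra:
            m = s.meta
            fname = f"{m.lab_id}_{m.method}_{m.role[:3]}_{m.level_id}_r{m.replicate_id}.txt"
            fname = fname.replace("@", "-")
            write_spectrum_table(root / fname, s)
            rows.append(
                {
                    "file": fname,
                    "lab": m.lab_id,
                    "method": str(m.method),
                    "role": m.role,
                    "level": m.level_id,
                    "replicate": m.replicate_id,
                    "concentration_uM": m.concentration_uM,
                }
            )
    manifest = root / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest, index=False)
    return manifest


# ---------------------------------------------------------------------------
# integrity screening


@dataclass
class IntegrityReport:
    """Per-spectrum flags plus a dataset verdict from the integrity screen."""

    lab_id: str
    method: MethodId
    flags: list[list[str]]  # parallel to Dataset.spectra; empty list = clean
    verdict: str  # "pass" | "reject"

    @property
    def n_flagged(self) -> int:
        return sum(1 for f in self.flags if f)


def _contaminant_signature(s: Spectrum, lo: float, hi: float) -> np.ndarray | None:
    """Baseline-corrected, area-normalized intensities on [lo, hi]."""
    from .preprocess import baseline_correct  # local import to avoid a cycle

    mask = (s.wavenumber >= lo) & (s.wavenumber <= hi)
    if mask.sum() < 8:
        return None
    sub = Spectrum(s.wavenumber[mask], s.intensity[mask], s.meta)
    corrected, _ = baseline_correct(sub)
    y = corrected.intensity
    area = np.trapezoid(np.abs(y), sub.wavenumber)
    if area <= 0:
        return None
    return y / area


def integrity_check(
    ds: Dataset,
    contaminant_refs: Sequence[Spectrum] = (),
    corr_threshold: float = 0.9,
    band_window: tuple[float, float] = ADENINE_WINDOW,
) -> IntegrityReport:
    """Screen a dataset for unusable spectra before any analysis.

    Flags raised per spectrum:

    * ``non-finite data`` — defensive; constructed spectra are finite.
    * ``band window not covered`` — axis does not span the analyte window.
    * ``contaminant r=...`` — Pearson correlation with a contaminant
      reference (both baseline-corrected and area-normalized on their
      overlap region) at or above ``corr_threshold``.  This is the
      mechanical surrogate for expert inspection of interfering
      substrate features such as parafilm bands.

    The dataset verdict is ``reject`` when more than half of its spectra
    carry a contaminant flag.
    """
    flags: list[list[str]] = []
    n_contaminated = 0
    spectra = ds.spectra
    for s in spectra:
        f: list[str] = []
        if not (np.all(np.isfinite(s.intensity)) and np.all(np.isfinite(s.wavenumber))):
            f.append("non-finite data")
        if not s.covers(*band_window):
            f.append("band window not covered")
        best_r = None
        for ref in contaminant_refs:
            lo = max(s.wavenumber[0], ref.wavenumber[0])
            hi = min(s.wavenumber[-1], ref.wavenumber[-1])
            if hi <= lo:
                continue
            sig_s = _contaminant_signature(s, lo, hi)
            ref_i = np.interp(s.wavenumber, ref.wavenumber, ref.intensity)
            ref_on_axis = Spectrum(s.wavenumber, ref_i, s.meta)
            sig_r = _contaminant_signature(ref_on_axis, lo, hi)
            if sig_s is None or sig_r is None or sig_s.size != sig_r.size:
                continue
            with np.errstate(invalid="ignore"):
                r = float(np.corrcoef(sig_s, sig_r)[0, 1])
            if np.isfinite(r) and (best_r is None or r > best_r):
                best_r = r
        if best_r is not None and best_r >= corr_threshold:
            f.append(f"contaminant r={best_r:.3f}")
            n_contaminated += 1
        flags.append(f)
    verdict = "reject" if spectra and n_contaminated > 0.5 * len(spectra) else "pass"
    return IntegrityReport(ds.lab_id, ds.method, flags, verdict)
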