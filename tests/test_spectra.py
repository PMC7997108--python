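"""Spectrum containers, text I/O and the integrity screen."""

import numpy as np
import pandas as pd
import pytest

from sersils.spectra import (
    DEFAULT_METHODS,
    Dataset,
    MethodId,
    Spectrum,
    SpectrumMeta,
    integrity_check,
    load_ils_collection,
    read_spectrum_table,
    write_ils_collection,
    write_spectrum_table,
)
from sersils.synthetic import generate_collection, pseudo_voigt
from conftest import small_config


def meta(role="calibration", conc=10.0, level="C1", rep=1, lab="L01"):
    return SpectrumMeta(lab, DEFAULT_METHODS[1], role, level, conc, rep)


class TestMethodId:
    @pytest.mark.parametrize(
        "code,form,metal,exc",
        [
            ("cAg@785", "colloidal", "Ag", 785.0),
            ("sAg@532", "solid", "Ag", 532.0),
            ("cAu@785 nm", "colloidal", "Au", 785.0),
        ],
    )
    def test_parse_roundtrip(self, code, form, metal, exc):
        m = MethodId.parse(code)
        assert (m.substrate_form, m.metal, m.excitation_nm) == (form, metal, exc)
        assert MethodId.parse(str(m)) == m

    def test_six_default_methods_and_strictness(self):
        assert len(DEFAULT_METHODS) == 6
        with pytest.raises(ValueError):
            MethodId.parse("cAg@633")  # not part of the trial
        assert MethodId.parse("cAg@633", strict=False).excitation_nm == 633.0

    def test_replicate_scheme(self):
        assert MethodId.parse("cAg@785").replicates_per_sample == 3
        assert MethodId.parse("sAg@785").replicates_per_sample == 9


class TestSpectrum:
    def test_invariants(self):
        with pytest.raises(ValueError):
            Spectrum([1.0, 2.0], [1.0], meta())  # length mismatch
        with pytest.raises(ValueError):
            Spectrum([2.0, 1.0], [1.0, 1.0], meta())  # not increasing
        with pytest.raises(ValueError):
            Spectrum([1.0, 2.0], [1.0, np.nan], meta())  # non-finite
        with pytest.raises(ValueError):
            Spectrum([1.0], [1.0], meta())  # too short

    def test_calibration_requires_concentration(self):
        with pytest.raises(ValueError):
            SpectrumMeta("L01", DEFAULT_METHODS[0], "calibration", "C0", None)
        # unknown concentration is fine for a test sample
        SpectrumMeta("L01", DEFAULT_METHODS[0], "test", "X1", None)


class TestTableIO:
    def test_parse_and_descending_resort(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("# comment\n700,1.0\n710,2.0\n720,1.5\n")
        s = read_spectrum_table(p, meta())
        assert np.array_equal(s.wavenumber, [700, 710, 720])
        assert np.array_equal(s.intensity, [1.0, 2.0, 1.5])
        p.write_text("720,1.5\n710,2.0\n700,1.0\n")
        s2 = read_spectrum_table(p, meta())
        assert np.array_equal(s2.wavenumber, s.wavenumber)
        assert np.array_equal(s2.intensity, s.intensity)

    @pytest.mark.parametrize("sep", [",", "\t", ";", "  "])
    def test_delimiter_autodetect(self, tmp_path, sep):
        p = tmp_path / "s.txt"
        p.write_text(f"700{sep}1.0\n710{sep}2.0\n")
        s = read_spectrum_table(p, meta())
        assert np.array_equal(s.intensity, [1.0, 2.0])

    @pytest.mark.parametrize(
        "text,msg",
        [
            ("700,NaN\n710,2\n", "non-finite"),
            ("700,a\n710,2\n", "non-numeric"),
            ("700,1\n", "fewer than 2"),
            ("700,1\n700,2\n", "duplicated"),
        ],
    )
    def test_error_paths(self, tmp_path, text, msg):
        p = tmp_path / "bad.txt"
        p.write_text(text)
        with pytest.raises(ValueError, match=msg):
            read_spectrum_table(p, meta())

    def test_roundtrip_full_precision(self, tmp_path):
        rng = np.random.default_rng(0)
        s = Spectrum(np.sort(rng.uniform(400, 1800, 50)), rng.normal(size=50), meta())
        p = tmp_path / "rt.txt"
        write_spectrum_table(p, s)
        s2 = read_spectrum_table(p, s.meta)
        assert np.array_equal(s.wavenumber, s2.wavenumber)
        assert np.array_equal(s.intensity, s2.intensity)


class TestCollectionIO:
    def test_write_load_groups_and_counts(self, tmp_path):
        cfg = small_config(seed=3)
        collection, _ = generate_collection(cfg)
        manifest = write_ils_collection(tmp_path, collection)
        loaded = load_ils_collection(tmp_path, manifest)
        assert len(loaded) == 2  # one per lab
        # 5 cal levels x 3 reps + 5 test levels x 3 reps = 30 spectra
        assert all(len(ds.spectra) == 30 for ds in loaded)
        orig = {(d.lab_id, str(d.method)): d for d in collection}
        for ds in loaded:
            src = orig[(ds.lab_id, str(ds.method))]
            for a, b in zip(ds.spectra, src.spectra):
                assert np.array_equal(a.intensity, b.intensity)

    def test_row_order_independence(self, tmp_path):
        cfg = small_config(seed=4)
        collection, _ = generate_collection(cfg)
        manifest = write_ils_collection(tmp_path, collection)
        df = pd.read_csv(manifest, dtype={"lab": str, "level": str})
        shuffled = df.sample(frac=1.0, random_state=1)
        a = load_ils_collection(tmp_path, df)
        b = load_ils_collection(tmp_path, shuffled)
        for da, db in zip(a, b):
            assert da.lab_id == db.lab_id
            for sa, sb in zip(da.spectra, db.spectra):
                assert sa.meta == sb.meta
                assert np.array_equal(sa.intensity, sb.intensity)

    def test_missing_replicate_logged_not_fatal(self, tmp_path):
        cfg = small_config(seed=5)
        collection, _ = generate_collection(cfg)
        manifest = write_ils_collection(tmp_path, collection)
        df = pd.read_csv(manifest, dtype={"lab": str, "level": str})
        df = df.iloc[1:]  # drop one replicate
        loaded = load_ils_collection(tmp_path, df)
        notes = "\n".join(n for ds in loaded for n in ds.provenance)
        assert "missing" in notes

    def test_missing_file_raises(self, tmp_path):
        df = pd.DataFrame(
            [{"file": "nope.txt", "lab": "L01", "method": "cAg@785", "role": "test",
              "level": "X1", "replicate": 1, "concentration_uM": 1.0}]
        )
        with pytest.raises(FileNotFoundError):
            load_ils_collection(tmp_path, df)


class TestIntegrityCheck:
    def test_clean_dataset_passes(self):
        collection, _ = generate_collection(small_config(seed=6))
        report = integrity_check(collection[0], [])
        assert report.verdict == "pass"
        assert report.n_flagged == 0

    def test_band_window_coverage_flag(self):
        axis = np.arange(800.0, 1800.0)
        m = meta()
        bad = Spectrum(axis, np.ones_like(axis), m)
        axis2 = np.arange(400.0, 1800.0)
        good = Spectrum(axis2, np.ones_like(axis2), meta(level="C2", conc=20.0))
        ds = Dataset("L01", m.method, [bad, good], [], [])
        report = integrity_check(ds, [])
        assert report.flags[0] == ["band window not covered"]
        assert report.flags[1] == []
        assert report.verdict == "pass"

    def test_contaminated_dataset_rejected(self):
        # spectra that *are* the contaminant (plus 1% noise) correlate
        # above 0.9 with the reference and trip the >50% rule
        cfg = small_config(seed=7, contaminant_prob=1.0, noise_sd_additive=0.0)
        collection, _ = generate_collection(cfg)
        ds = collection[0]
        axis = ds.spectra[0].wavenumber
        contam = np.zeros_like(axis)
        for center, fwhm, area in cfg.contaminant_bands:
            contam += area * pseudo_voigt(axis, center, fwhm)
        rng = np.random.default_rng(0)
        noisy = [
            s.with_intensity(contam + 0.01 * contam.max() * rng.standard_normal(axis.size))
            for s in ds.spectra
        ]
        pure = Spectrum(axis, contam, ds.spectra[0].meta)
        ds2 = Dataset(ds.lab_id, ds.method, noisy[:15], noisy[15:], [])
        report = integrity_check(ds2, [pure], corr_threshold=0.9)
        assert report.verdict == "reject"
        assert report.n_flagged > 0.5 * len(ds2.spectra)

    def test_determinism(self, noisy_dataset):
        r1 = integrity_check(noisy_dataset, [])
        r2 = integrity_check(noisy_dataset, [])
        assert r1.verdict == r2.verdict and r1.flags == r2.flags
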