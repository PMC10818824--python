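"""Emission-scan and EEM machinery: I/O, peak picking, ridge, blue shift."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import quenchfit as qf
from quenchfit.exceptions import (CapabilityError, DomainError, FormatError,
                                  ValidationError)

from conftest import brute_force_peaks, brute_force_ridge_max


def make_eem(ex, em, z):
    return qf.EEM(np.asarray(ex, float), np.asarray(em, float),
                  np.asarray(z, float))


class TestEEMValidation:
    def test_zero_matrix_is_valid(self):
        eem = make_eem([200, 205, 210], [270, 275, 280], np.zeros((3, 3)))
        assert eem.shape == (3, 3)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            make_eem([200, 205], [270, 275, 280], np.zeros((3, 3)))

    def test_negative_intensity_rejected(self):
        z = np.zeros((3, 3))
        z[1, 2] = -1.0
        with pytest.raises(ValidationError, match="negative"):
            make_eem([200, 205, 210], [270, 275, 280], z)

    @pytest.mark.parametrize("grid", [[200, 210, 205], [200, 205, 215]])
    def test_bad_grids_rejected(self, grid):
        with pytest.raises(FormatError):
            make_eem(grid, [270, 275, 280], np.zeros((3, 3)))


class TestEEMIO:
    def test_round_trip_lossless(self, tmp_path, hsa_eem):
        path = tmp_path / "eem.csv"
        qf.write_eem(hsa_eem, path, header_comment="seed=0")
        back = qf.read_eem(path)
        np.testing.assert_array_equal(back.intensity, hsa_eem.intensity)
        np.testing.assert_array_equal(back.excitation_grid, hsa_eem.excitation_grid)
        np.testing.assert_array_equal(back.emission_grid, hsa_eem.emission_grid)

    def test_zero_case(self, tmp_path):
        eem = make_eem([200, 205, 210], [270, 275, 280], np.zeros((3, 3)))
        path = tmp_path / "zero.csv"
        qf.write_eem(eem, path)
        assert qf.read_eem(path).intensity.sum() == 0.0

    def test_synthetic_file_max_matches_generator(self, tmp_path):
        cfg = qf.hsa_eem_config(baseline_sigma=2.0, seed=1)
        eem = qf.simulate_eem(cfg)
        path = tmp_path / "noisy.csv"
        qf.write_eem(eem, path)
        back = qf.read_eem(path)
        # the dominant tryptophan/tyrosine peak (amp 1803) sets the max
        assert back.intensity.max() == pytest.approx(1803.0, rel=0.02)

    def test_malformed_grid_names_offender(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(",270,275,280\n200,0,0,0\n195,0,0,0\n", encoding="utf-8")
        with pytest.raises(FormatError, match="excitation"):
            qf.read_eem(path)

    def test_negative_cell_rejected_on_read(self, tmp_path):
        path = tmp_path / "neg.csv"
        path.write_text(",270,275\n200,0,-3\n205,0,0\n", encoding="utf-8")
        with pytest.raises(ValidationError):
            qf.read_eem(path)


def gaussian_eem(centers_amps, ex=None, em=None):
    ex = np.arange(200.0, 341.0, 5.0) if ex is None else ex
    em = np.arange(270.0, 461.0, 5.0) if em is None else em
    z = np.zeros((ex.size, em.size))
    for (cx, cy, a) in centers_amps:
        z += a * np.exp(-((ex[:, None] - cx) ** 2) / (2 * 12.0 ** 2)
                        - ((em[None, :] - cy) ** 2) / (2 * 12.0 ** 2))
    return make_eem(ex, em, z)


class TestPeakDetection:
    def test_single_gaussian_single_peak(self):
        eem = gaussian_eem([(280.0, 335.0, 100.0)])
        peaks = qf.detect_fluorescence_peaks(eem)
        assert len(peaks) == 1
        assert (peaks[0].excitation_nm, peaks[0].emission_nm) == (280.0, 335.0)

    def test_hsa_preset_two_peaks_at_stated_centers(self, hsa_eem):
        peaks = qf.detect_fluorescence_peaks(hsa_eem)
        assert len(peaks) == 2
        # sorted by decreasing intensity: trp/tyr peak first
        assert (peaks[0].excitation_nm, peaks[0].emission_nm) == (280.0, 335.0)
        assert (peaks[1].excitation_nm, peaks[1].emission_nm) == (235.0, 325.0)
        assert peaks[0].intensity == pytest.approx(1803.0, rel=0.01)
        assert peaks[1].intensity == pytest.approx(362.3, rel=0.01)

    def test_no_peaks_returns_empty_list(self):
        eem = make_eem([200, 205, 210], [270, 275, 280], np.zeros((3, 3)))
        assert qf.detect_fluorescence_peaks(eem) == []

    def test_bad_prominence_rejected(self, hsa_eem):
        with pytest.raises(DomainError):
            qf.detect_fluorescence_peaks(hsa_eem, min_prominence=0.0)

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1),
           st.integers(min_value=4, max_value=50),
           st.integers(min_value=4, max_value=50))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_brute_force_on_random_grids(self, seed, nex, nem):
        rng = np.random.default_rng(seed)
        ex = 200.0 + 5.0 * np.arange(nex)
        em = 250.0 + 5.0 * np.arange(nem)
        eem = make_eem(ex, em, rng.uniform(0, 100, (nex, nem)))
        got = [(p.excitation_nm, p.emission_nm, p.intensity)
               for p in qf.detect_fluorescence_peaks(eem, 10.0, 0.05)]
        assert got == brute_force_peaks(eem, 10.0, 0.05)


class TestRayleighRidge:
    def test_hsa_preset_ridge(self, hsa_eem):
        ridge = qf.locate_rayleigh_ridge(hsa_eem)
        assert ridge.kind == "rayleigh_first_order"
        assert (ridge.excitation_nm, ridge.emission_nm) == (290.0, 290.0)
        assert ridge.intensity == pytest.approx(1058.0, rel=0.01)

    def test_zero_matrix_first_in_band_cell(self):
        eem = make_eem([270, 275, 280], [270, 275, 280], np.zeros((3, 3)))
        ridge = qf.locate_rayleigh_ridge(eem, 10.0)
        assert ridge.intensity == 0.0
        # tie-break: first in-band cell in grid order
        assert (ridge.excitation_nm, ridge.emission_nm) == (270.0, 270.0)

    def test_no_overlap_is_domain_error(self):
        eem = make_eem([200, 205, 210], [400, 405, 410], np.zeros((3, 3)))
        with pytest.raises(DomainError):
            qf.locate_rayleigh_ridge(eem, 10.0)

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_brute_force_and_dominates_band(self, seed):
        rng = np.random.default_rng(seed)
        ex = 250.0 + 5.0 * np.arange(12)
        em = 250.0 + 5.0 * np.arange(15)
        eem = make_eem(ex, em, rng.uniform(0, 50, (12, 15)))
        ridge = qf.locate_rayleigh_ridge(eem, 10.0)
        bx, by, bv = brute_force_ridge_max(eem, 10.0)
        assert (ridge.excitation_nm, ridge.emission_nm, ridge.intensity) == (bx, by, bv)
        band = np.abs(ex[:, None] - em[None, :]) <= 10.0
        assert ridge.intensity >= eem.intensity[band].max()


class TestEmissionMaximum:
    def test_constructed_mode(self):
        wl = np.arange(285.0, 431.0, 5.0)
        it = np.exp(-((wl - 335.0) ** 2) / 200.0)
        assert qf.emission_maximum(qf.EmissionScan(wl, it))[0] == 335.0

    def test_monotone_decreasing_returns_shortest(self):
        wl = np.arange(285.0, 431.0, 5.0)
        scan = qf.EmissionScan(wl, np.linspace(10, 1, wl.size))
        assert qf.emission_maximum(scan)[0] == 285.0

    def test_flat_scan_warns(self, caplog):
        wl = np.arange(285.0, 301.0, 5.0)
        scan = qf.EmissionScan(wl, np.ones(wl.size))
        with caplog.at_level("WARNING"):
            out = qf.emission_maximum(scan)
        assert out == (285.0, 1.0)
        assert any("flat" in rec.message for rec in caplog.records)


class TestPeakShift:
    def test_default_blue_shift(self):
        cfg = qf.TitrationSimConfig(model="modified_sv", fa=0.8, ksv=1500.0, seed=1)
        series = qf.simulate_titration_scans(cfg)
        assert qf.peak_shift(series) == pytest.approx(-25.0)

    def test_generator_shift_parameter_exact(self):
        cfg = qf.TitrationSimConfig(model="modified_sv", fa=0.8, ksv=1500.0, seed=1)
        series = qf.simulate_titration_scans(cfg, peak_shift_total_nm=-10.0)
        assert qf.peak_shift(series) == -10.0

    def test_identical_scans_zero_shift(self):
        cfg = qf.TitrationSimConfig(model="modified_sv", fa=0.8, ksv=1500.0, seed=1)
        series = qf.simulate_titration_scans(cfg, peak_shift_total_nm=0.0)
        assert qf.peak_shift(series) == 0.0

    def test_antisymmetric_under_scan_swap(self):
        cfg = qf.TitrationSimConfig(model="modified_sv", fa=0.8, ksv=1500.0, seed=1)
        series = qf.simulate_titration_scans(cfg)
        fwd = qf.peak_shift(series)
        swapped = qf.TitrationSeries(
            series.ligand_id, series.concentrations, series.intensities,
            tuple(series.scans[::-1]))
        # the C=0 slot now holds the most-quenched scan and vice versa
        assert qf.peak_shift(swapped) == -fwd

    def test_scalar_series_raises_capability_error(self, sv_series):
        with pytest.raises(CapabilityError, match="scalar"):
            qf.peak_shift(sv_series)
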