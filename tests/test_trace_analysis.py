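"""Intensity profiles → lengths, counts, QC, tension bins, activation thresholds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vwflow.hydrodynamics import FlowCondition, average_monomer_force, tension_profile
from vwflow.polymer import Concatemer
from vwflow.trace_analysis import (
    CalibrationParams,
    IntensityProfile,
    activation_call,
    bin_by_tension,
    estimate_single_fluor_intensity,
    fit_activation_threshold,
    intensity_to_count,
    measure_length,
    monomer_extension,
    qc_filter,
    threshold_stress,
)

CALIB = CalibrationParams(single_fluor_intensity=200.0, degree_of_labeling=0.67)


def top_hat_profile(extent_um=3.0, start_um=2.0, pixel=0.05, total_um=10.0,
                    amplitude=100.0, noise_sd=0.0, rng=None, ligand=None):
    x = np.arange(0.0, total_um, pixel)
    y = np.where((x >= start_um) & (x < start_um + extent_um), amplitude, 0.0)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, y.size)
    return IntensityProfile(positions=x, vwf_channel=y, ligand_channel=ligand)


class TestMeasureLength:
    def test_known_extent_at_snr20(self):
        rng = np.random.default_rng(1)
        prof = top_hat_profile(extent_um=3.0, amplitude=100.0, noise_sd=5.0, rng=rng)
        m = measure_length(prof)
        assert m.detected
        assert m.length_um == pytest.approx(3.0, abs=0.1)

    def test_all_background_not_detected(self):
        rng = np.random.default_rng(2)
        prof = top_hat_profile(amplitude=0.0, noise_sd=5.0, rng=rng)
        m = measure_length(prof)
        assert not m.detected
        assert m.length_um == 0.0

    def test_single_bright_pixel(self):
        x = np.arange(0.0, 5.0, 0.05)
        y = np.zeros(x.size)
        y[40] = 1000.0
        prof = IntensityProfile(positions=x, vwf_channel=y)
        m = measure_length(prof)
        assert m.detected
        assert m.length_um == pytest.approx(0.05, abs=1e-9)


class TestIntensityToCount:
    def test_vwf_monomer_count(self):
        # 67 single-fluorophore units at 0.67 labels/monomer → 100 monomers
        assert intensity_to_count(67 * 200.0, CALIB) == pytest.approx(100.0)

    def test_zero(self):
        assert intensity_to_count(0.0, CALIB) == 0.0

    def test_ligand_dol(self):
        calib = CalibrationParams(200.0, 1.01)
        assert intensity_to_count(200.0 * 1.01 * 5, calib) == pytest.approx(5.0)

    @given(count=st.floats(0.1, 1e4), single=st.floats(10.0, 1e4),
           dol=st.floats(0.1, 2.0))
    @settings(derandomize=True, max_examples=50)
    def test_round_trip(self, count, single, dol):
        calib = CalibrationParams(single, dol)
        assert intensity_to_count(count * dol * single, calib) == pytest.approx(count, rel=1e-9)

    def test_tirf_height_correction(self):
        flat = intensity_to_count(1000.0, CALIB)
        corrected = intensity_to_count(1000.0, CALIB, dye_height=10.0)
        assert corrected > flat  # attenuated signal maps to a larger count

    def test_zero_calibration_rejected(self):
        calib = CalibrationParams(0.0, 0.67)
        with pytest.raises(ValueError):
            intensity_to_count(100.0, calib)


class TestPhotobleachCalibration:
    def test_three_equal_steps(self):
        rng = np.random.default_rng(3)
        s = 200.0
        levels = np.concatenate([np.full(30, 3 * s), np.full(30, 2 * s),
                                 np.full(30, s), np.full(30, 0.0)])
        trace = levels + rng.normal(0.0, s / 10.0, levels.size)
        assert estimate_single_fluor_intensity(trace) == pytest.approx(s, rel=0.05)

    def test_single_step(self):
        trace = np.concatenate([np.full(20, 150.0), np.full(20, 0.0)])
        assert estimate_single_fluor_intensity(trace) == pytest.approx(150.0, rel=0.01)

    def test_smooth_ramp_fails(self):
        with pytest.raises(ValueError):
            estimate_single_fluor_intensity(np.linspace(100.0, 0.0, 60))


class TestMonomerExtension:
    @pytest.mark.parametrize("length,n,expected", [
        (6.0, 100, 60.0),   # fully extended, EM-like contour
        (2.0, 100, 20.0),   # the QC exclusion boundary
        (0.0, 100, 0.0),
    ])
    def test_values(self, length, n, expected):
        assert monomer_extension(length, n) == pytest.approx(expected)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            monomer_extension(1.0, 0)


class TestQcFilter:
    def test_low_extension_fraction(self):
        """A cohort built with 16% sub-20 nm/monomer concatemers loses ≈16%."""
        rows = []
        for cid in range(100):
            ext = 15.0 if cid < 16 else 40.0  # nm per monomer
            for rep in range(2):
                rows.append({"concatemer_id": cid, "shear_dyn_cm2": 1280.0,
                             "length_um": 100 * ext / 1000.0, "n_monomers": 100})
        result, counts = qc_filter(pd.DataFrame(rows))
        assert counts["low_extension"] == 16
        assert counts["kept"] == 84

    def test_identical_repeats_kept(self):
        rows = [{"concatemer_id": 0, "shear_dyn_cm2": 1280.0,
                 "length_um": 4.0, "n_monomers": 100}] * 3
        result, counts = qc_filter(pd.DataFrame(rows))
        assert result["keep"].all()

    def test_irreproducible_length_excluded(self):
        rows = [
            {"concatemer_id": 0, "shear_dyn_cm2": 640.0, "length_um": 4.0, "n_monomers": 100},
            {"concatemer_id": 0, "shear_dyn_cm2": 640.0, "length_um": 2.0, "n_monomers": 100},
        ]
        result, counts = qc_filter(pd.DataFrame(rows))
        assert counts["length_cv"] == 1
        assert not result["keep"].iloc[0]

    def test_single_observation_flagged_unevaluated(self):
        rows = [{"concatemer_id": 0, "shear_dyn_cm2": 640.0,
                 "length_um": 4.0, "n_monomers": 100}]
        result, counts = qc_filter(pd.DataFrame(rows))
        assert result["keep"].iloc[0]
        assert not result["cv_evaluated"].iloc[0]
        assert counts["cv_unevaluated"] == 1


def uniform_ligand_profile(n_monomers, length_um, ligand_per_pixel=101.0,
                           pixel=0.05, margin=1.0):
    total = length_um + 2 * margin
    x = np.arange(0.0, total, pixel)
    inside = (x >= margin) & (x < margin + length_um)
    vwf = np.where(inside, 1000.0, 0.0)
    lig = np.where(inside, ligand_per_pixel, 0.0)
    return IntensityProfile(positions=x, vwf_channel=vwf, ligand_channel=lig)


class TestBinByTension:
    LIG_CALIB = CalibrationParams(100.0, 1.01)

    def test_long_concatemer_spans_seven_bins(self):
        cm = Concatemer(150, 0)
        tp = tension_profile(cm, FlowCondition(1280.0))
        prof = uniform_ligand_profile(150, 6.0)
        out = bin_by_tension(prof, tp, self.LIG_CALIB)
        assert len(out) == 7
        assert not out.attrs["incomplete"]
        assert list(out["bin_low"]) == [0.0, 8.0, 16.0, 24.0, 32.0, 40.0, 48.0]

    def test_short_concatemer_two_bins(self):
        # 20 monomers at ~0.5 pN/monomer: max tension ~10 pN → bins [0,8), [8,16)
        cm = Concatemer(20, 0)
        tp = tension_profile(cm, FlowCondition(1280.0))
        prof = uniform_ligand_profile(20, 1.2)
        out = bin_by_tension(prof, tp, self.LIG_CALIB)
        assert list(out["bin_low"]) == [0.0, 8.0]
        assert out.attrs["incomplete"]

    def test_zero_ligand_channel(self):
        cm = Concatemer(150, 0)
        tp = tension_profile(cm, FlowCondition(1280.0))
        prof = uniform_ligand_profile(150, 6.0, ligand_per_pixel=0.0)
        out = bin_by_tension(prof, tp, self.LIG_CALIB)
        assert (out["ligand_per_um"] == 0.0).all()

    def test_density_bookkeeping(self):
        """Sum over bins of density × bin length equals the total ligand count
        (110 monomers: every site stays below the 56 pN bin ceiling)."""
        cm = Concatemer(110, 0)
        tp = tension_profile(cm, FlowCondition(1280.0))
        prof = uniform_ligand_profile(110, 5.0, ligand_per_pixel=101.0)
        out = bin_by_tension(prof, tp, self.LIG_CALIB)
        total_from_bins = (out["ligand_per_um"] * out["length_um"]).sum()
        inside = prof.ligand_channel > 0
        total_direct = intensity_to_count(prof.ligand_channel[inside].sum(), self.LIG_CALIB)
        assert total_from_bins == pytest.approx(total_direct, abs=1.0)


class TestActivationCall:
    def test_strong_signal(self):
        rng = np.random.default_rng(5)
        bg = rng.normal(0.0, 1.0, 500)
        roi = np.full(5, 10.0)
        assert activation_call(roi, bg)

    def test_background_false_positive_rate(self):
        """Noise-only ROIs trip the 3-SD, 3-frame criterion only rarely."""
        rng = np.random.default_rng(6)
        bg = rng.normal(0.0, 1.0, 2000)
        false_pos = sum(
            activation_call(rng.normal(0.0, 1.0, 3), bg) for _ in range(2000)
        )
        assert false_pos / 2000 < 0.01

    def test_exactly_at_threshold_is_negative(self):
        bg = np.array([0.0, 2.0, 0.0, 2.0] * 25)
        thr = bg.mean() + 3 * bg.std(ddof=0)
        assert not activation_call(np.full(5, thr), bg)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            activation_call(np.ones(5), np.array([]))


class TestThresholdStress:
    def test_first_positive_sigma(self):
        calls = [(80.0, False), (480.0, False), (720.0, True), (1280.0, True)]
        res = threshold_stress(calls)
        assert res.defined
        assert res.sigma_t == 720.0
        assert not res.inconsistent

    def test_never_activated(self):
        res = threshold_stress([(80.0, False), (480.0, False)])
        assert not res.defined
        assert np.isnan(res.sigma_t)

    def test_inconsistent_calls_flagged(self):
        res = threshold_stress([(80.0, True), (480.0, False), (720.0, True)])
        assert res.sigma_t == 80.0
        assert res.inconsistent

    def test_non_monotone_schedule_rejected(self):
        with pytest.raises(ValueError):
            threshold_stress([(480.0, False), (80.0, True)])


class TestActivationThresholdFit:
    def test_exact_hyperbola(self):
        b_true = 6.9e4
        rng = np.random.default_rng(7)
        sizes = rng.integers(20, 201, 240)
        records = pd.DataFrame({"n_vwf": sizes, "sigma_t": b_true / sizes})
        res = fit_activation_threshold(records)
        assert res.b == pytest.approx(b_true, rel=1e-6)

    def test_tension_threshold_uniformity(self):
        """A pure tension threshold: max tension at σ_T is size-independent
        while σ_T itself spans several-fold."""
        b_true = 6.9e4
        rng = np.random.default_rng(8)
        sizes = np.exp(rng.uniform(np.log(20), np.log(200), 240)).astype(int)
        records = pd.DataFrame({"n_vwf": sizes, "sigma_t": b_true / sizes})
        res = fit_activation_threshold(records)
        assert res.max_tension_cv < 0.15
        sigma50 = res.per_bin["sigma50"]
        assert sigma50.max() / sigma50.min() > 3.0
        # the uniform tension level is f_mono(b)·1 by construction
        expected = average_monomer_force(FlowCondition(b_true))
        assert res.median_max_tension == pytest.approx(expected, rel=0.02)

    def test_too_few_bins_rejected(self):
        records = pd.DataFrame({"n_vwf": [30] * 10, "sigma_t": [2000.0] * 10})
        with pytest.raises(ValueError):
            fit_activation_threshold(records)
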