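"""Synthetic-data generator: determinism, distributions, exact simulators."""

import dataclasses

import numpy as np
import pytest

from vwflow.kinetics import KineticsParams, association_curve
from vwflow.polymer import Concatemer
from vwflow.synthetic import (
    SimConfig,
    preset_10mM,
    preset_150mM,
    render_profile,
    sample_cohort,
    simulate_binding,
    simulate_extension,
    simulate_photobleach,
    simulate_telegraph,
    steady_extension,
)
from vwflow.trace_analysis import measure_length


class TestConfig:
    def test_seed_mandatory(self):
        with pytest.raises((TypeError, ValueError)):
            SimConfig(seed=None)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, k_off=-1.0)
        with pytest.raises(ValueError):
            SimConfig(seed=1, relax_amplitude=1.5)

    def test_json_round_trip(self, tmp_path):
        cfg = preset_10mM(seed=42)
        path = tmp_path / "cfg.json"
        cfg.to_json(path)
        assert SimConfig.from_json(path) == cfg

    def test_unknown_field_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"seed": 1, "bogus_knob": 3}')
        with pytest.raises(ValueError, match="bogus_knob"):
            SimConfig.from_json(path)


class TestCohort:
    def test_reproducible_under_seed(self):
        c1 = sample_cohort(SimConfig(seed=5, cohort_size=112))
        c2 = sample_cohort(SimConfig(seed=5, cohort_size=112))
        assert len(c1) == len(c2) == 112
        for a, b in zip(c1, c2):
            assert a.n_monomers == b.n_monomers
            assert a.tether_monomer_index == b.tether_monomer_index
            np.testing.assert_array_equal(a.fluorophores_per_monomer,
                                          b.fluorophores_per_monomer)

    def test_size_bounds_and_end_bias(self, config):
        cohort = sample_cohort(config)
        for cm in cohort:
            assert 20 <= cm.n_monomers <= 200
            # tether within the terminal 10% of either end
            offset = min(cm.tether_monomer_index, cm.n_monomers - 1 - cm.tether_monomer_index)
            assert offset <= 0.1 * cm.n_monomers

    def test_labeling_density(self):
        cohort = sample_cohort(SimConfig(seed=3, cohort_size=500))
        fluors = np.concatenate([cm.fluorophores_per_monomer for cm in cohort])
        assert fluors.size > 1e4
        assert fluors.mean() == pytest.approx(0.67, abs=0.02)


class TestTelegraph:
    def test_stationary_occupancy(self):
        """Long-run per-site occupancy matches the analytic telegraph law."""
        rng = np.random.default_rng(21)
        kon, koff = 5.0, 3.9
        frames = np.array([3.0])  # ~27 relaxation times
        states = simulate_telegraph(np.full(10_000, kon), koff, frames, rng)
        p_hat = states[:, 0].mean()
        p_true = kon / (kon + koff)
        se = np.sqrt(p_true * (1 - p_true) / 10_000)
        assert abs(p_hat - p_true) < 3 * se

    def test_matches_association_curve(self):
        """Ensemble mean over 1000 sites tracks the 1:1 kinetic model within 3 SE."""
        rng = np.random.default_rng(22)
        frames = np.arange(1, 35) / 57.0
        states = simulate_telegraph(np.full(1000, 5.0), 3.9, frames, rng)
        mean = states.mean(axis=0)
        params = KineticsParams(k_on=50e6, k_off=3.9, n_total=1.0,
                                ligand_concentration=100.0)
        pred = association_curve(frames, params)
        se = np.sqrt(np.maximum(pred * (1 - pred), 1e-12) / 1000)
        assert np.all(np.abs(mean - pred) < 3 * se + 1e-9)

    def test_zero_on_rate_never_binds(self):
        rng = np.random.default_rng(23)
        states = simulate_telegraph(np.zeros(100), 3.9, np.arange(1, 10) * 0.1, rng)
        assert not states.any()


class TestExtension:
    def test_saturation_and_compact_limits(self, config):
        assert steady_extension(1280.0, 5.0, config) == pytest.approx(5.0)
        assert steady_extension(10.0, 5.0, config) == config.compact_size_um
        assert steady_extension(15.0, 5.0, config) == config.compact_size_um

    def test_relaxation_tau_power_law(self):
        cfg = SimConfig(seed=1, tau_scatter_sigma_log=0.0)
        rng = np.random.default_rng(0)
        cm = Concatemer(100, 0)
        schedule = [(1280.0, 0.2), (0.0, 2.0)]
        _, truth4 = simulate_extension(cm, schedule, cfg, rng, extension_per_monomer=40.0)
        _, truth1 = simulate_extension(cm, schedule, cfg, rng, extension_per_monomer=10.0)
        ratio = truth4["true_tau_s"] / truth1["true_tau_s"]
        assert ratio == pytest.approx(4.0**0.59, rel=1e-9)

    def test_binding_shielded_when_compact(self, config, rng):
        cm = Concatemer(100, 0)
        states = simulate_binding(cm, sigma=10.0, concentration_nM=100.0,
                                  frame_times=np.arange(1, 10) * 0.1,
                                  config=config, rng=rng)
        assert not states.any()


class TestRendering:
    def test_zero_fluorophores_noise_floor(self, config, rng):
        cm = Concatemer(50, 0, np.zeros(50, dtype=int))
        prof = render_profile(cm, 2.0, np.zeros(50, dtype=bool), config, rng)
        assert abs(prof.vwf_channel.mean()) < 3 * config.read_noise_sd
        assert prof.vwf_channel.std() < 2 * config.read_noise_sd

    def test_signal_bookkeeping(self, config):
        """Integrated VWF signal ≈ fluorophore count × single-fluor × attenuation."""
        from vwflow.hydrodynamics import tirf_attenuation

        rng = np.random.default_rng(31)
        cm = Concatemer(150, 0, rng.poisson(0.67, 150))
        prof = render_profile(cm, 6.0, np.zeros(150, dtype=bool), config, rng)
        atten = tirf_attenuation(config.vwf_height, config.reference_height,
                                 config.tirf_penetration_depth)
        expected = cm.total_fluorophores * config.single_fluor_vwf * atten
        assert prof.vwf_channel.sum() == pytest.approx(expected, rel=0.05)

    def test_compact_state_single_spot(self, config):
        rng = np.random.default_rng(32)
        cm = Concatemer(100, 0, rng.poisson(0.67, 100))
        prof = render_profile(cm, config.compact_size_um, np.zeros(100, dtype=bool),
                              config, rng)
        assert measure_length(prof).detected
        # intensity-weighted spot width stays within ~2× the PSF width
        y = np.clip(prof.vwf_channel, 0.0, None)
        x = prof.positions
        mu = np.average(x, weights=y)
        width = np.sqrt(np.average((x - mu) ** 2, weights=y))
        assert width <= 2 * config.psf_sigma_um


class TestPhotobleach:
    def test_single_fluorophore_single_step(self, config):
        rng = np.random.default_rng(41)
        trace = simulate_photobleach(1, config, rng)
        head, tail = trace[:3].mean(), trace[-3:].mean()
        assert head - tail == pytest.approx(config.single_fluor_vwf, rel=0.25)

    def test_mean_step_size(self, config):
        """Generator bookkeeping: the mean bleach step is the configured
        single-fluorophore intensity."""
        rng = np.random.default_rng(42)
        steps = []
        for _ in range(400):
            tr = simulate_photobleach(1, config, rng, duration=15.0)
            steps.append(tr[0] - tr[-1])
        assert np.mean(steps) == pytest.approx(config.single_fluor_vwf, rel=0.02)

    def test_zero_bleach_rate_constant_trace(self):
        cfg = SimConfig(seed=1, bleach_rate=0.0)
        rng = np.random.default_rng(43)
        trace = simulate_photobleach(5, cfg, rng, duration=2.0)
        assert np.ptp(trace) < 8 * cfg.read_noise_sd


def test_end_to_end_determinism(tmp_path):
    """Identical config + seed produce byte-identical datasets."""
    from vwflow.synthetic import generate_equilibrium_binding_dataset

    cfg = preset_150mM(seed=77)
    bins1, _ = generate_equilibrium_binding_dataset(cfg, n_concatemers=20)
    bins2, _ = generate_equilibrium_binding_dataset(cfg, n_concatemers=20)
    assert [dataclasses.astuple(b) for b in bins1] == [dataclasses.astuple(b) for b in bins2]
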