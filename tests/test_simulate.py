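"""Synthetic-data generator: CTMC statistics, photon counts, determinism."""

import numpy as np
import pytest

from getfret.kinetics import ChaseModelSpec
from getfret.simulate import (
    SimConfig,
    SimulationError,
    simulate_chase_trace,
    simulate_photon_stream,
    simulate_state_path,
    stationary_distribution,
    three_state_config,
    three_state_emission,
)


class TestStatePath:
    def test_absorbing_case_single_dwell(self):
        path = simulate_state_path(np.zeros((3, 3)), 5.0, seed=0)
        assert len(path.states) == 1
        assert path.boundaries[0] == 0.0 and path.boundaries[-1] == 5.0

    def test_mean_dwell_matches_exponential(self):
        """Symmetric 100/s chain: mean dwell ~ 1/k within 3 standard errors."""
        k = 100.0
        path = simulate_state_path(np.array([[0, k], [k, 0]]), 100.0, seed=1)
        d = path.dwell_durations()[:-1]  # last dwell censored by duration
        assert d.size >= 5000
        se = d.std(ddof=1) / np.sqrt(d.size)
        assert abs(d.mean() - 1.0 / k) < 3 * se

    def test_time_fraction_matches_stationary(self):
        """k12=200, k21=100 -> one third of the time in state 1."""
        rates = np.array([[0, 200.0], [100.0, 0]])
        assert np.allclose(stationary_distribution(rates), [1 / 3, 2 / 3])
        path = simulate_state_path(rates, 200.0, seed=2)
        d = path.dwell_durations()
        frac = d[path.states == 0].sum() / d.sum()
        assert abs(frac - 1 / 3) < 0.02

    def test_invalid_rate_matrix_rejected(self):
        with pytest.raises(SimulationError):
            simulate_state_path(np.array([[0, -1.0], [1.0, 0]]), 1.0)
        with pytest.raises(SimulationError):
            simulate_state_path(np.zeros((2, 3)), 1.0)


class TestPhotonStream:
    def test_no_fret_limit_every_donor_photon_is_dd(self):
        cfg = SimConfig(
            duration=5.0,
            state_rates=np.zeros((1, 1)),
            state_emission=np.array([[30e3, 0.0, 30e3]]),
            background_rates=(0.0, 0.0, 0.0),
            species_fractions=(1.0, 0.0, 0.0),
            seed=3,
        )
        counts = simulate_photon_stream(cfg).stream_counts()
        assert counts["DA"] == 0 and counts["DD"] > 0

    def test_pure_background_poisson_count(self):
        """3 x 1 kHz background over 100 s -> ~3e5 photons."""
        cfg = SimConfig(
            duration=100.0,
            state_rates=np.zeros((1, 1)),
            state_emission=np.array([[0.0, 0.0, 0.0]]),
            burst_rate=0.0,
            background_rates=(1e3, 1e3, 1e3),
            seed=4,
        )
        n = len(simulate_photon_stream(cfg))
        assert abs(n - 3e5) < 4 * np.sqrt(3e5)

    def test_timestamps_sorted_and_quantized(self, dynamic_stream):
        assert (np.diff(dynamic_stream.timestamps) >= 0).all()
        assert dynamic_stream.timestamps.dtype == np.int64

    def test_same_seed_reproduces_exactly(self):
        cfg = three_state_config(100.0, 200.0, duration=3.0, seed=7)
        a = simulate_photon_stream(cfg)
        b = simulate_photon_stream(three_state_config(100.0, 200.0, duration=3.0, seed=7))
        assert np.array_equal(a.timestamps, b.timestamps)
        assert np.array_equal(a.detector, b.detector)
        assert np.array_equal(a.excitation, b.excitation)

    def test_different_seed_differs(self):
        a = simulate_photon_stream(three_state_config(100.0, 200.0, duration=3.0, seed=7))
        b = simulate_photon_stream(three_state_config(100.0, 200.0, duration=3.0, seed=8))
        assert not np.array_equal(a.timestamps, b.timestamps)

    def test_per_stream_rates_reconstruct_intensities(self):
        """Delivered stream counts match the generating Poisson intensities."""
        cfg = SimConfig(
            duration=50.0,
            state_rates=np.zeros((1, 1)),
            state_emission=np.array([[20e3, 10e3, 24e3]]),
            burst_rate=0.0,
            background_rates=(500.0, 200.0, 800.0),
            seed=5,
        )
        counts = simulate_photon_stream(cfg).stream_counts()
        for key, rate in (("DD", 500.0), ("DA", 200.0), ("AA", 800.0)):
            expect = rate * cfg.duration
            assert abs(counts[key] - expect) < 5 * np.sqrt(expect)

    def test_occupancy_without_switching_matches_initial_draw(self):
        """Frozen chain: per-burst state frequencies follow the initial draw."""
        em = three_state_emission(0.1, 0.9)[:2]
        cfg = SimConfig(
            duration=40.0,
            state_rates=np.zeros((2, 2)),
            state_emission=em,
            background_rates=(0.0, 0.0, 0.0),
            seed=6,
        )
        s = simulate_photon_stream(cfg)
        lab = s.stream_labels()
        nda = np.sum(lab == 1)
        ndd = np.sum(lab == 0)
        e_global = nda / (ndd + nda)
        # equal initial-draw probabilities -> mean E* ~ 0.5
        assert abs(e_global - 0.5) < 0.05


class TestSimConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = three_state_config(44.2, 200.0, duration=12.0, seed=9)
        p = tmp_path / "cfg.yaml"
        cfg.save(p)
        cfg2 = SimConfig.load(p)
        assert np.array_equal(cfg.state_rates, cfg2.state_rates)
        assert np.array_equal(cfg.state_emission, cfg2.state_emission)
        assert cfg2.seed == 9 and cfg2.duration == 12.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"species_fractions": (0.5, 0.4, 0.2)},
            {"donor_fraction_of_period": 1.2},
            {"clock_period": 1e-5},
            {"burst_duration_mean": -1.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(SimulationError):
            SimConfig(**kwargs)


def test_chase_trace_no_chase_is_flat_zero():
    trace = simulate_chase_trace(
        ChaseModelSpec.invasion(0.0), np.linspace(1e-6, 30, 40), noise_sd=0.0
    )
    assert np.allclose(trace.fluorescence, 0.0, atol=1e-9)


def test_chase_trace_noise_level():
    t = np.linspace(1e-6, 30, 400)
    tr = simulate_chase_trace(ChaseModelSpec.spontaneous(20.0), t, noise_sd=0.05, seed=1)
    tr0 = simulate_chase_trace(ChaseModelSpec.spontaneous(20.0), t, noise_sd=0.0)
    resid = tr.fluorescence - tr0.fluorescence
    assert 0.03 < resid.std() < 0.07
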