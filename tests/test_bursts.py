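"""Background estimation, burst search, filters, E*/S."""

import numpy as np
import pytest

from getfret.bursts import (
    Burst,
    BurstAnalysisError,
    burst_search,
    compute_es,
    dual_channel_burst_search,
    es_histogram,
    estimate_background,
    filter_bursts,
    _intersect_intervals,
)
from getfret.simulate import SimConfig, simulate_photon_stream, three_state_emission

from conftest import build_stream


def poisson_stream(rate, duration, seed, clock=100e-9, stream_cycle=(0, 1, 2)):
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration)
    ticks = np.sort(rng.integers(0, int(duration / clock), n))
    streams = np.resize(np.asarray(stream_cycle), n)
    return build_stream(ticks, streams, clock=clock, duration=duration)


class TestBackground:
    def test_homogeneous_rate_recovered_within_5pc(self):
        s = poisson_stream(2000.0, 100.0, seed=1)
        bg = estimate_background(s, interval=50.0)
        for est in bg:
            assert abs(est.rates["all"] - 2000.0) / 2000.0 < 0.05

    def test_short_acquisition_single_interval(self):
        s = poisson_stream(1000.0, 49.0, seed=2)
        bg = estimate_background(s, interval=50.0)
        assert len(bg) == 1
        assert bg[0].t_start == 0.0

    def test_burst_stream_background_below_naive_rate(self, dynamic_stream):
        bg = estimate_background(dynamic_stream)
        naive = len(dynamic_stream) / dynamic_stream.duration
        assert all(est.rates["all"] < naive for est in bg)

    def test_empty_stream_rejected(self):
        with pytest.raises(BurstAnalysisError):
            estimate_background(build_stream([], []))


def cluster_stream(seed=3, n_cluster=50, clock=100e-9):
    """1 kHz background over 10 s + one dense cluster at ~100 kHz."""
    rng = np.random.default_rng(seed)
    bg_ticks = np.sort(rng.integers(0, int(10 / clock), 10_000))
    t0 = int(5.0 / clock)
    cl_ticks = t0 + np.sort(rng.integers(0, int(n_cluster / 100e3 / clock), n_cluster))
    ticks = np.sort(np.concatenate([bg_ticks, cl_ticks]))
    streams = np.resize([0, 1, 2], ticks.size)
    return build_stream(ticks, streams, clock=clock, duration=10.0), t0


class TestBurstSearch:
    def test_single_cluster_found_exactly_once(self):
        s, t0 = cluster_stream()
        bg = estimate_background(s)
        bursts = burst_search(s, background=bg, excitation_channel="all")
        assert len(bursts) == 1
        b = bursts[0]
        assert b.t_start >= t0 * s.clock_period - 1e-3
        assert b.n_dd + b.n_da + b.n_aa >= 40

    def test_cluster_below_minimum_photons_ignored(self):
        s, _ = cluster_stream(n_cluster=9)
        bg = estimate_background(s)
        assert burst_search(s, m=10, background=bg, excitation_channel="all") == []

    def test_pure_background_yields_no_bursts(self):
        s = poisson_stream(1500.0, 60.0, seed=4)
        bg = estimate_background(s)
        assert burst_search(s, background=bg, excitation_channel="all") == []

    def test_bursts_disjoint(self, dynamic_stream, dynamic_background):
        bursts = burst_search(
            dynamic_stream, background=dynamic_background, excitation_channel="donor"
        )
        assert len(bursts) > 10
        for a, b in zip(bursts[:-1], bursts[1:]):
            assert a.istop <= b.istart

    def test_background_required(self, dynamic_stream):
        with pytest.raises(BurstAnalysisError):
            burst_search(dynamic_stream, background=None)


class TestDualChannel:
    def test_donor_only_species_removed(self):
        cfg = SimConfig(
            duration=20.0,
            state_rates=np.zeros((3, 3)),
            state_emission=three_state_emission(0.2, 0.8),
            species_fractions=(0.0, 1.0, 0.0),  # donor-only
            seed=5,
        )
        s = simulate_photon_stream(cfg)
        bg = estimate_background(s)
        don = burst_search(s, background=bg, excitation_channel="donor")
        dcbs = dual_channel_burst_search(s, background=bg)
        assert len(don) > 20
        assert len(dcbs) <= len(don) * 0.05

    def test_intersection_contained_in_parent_spans(self, dynamic_stream, dynamic_background):
        don = burst_search(dynamic_stream, background=dynamic_background,
                           excitation_channel="donor")
        acc = burst_search(dynamic_stream, background=dynamic_background,
                           excitation_channel="acceptor")
        both = dual_channel_burst_search(dynamic_stream, background=dynamic_background)
        assert both
        for b in both:
            in_don = any(d.t_start - 1e-7 <= b.t_start and b.t_stop <= d.t_stop + 1e-7
                         for d in don)
            in_acc = any(a.t_start - 1e-7 <= b.t_start and b.t_stop <= a.t_stop + 1e-7
                         for a in acc)
            assert in_don and in_acc

    def test_interval_algebra_two_overlapping_vs_one_long(self):
        inter = _intersect_intervals([(0.0, 3.0), (2.0, 5.0)], [(1.0, 4.5)])
        assert inter == [(1.0, 3.0), (2.0, 4.5)]


class TestFilters:
    @pytest.mark.parametrize(
        "counts,kept",
        [
            ((20, 5, 3), False),   # n_AA below 15
            ((8, 7, 15), True),    # both thresholds met at the boundary
            ((7, 7, 20), False),   # donor-excitation sum below 15
            ((15, 0, 15), True),
        ],
    )
    def test_threshold_rules(self, counts, kept):
        b = Burst(0, 1, 0.0, 1e-3, *counts)
        assert (filter_bursts([b]) == [b]) is kept

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(6)
        bursts = [
            Burst(i, i + 1, 0.0, 1e-3, *rng.integers(0, 40, 3)) for i in range(300)
        ]
        once = filter_bursts(bursts)
        assert filter_bursts(once) == once
        stricter = filter_bursts(bursts, min_donor_exc=20, min_aa=20)
        assert set(id(b) for b in stricter) <= set(id(b) for b in once)


class TestES:
    @pytest.mark.parametrize(
        "counts,e,s",
        [
            ((30, 10, 40), 0.25, 0.5),
            ((17, 0, 12), 0.0, 17 / 29),
            ((0, 9, 0), 1.0, 1.0),
        ],
    )
    def test_es_arithmetic(self, counts, e, s):
        est, sst = compute_es(Burst(0, 1, 0.0, 1e-3, *counts))
        assert est == pytest.approx(e)
        assert sst == pytest.approx(s)

    def test_undefined_ratios_are_nan(self):
        b = Burst(0, 1, 0.0, 1e-3, 0, 0, 5)
        assert np.isnan(b.e_star)
        assert b.s == 0.0

    def test_histogram_rejects_empty_selection(self):
        bursts = [Burst(0, 1, 0.0, 1e-3, 30, 2, 1)]  # S ~ 0.97
        with pytest.raises(BurstAnalysisError):
            es_histogram(bursts)

    def test_static_mixture_is_bimodal(self):
        cfg = SimConfig(
            duration=60.0,
            state_rates=np.zeros((2, 2)),
            state_emission=three_state_emission(0.2, 0.8)[:2],
            seed=7,
        )
        s = simulate_photon_stream(cfg)
        bg = estimate_background(s)
        bursts = filter_bursts(dual_channel_burst_search(s, background=bg))
        hist = es_histogram(bursts)
        peaks = hist.peaks(min_fraction=0.02)
        low = peaks[peaks < 0.5]
        high = peaks[peaks > 0.5]
        assert low.size and abs(low[np.argmin(abs(low - 0.2))] - 0.2) < 0.05
        assert high.size and abs(high[np.argmin(abs(high - 0.8))] - 0.8) < 0.05


from hypothesis import given, settings, strategies as st


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    n_dd=st.integers(0, 500), n_da=st.integers(0, 500), n_aa=st.integers(0, 500)
)
def test_es_bounded_and_filter_monotone_property(n_dd, n_da, n_aa):
    """E*/S stay in [0,1] wherever defined; raising thresholds never keeps
    a burst that lower thresholds rejected."""
    b = Burst(0, 1, 0.0, 1e-3, n_dd, n_da, n_aa)
    if n_dd + n_da > 0:
        assert 0.0 <= b.e_star <= 1.0
    if n_dd + n_da + n_aa > 0:
        assert 0.0 <= b.s <= 1.0
    loose = bool(filter_bursts([b], 10, 10))
    strict = bool(filter_bursts([b], 15, 15))
    assert not (strict and not loose)
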