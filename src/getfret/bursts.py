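"""Burst search, filtering, and per-burst E*/S for µs-ALEX data.

Single-molecule transits are located by a sliding-window rate criterion: a
burst is a run of at least ``m`` consecutive photons whose local count rate
exceeds ``F``-fold the background rate, with the background re-estimated on
successive 50-s intervals by maximum-likelihood fitting of the interphoton
delay distribution.  For mixtures containing donor-only or acceptor-only
contaminants, a dual-channel burst search keeps only transits detected in
both the donor-excitation and acceptor-excitation photon streams.

Per burst, the apparent FRET efficiency and stoichiometry are

    E* = n_DA / (n_DD + n_DA)
    S  = (n_DD + n_DA) / (n_DD + n_DA + n_AA)

uncorrected for leakage, direct excitation, or gamma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .photons import PhotonStream, DD, DA, AA, DONOR_EXC, ACCEPTOR_EXC

logger = logging.getLogger(__name__)


class BurstAnalysisError(ValueError):
    pass


@dataclass
class BackgroundEstimate:
    """Per-interval background rates from the interphoton-delay tail fit."""

    interval_index: int
    t_start: float
    t_stop: float
    rates: dict[str, float]  # per second, keys DD/DA/AA/all
    n_delays_used: dict[str, int]
    thresholds: dict[str, float]


@dataclass
class Burst:
    """One single-molecule transit: photon span, stream counts, E*, S."""

    istart: int  # photon index on the full stream, half-open span
    istop: int
    t_start: float
    t_stop: float
    n_dd: int
    n_da: int
    n_aa: int

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    @property
    def n_donor_exc(self) -> int:
        return self.n_dd + self.n_da

    @property
    def e_star(self) -> float:
        d = self.n_dd + self.n_da
        return self.n_da / d if d > 0 else np.nan

    @property
    def s(self) -> float:
        tot = self.n_dd + self.n_da + self.n_aa
        return (self.n_dd + self.n_da) / tot if tot > 0 else np.nan


def compute_es(burst: Burst) -> tuple[float, float]:
    """(E*, S) of a burst; NaN where the defining ratio is undefined."""
    return burst.e_star, burst.s


def make_burst(stream: PhotonStream, istart: int, istop: int) -> Burst:
    labels = stream.stream_labels()[istart:istop]
    times = stream.times
    return Burst(
        istart=int(istart),
        istop=int(istop),
        t_start=float(times[istart]),
        t_stop=float(times[istop - 1]) if istop > istart else float(times[istart]),
        n_dd=int(np.sum(labels == DD)),
        n_da=int(np.sum(labels == DA)),
        n_aa=int(np.sum(labels == AA)),
    )


# ---------------------------------------------------------------------------
# Background estimation
# ---------------------------------------------------------------------------

def _tail_mle_rate(times: np.ndarray) -> tuple[float, int, float]:
    """Censored-exponential MLE of the background rate from delay tails.

    Delays above 4x the median delay are taken as pure-background; for an
    exponential, the tail above a threshold is exponential with the same
    rate, so rate = 1 / (mean(tail) - threshold).
    Returns (rate, n_delays_used, threshold); rate 0 when undetermined.
    """
    if times.size < 2:
        return 0.0, 0, 0.0
    delays = np.diff(times)
    thr = 4.0 * np.median(delays)
    tail = delays[delays > thr]
    if tail.size == 0 or tail.mean() <= thr:
        return 0.0, 0, thr
    return 1.0 / (tail.mean() - thr), int(tail.size), float(thr)


_BG_KEYS = ("DD", "DA", "AA", "all")


def estimate_background(
    stream: PhotonStream, interval: float = 50.0, min_delays: int = 20
) -> list[BackgroundEstimate]:
    """Per-interval, per-stream background rates (delay-tail MLE).

    The acquisition is tiled with ``interval``-second windows (a trailing
    remainder shorter than the interval is merged into the last window).
    Streams with fewer than ``min_delays`` tail delays in an interval fall
    back to the whole-acquisition estimate for that stream.
    """
    if len(stream) == 0:
        raise BurstAnalysisError("cannot estimate background of an empty stream")
    times = stream.times
    labels = stream.stream_labels()
    sel = {
        "DD": labels == DD,
        "DA": labels == DA,
        "AA": labels == AA,
        "all": labels != 3,
    }
    global_rates = {k: _tail_mle_rate(times[sel[k]])[0] for k in _BG_KEYS}

    n_int = max(1, int(stream.duration // interval))
    edges = np.arange(n_int + 1) * interval
    edges[-1] = max(stream.duration, times[-1] + stream.clock_period)
    out = []
    for i in range(n_int):
        in_win = (times >= edges[i]) & (times < edges[i + 1])
        rates, nd, thrs = {}, {}, {}
        for k in _BG_KEYS:
            r, n, thr = _tail_mle_rate(times[in_win & sel[k]])
            if n < min_delays:
                logger.warning(
                    "background interval %d stream %s: %d tail delays < %d, "
                    "using whole-acquisition rate", i, k, n, min_delays,
                )
                r = global_rates[k]
            rates[k], nd[k], thrs[k] = r, n, thr
        out.append(BackgroundEstimate(i, float(edges[i]), float(edges[i + 1]), rates, nd, thrs))
    return out


def _bg_lookup(background: list[BackgroundEstimate], t: np.ndarray, key: str) -> np.ndarray:
    starts = np.array([b.t_start for b in background])
    rates = np.array([b.rates[key] for b in background])
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(background) - 1)
    return rates[idx]


# ---------------------------------------------------------------------------
# Burst search
# ---------------------------------------------------------------------------

def _channel_mask(stream: PhotonStream, channel: str) -> tuple[np.ndarray, str]:
    labels = stream.stream_labels()
    if channel == "donor":
        return stream.excitation == DONOR_EXC, "DD"  # bg key: donor-excitation
    if channel == "acceptor":
        return labels == AA, "AA"
    if channel == "all":
        return labels != 3, "all"
    raise BurstAnalysisError(f"unknown excitation channel {channel!r}")


def burst_search(
    stream: PhotonStream,
    m: int = 10,
    F: float = 15.0,
    background: list[BackgroundEstimate] | None = None,
    excitation_channel: str = "all",
) -> list[Burst]:
    """Sliding-window burst search on one photon channel.

    A window of ``m`` consecutive channel photons is "hot" when its span is
    shorter than ``m / (F * bg)`` — i.e. its local rate is at least
    ``F``-fold above the interval's background rate.  Photons covered by
    any hot window are merged into maximal runs; runs of at least ``m``
    photons are returned as bursts (spans indexed on the full stream, with
    counts from all analysis photons inside the span).
    """
    if m < 2 or F <= 1:
        raise BurstAnalysisError("require m >= 2 and F > 1")
    if background is None:
        raise BurstAnalysisError("background estimates are required")
    mask, bgkey = _channel_mask(stream, excitation_channel)
    idx = np.nonzero(mask)[0]
    if idx.size < m:
        return []
    times = stream.times[idx]
    if excitation_channel == "donor":
        bg = _bg_lookup(background, times, "DD") + _bg_lookup(background, times, "DA")
    else:
        bg = _bg_lookup(background, times, bgkey)
    if np.any(bg <= 0):
        raise BurstAnalysisError("zero background rate: F x background undefined")

    span = times[m - 1:] - times[: times.size - m + 1]
    hot_start = span <= (m / (F * bg[: times.size - m + 1]))
    # photon j is hot if any window starting in [j-m+1, j] is hot
    hot = np.zeros(times.size, dtype=bool)
    run = np.flatnonzero(hot_start)
    for off in range(m):  # m is small (default 10)
        hot[run + off] = True

    bursts = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], hot.view(np.int8), [0]))))
    for a, b in zip(edges[::2], edges[1::2]):
        if b - a >= m:
            bursts.append(make_burst(stream, idx[a], idx[b - 1] + 1))
    return bursts


def _intersect_intervals(
    aset: list[tuple[float, float]], bset: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    """All positive-length pairwise intersections of two interval lists."""
    out = []
    for a0, a1 in aset:
        for b0, b1 in bset:
            lo, hi = max(a0, b0), min(a1, b1)
            if hi > lo:
                out.append((lo, hi))
    return sorted(out)


def dual_channel_burst_search(
    stream: PhotonStream,
    m: int = 10,
    F: float = 15.0,
    background: list[BackgroundEstimate] | None = None,
) -> list[Burst]:
    """Bursts detected in both the donor- and acceptor-excitation channels.

    Runs the single-channel search independently on donor-excitation
    photons and on AA photons; only time-overlapping burst pairs survive,
    and each returned burst spans the intersection (counts recomputed).
    Donor-only and acceptor-only species are thereby screened out.
    """
    don = burst_search(stream, m, F, background, "donor")
    acc = burst_search(stream, m, F, background, "acceptor")
    eps = stream.clock_period / 2
    inter = _intersect_intervals(
        [(b.t_start - eps, b.t_stop + eps) for b in don],
        [(b.t_start - eps, b.t_stop + eps) for b in acc],
    )
    times = stream.times
    out = []
    for lo, hi in inter:
        i0 = int(np.searchsorted(times, lo, side="left"))
        i1 = int(np.searchsorted(times, hi, side="right"))
        if i1 > i0:
            out.append(make_burst(stream, i0, i1))
    return out


def filter_bursts(
    bursts: list[Burst], min_donor_exc: int = 15, min_aa: int = 15
) -> list[Burst]:
    """Keep bursts with n_DD + n_DA >= 15 and n_AA >= 15 (both inclusive).

    The first criterion removes acceptor-only species, the second
    donor-only species.  Idempotent; removal counts are logged.
    """
    kept, rm1, rm2 = [], 0, 0
    for b in bursts:
        if b.n_donor_exc < min_donor_exc:
            rm1 += 1
        elif b.n_aa < min_aa:
            rm2 += 1
        else:
            kept.append(b)
    logger.info(
        "filter_bursts: kept %d, removed %d (donor-exc < %d), %d (AA < %d)",
        len(kept), rm1, min_donor_exc, rm2, min_aa,
    )
    return kept


# ---------------------------------------------------------------------------
# E*/S histogramming
# ---------------------------------------------------------------------------

@dataclass
class EsHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    n_selected: int
    modal_e: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def peaks(self, min_fraction: float = 0.02) -> np.ndarray:
        """Bin centers of local maxima holding >= min_fraction of bursts."""
        pk, _ = find_peaks(self.counts, height=min_fraction * max(self.n_selected, 1))
        return self.bin_centers[pk]


def es_histogram(
    bursts: list[Burst],
    s_range: tuple[float, float] = (0.2, 0.8),
    bin_width: float = 0.035,
    e_range: tuple[float, float] = (-0.1, 1.1),
) -> EsHistogram:
    """E* histogram of doubly-labelled bursts (S in the closed s_range)."""
    es = np.array([b.e_star for b in bursts])
    ss = np.array([b.s for b in bursts])
    sel = (ss >= s_range[0]) & (ss <= s_range[1]) & np.isfinite(es)
    if not sel.any():
        raise BurstAnalysisError(
            f"no bursts with S in [{s_range[0]}, {s_range[1]}] — nothing to histogram"
        )
    edges = np.arange(e_range[0], e_range[1] + bin_width / 2, bin_width)
    counts, edges = np.histogram(es[sel], bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EsHistogram(edges, counts, int(sel.sum()), float(centers[np.argmax(counts)]))


def burst_table(bursts: list[Burst]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "burst_id": np.arange(len(bursts)),
            "t_start_s": [b.t_start for b in bursts],
            "t_stop_s": [b.t_stop for b in bursts],
            "n_DD": [b.n_dd for b in bursts],
            "n_DA": [b.n_da for b in bursts],
            "n_AA": [b.n_aa for b in bursts],
            "E_star": [b.e_star for b in bursts],
            "S": [b.s for b in bursts],
        }
    )
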