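"""Burst variance analysis (BVA): within-burst FRET dynamics detection.

If a burst arises from a single static conformation, the number of
acceptor photons among the ``n`` donor-excitation photons of any sub-burst
is binomial, so the standard deviation of sub-burst apparent FRET
efficiencies is bounded by the shot-noise ("static") limit

    sigma_E*(E*, n) = sqrt(E* (1 - E*) / n).

Conformations interconverting on the millisecond (diffusion) timescale or
faster inflate the observed SD above this curve.  Sub-bursts are
consecutive, non-overlapping groups of a fixed number of donor-excitation
photons (default 5); remainder photons are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bursts import Burst
from .photons import PhotonStream, DD, DA

__all__ = ["static_limit", "burst_sd", "binned_sd", "BVAResult"]


def static_limit(e_star: float | np.ndarray, n: int) -> float | np.ndarray:
    """Shot-noise-limited SD of E* for a static species with n photons."""
    e = np.asarray(e_star, dtype=float)
    if np.any((e < 0) | (e > 1)) or n < 1:
        raise ValueError("require 0 <= E* <= 1 and n >= 1")
    out = np.sqrt(e * (1.0 - e) / n)
    return float(out) if np.isscalar(e_star) else out


def burst_sd(
    stream: PhotonStream, burst: Burst, n_sub: int = 5
) -> tuple[float, np.ndarray] | None:
    """Per-burst SD of sub-burst E* values around the burst E*.

    Returns ``(sd, e_sub_values)``; ``None`` when the burst has fewer than
    ``n_sub`` donor-excitation photons (no complete sub-burst).
    """
    labels = stream.stream_labels()[burst.istart:burst.istop]
    donor_exc = labels[(labels == DD) | (labels == DA)]
    m = donor_exc.size // n_sub
    if m == 0:
        return None
    groups = (donor_exc[: m * n_sub] == DA).reshape(m, n_sub)
    e_sub = groups.sum(axis=1) / n_sub
    sd = float(np.sqrt(np.mean((e_sub - burst.e_star) ** 2)))
    return sd, e_sub


@dataclass
class BVAResult:
    """Pooled BVA summary over a burst set."""

    per_burst: pd.DataFrame  # columns: e_star, sd, n_sub_bursts
    per_bin: pd.DataFrame    # columns: bin_center, sd_e, burst_fraction, static_limit, n_sub_bursts
    n_sub: int
    n_skipped: int           # bursts with < n_sub donor-excitation photons


def binned_sd(
    stream: PhotonStream,
    bursts: list[Burst],
    n_sub: int = 5,
    n_bins: int = 20,
    width: float = 0.05,
    min_fraction: float = 0.025,
) -> BVAResult:
    """Pooled sub-burst SD of E* per E* bin.

    Bursts are binned by their E* into ``n_bins`` half-open bins of
    ``width`` starting at 0 (top bin closed); within each bin all sub-burst
    e* values are pooled and their SD computed around the pooled mean.
    Only bins containing at least ``min_fraction`` of all bursts report an
    SD (others carry NaN).
    """
    if not bursts:
        raise ValueError("no bursts for BVA")
    rows, pooled_e, pooled_bin = [], [], []
    n_skipped = 0
    edges = np.arange(n_bins + 1) * width
    for b in bursts:
        res = burst_sd(stream, b, n_sub)
        if res is None:
            n_skipped += 1
            continue
        sd, e_sub = res
        rows.append((b.e_star, sd, e_sub.size))
        k = int(np.digitize(b.e_star, edges)) - 1
        if k == n_bins and b.e_star == edges[-1]:  # top bin closed
            k = n_bins - 1
        if 0 <= k < n_bins:
            pooled_e.append(e_sub)
            pooled_bin.append(np.full(e_sub.size, k))
    per_burst = pd.DataFrame(rows, columns=["e_star", "sd", "n_sub_bursts"])
    n_total = len(per_burst)

    centers = edges[:-1] + width / 2
    sd_e = np.full(n_bins, np.nan)
    frac = np.zeros(n_bins)
    n_subs = np.zeros(n_bins, dtype=int)
    if pooled_e:
        all_e = np.concatenate(pooled_e)
        all_b = np.concatenate(pooled_bin)
        burst_bins = np.clip(
            np.digitize(per_burst["e_star"], edges) - 1, 0, n_bins - 1
        )
        for k in range(n_bins):
            frac[k] = np.sum(burst_bins == k) / max(n_total, 1)
            ek = all_e[all_b == k]
            n_subs[k] = ek.size
            if frac[k] >= min_fraction and ek.size:
                mu = ek.mean()
                sd_e[k] = np.sqrt(np.mean((ek - mu) ** 2))
    per_bin = pd.DataFrame(
        {
            "bin_center": centers,
            "sd_e": sd_e,
            "burst_fraction": frac,
            "static_limit": static_limit(centers, n_sub),
            "n_sub_bursts": n_subs,
        }
    )
    return BVAResult(per_burst, per_bin, n_sub, n_skipped)
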