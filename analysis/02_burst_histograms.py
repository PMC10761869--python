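"""Burst search and E*/S histograms for open- vs closed-shifted ensembles.

Simulates µs-ALEX photon streams for an apo-like (mostly open) chaperone
and for a substrate-loaded ensemble with ~half closed occupancy, runs the
dual-channel burst search and filters, and histograms the apparent FRET
efficiency of doubly-labelled bursts.

Writes results/hist_apo.csv, results/hist_loaded.csv, results/bursts_*.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from getfret.bursts import (
    burst_table,
    dual_channel_burst_search,
    es_histogram,
    estimate_background,
    filter_bursts,
)
from getfret.simulate import simulate_photon_stream, three_state_config

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

DURATION = 150.0  # seconds of acquisition per condition


def run(tag, k_oc, k_co, seed):
    cfg = three_state_config(
        k_oc, k_co, duration=DURATION, e_open=0.15, e_closed=0.85, seed=seed
    )
    stream = simulate_photon_stream(cfg)
    background = estimate_background(stream)
    bursts = filter_bursts(dual_channel_burst_search(stream, background=background))
    burst_table(bursts).to_csv(OUT / f"bursts_{tag}.csv", index=False)
    hist = es_histogram(bursts)
    pd.DataFrame({"bin_center": hist.bin_centers, "count": hist.counts}).to_csv(
        OUT / f"hist_{tag}.csv", index=False
    )
    print(f"{tag}: {len(bursts)} bursts after filters, "
          f"{hist.n_selected} with S in [0.2, 0.8]; "
          f"modal E* = {hist.modal_e:.3f}; peaks at {np.round(hist.peaks(), 3)}")
    return hist


def main() -> None:
    run("apo", 0.221 * 200.0, 200.0, seed=11)     # K_closing ~ 0.22: open-dominated
    run("loaded", 100.0, 100.0, seed=12)          # K_closing = 1: half closed


if __name__ == "__main__":
    main()
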