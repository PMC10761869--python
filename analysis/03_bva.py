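"""Burst variance analysis: static mixtures vs millisecond dynamics.

A static mixture of low- and high-FRET molecules produces sub-burst E*
scatter on the binomial shot-noise curve; molecules interconverting on the
millisecond timescale push the pooled sub-burst SD above it at
intermediate E*.  This driver simulates both cases and writes the per-bin
BVA tables.

Writes results/bva_static.csv and results/bva_dynamic.csv.
"""

from pathlib import Path

import numpy as np

from getfret.bursts import dual_channel_burst_search, estimate_background, filter_bursts
from getfret.bva import binned_sd
from getfret.simulate import (
    SimConfig,
    simulate_photon_stream,
    three_state_config,
    three_state_emission,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def analyze(stream):
    background = estimate_background(stream)
    bursts = filter_bursts(dual_channel_burst_search(stream, background=background))
    return binned_sd(stream, bursts)


def main() -> None:
    static_cfg = SimConfig(
        duration=120.0,
        state_rates=np.zeros((2, 2)),
        state_emission=three_state_emission(0.2, 0.8)[:2],
        seed=21,
    )
    res_s = analyze(simulate_photon_stream(static_cfg))
    res_s.per_bin.to_csv(OUT / "bva_static.csv", index=False)

    dyn_cfg = three_state_config(300.0, 300.0, duration=120.0, seed=22)
    res_d = analyze(simulate_photon_stream(dyn_cfg))
    res_d.per_bin.to_csv(OUT / "bva_dynamic.csv", index=False)

    t_s = res_s.per_bin.dropna(subset=["sd_e"])
    t_d = res_d.per_bin.dropna(subset=["sd_e"])
    dev_s = np.average(t_s.sd_e - t_s.static_limit, weights=t_s.burst_fraction)
    mid = t_d[(t_d.bin_center >= 0.3) & (t_d.bin_center <= 0.7)]
    print(f"Static mixture: weighted mean deviation from the shot-noise "
          f"limit = {dev_s:+.4f} (on the curve).")
    print(f"Dynamic 0.2<->0.8 at 300/s: SD exceeds the static limit by "
          f"{(mid.sd_e - mid.static_limit).min():.3f}-"
          f"{(mid.sd_e - mid.static_limit).max():.3f} at intermediate E* bins.")


if __name__ == "__main__":
    main()
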