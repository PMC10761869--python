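"""Chase-kinetics analysis: trap vs invasion mechanisms of TA release.

Simulates the two mass-action mechanisms by which an excess chase
chaperone can strip a tail-anchored (TA) substrate from a preformed
Sgt2-TA complex, fits the apparent release rate at each chase
concentration, and extracts the intrinsic dissociation rate from the
y-intercept of the k_obs-vs-[chase] line in the combined (two-pathway,
irreversible-capture) model.

Writes results/chase_kobs.csv and results/chase_fits.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from getfret.kinetics import (
    ChaseModelSpec,
    Trace,
    double_exp,
    fit_double_exp,
    fit_single_exp,
    kobs_vs_chase,
    measure_kobs,
    single_exp,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

CAMS = [2.5, 5.0, 10.0, 15.0, 30.0]
CPSRP43 = [14.0, 20.0, 28.0]


def main() -> None:
    rows = []
    for c in CAMS:
        rows.append(("invasion", c, measure_kobs(ChaseModelSpec.invasion(c))))
        rows.append(
            ("combined", c,
             measure_kobs(ChaseModelSpec.combined(c, irreversible_capture=True)))
        )
    for c in CPSRP43:
        rows.append(("spontaneous", c,
                     measure_kobs(ChaseModelSpec.spontaneous(c), window=(0, 60))))
    table = pd.DataFrame(rows, columns=["mechanism", "chase_uM", "k_obs_per_min"])
    table.to_csv(OUT / "chase_kobs.csv", index=False)

    comb = table[table.mechanism == "combined"]
    line = kobs_vs_chase(comb.chase_uM, comb.k_obs_per_min)
    spont = table[table.mechanism == "spontaneous"].k_obs_per_min

    # exponential-fit demonstrations on noisy synthetic traces
    rng = np.random.default_rng(0)
    t = np.linspace(0, 180, 90)
    single = fit_single_exp(
        Trace(t, single_exp(t, 1.0, 0.018) + rng.normal(0, 0.02, t.size))
    )
    t2 = np.linspace(0, 120, 90)
    biphasic = fit_double_exp(
        Trace(t2, double_exp(t2, 0.5, 0.7, 0.5, 0.03) + rng.normal(0, 0.02, t2.size))
    )

    summary = {
        "kobs_line": line,
        "spontaneous_kobs_mean": float(spont.mean()),
        "spontaneous_kobs_spread": float(spont.max() - spont.min()),
        "single_exp_fit_k": single.k,
        "double_exp_fit_k_fast": biphasic.k_fast,
        "double_exp_fit_k_slow": biphasic.k_slow,
    }
    (OUT / "chase_fits.json").write_text(json.dumps(summary, indent=2))

    print("Trap mechanism (cpSRP43-like chase): k_obs "
          f"{[round(k, 4) for k in spont]} per min — concentration independent.")
    print("Invasion mechanism: k_obs rises "
          f"{table[table.mechanism == 'invasion'].k_obs_per_min.round(3).tolist()} "
          f"per min over {CAMS} uM chase.")
    print(f"Combined-model line: slope {line['slope']:.4f} uM^-1 min^-1, "
          f"intercept {line['intercept']:.4f} min^-1 (intrinsic k_off).")
    print(f"Single-exp fit on a noisy dissociation trace: k = {single.k:.4f} min^-1.")
    print(f"Biphasic fit: k_fast = {biphasic.k_fast:.3f}, "
          f"k_slow = {biphasic.k_slow:.4f} min^-1.")


if __name__ == "__main__":
    main()
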