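# getfret

Single-molecule FRET burst analysis and chase kinetics for chaperone
conformational dynamics, driven entirely by synthetic data.

## The scientific problem

Tail-anchored membrane proteins (TAs) reach the endoplasmic reticulum
through a chaperone relay (Hsp70 → Sgt2 → Get3, the GET pathway).  The
dimeric cochaperone Sgt2 interconverts between a wide-open conformation
(its two substrate-binding domains ~130 Å apart, low FRET) and a closed
conformation (domains proximal, high FRET) on the millisecond timescale,
and the open↔closed equilibrium

    K_closing = k_open→closed / k_closed→open

is tuned by the bound substrate and upstream chaperones.  Measuring it
requires diffusion-based µs-ALEX smFRET: freely diffusing, doubly
labelled molecules produce photon *bursts*; alternating donor/acceptor
excitation gives each burst an apparent FRET efficiency
E\* = n_DA/(n_DD+n_DA) and a stoichiometry
S = (n_DD+n_DA)/(n_DD+n_DA+n_AA), which separates doubly labelled
molecules (S ≈ 0.5) from donor-only (S ≈ 1) and acceptor-only (S ≈ 0)
contaminants.  Ensemble chase experiments (adding an excess competitor
chaperone to a preformed Sgt2–TA complex) distinguish whether the chase
merely traps spontaneously released substrate (concentration-independent
kinetics) or actively invades the complex (concentration-dependent).

This package implements the full computational chain for such a study,
for anyone who wants to analyze photon streams or validate such analyses
without access to instrument data:

* **`getfret.simulate`** — generative model: bursts placed by a Poisson
  process, a continuous-time Markov chain over conformational +
  photophysical states inside each burst, alternation-gated Poisson
  photon emission, contaminant species, background, clock quantization.
* **`getfret.photons`** — photon-stream container and I/O (columnar text
  and a Photon-HDF5-style layout), excitation-window assignment.
* **`getfret.bursts`** — background estimation by interphoton-delay tail
  MLE on 50-s intervals, sliding-window burst search (m = 10 photons at
  ≥ 15× background), dual-channel burst search, the n_DD+n_DA ≥ 15 and
  n_AA ≥ 15 filters, E\*/S and histograms.
* **`getfret.bva`** — burst variance analysis: sub-burst E\* standard
  deviation against the shot-noise static limit √(E\*(1−E\*)/n).
* **`getfret.h2mm`** — photon-by-photon hidden Markov modelling with
  arrival-time-dependent transition operators (A^Δt), exact EM via an
  eigendecomposition divided-difference E-step, ICL model selection,
  Viterbi dwells, K_closing and subset-based uncertainties.
* **`getfret.kinetics`** — exponential chase-trace fits and the
  spontaneous-dissociation vs invasion mass-action ODE models, k_obs vs
  chase-concentration analysis, solubilization (hyperbolic) fits.
* **`getfret.pipeline` / `getfret.cli`** — end-to-end orchestration
  (`getfret all --sim-config … --out-dir …`).

Numbered drivers under `analysis/` run the full study on synthetic data
and write tables under `results/`.

## Worked example

Simulate a dynamic three-state condition (open ↔ closed at 100/200 s⁻¹,
i.e. K_closing = 0.5, plus an acceptor-dark blinking state), run the
burst pipeline and the 3-state photon HMM:

```python
from getfret.simulate import three_state_config, simulate_photon_stream
from getfret.bursts import estimate_background, dual_channel_burst_search, filter_bursts
from getfret.h2mm import BurstPhotonData, analyze_bursts

cfg = three_state_config(100.0, 200.0, duration=200.0, seed=3)
stream = simulate_photon_stream(cfg)
background = estimate_background(stream)
bursts = filter_bursts(dual_channel_burst_search(stream, background=background))
data = BurstPhotonData.from_stream(stream, bursts)
res = analyze_bursts(data, k=3, restarts=2, seed=1)
print(res.model.state_e_star().round(3), res.k_closing)
```

With these settings the fit returns state mean E\* of ≈ `[0.21, 0.79, 0.01]`
(open, closed, acceptor-dark) and `K_closing ≈ 0.47` — the generating
equilibrium 0.5 recovered from ~700 bursts of photon data alone.  The
analysis drivers print, for example:

```
$ python analysis/04_h2mm_kclosing.py
K_closing 0.221 -> recovered 0.237 (1163 bursts)
K_closing 0.497 -> recovered 0.446 (1170 bursts)
K_closing 0.722 -> recovered 0.749 (1194 bursts)
K_closing 0.937 -> recovered 0.959 (1169 bursts)
ICL selects K = 3 (ICL by K: {1: 180926, 2: 169509, 3: 168206, 4: 168265})
K_closing = 0.548 +- 0.070 (2 subsets)

$ python analysis/01_chase_kinetics.py
Trap mechanism (cpSRP43-like chase): k_obs [0.017, 0.0164, 0.016] per min — concentration independent.
Invasion mechanism: k_obs rises [0.123, 0.223, 0.403, 0.573, 1.067] per min over [2.5, 5.0, 10.0, 15.0, 30.0] uM chase.
Combined-model line: slope 0.0318 uM^-1 min^-1, intercept 0.0189 min^-1 (intrinsic k_off).
```

The trap mechanism's flat k_obs versus the invasion mechanism's linear
rise is the kinetic signature that distinguishes passive substrate
trapping from active extraction; the y-intercept of the combined-model
line reads off the intrinsic dissociation rate.

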