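# Methods

## Generative model for µs-ALEX photon streams

The simulator produces what a diffusion-based two-colour confocal
measurement with microsecond alternating laser excitation records: a
single sorted list of photon timestamps (integer multiples of the
100 ns clock), each labelled by detector (donor/acceptor) and excitation
window (donor/acceptor).  Its components:

* **Transits.** Single-molecule transits through the confocal spot are a
  homogeneous Poisson process (default 8 s⁻¹) with exponentially
  distributed durations (mean 3 ms).  Emission within a transit is a
  top-hat intensity window: no diffusion-profile shaping.  This loses
  the intensity rise/fall at burst edges but preserves every statistic
  the downstream analyses use (counts, interphoton delays, colour
  sequences).
* **States.** While in the spot, a doubly labelled molecule evolves as a
  continuous-time Markov chain over conformational and photophysical
  states (exact Gillespie realization; initial state drawn from the
  stationary distribution — molecules equilibrate between transits).
  The standard configuration has three states: open (E\* = 0.2),
  closed (E\* = 0.8), and an acceptor-dark blinking state reached at
  50 s⁻¹ and left at 500 s⁻¹, which emits all donor-excitation photons
  into DD and no AA (E\* ≈ 0, S ≈ 1).
* **Emission.** Per state, photons arrive as Poisson processes in the
  three streams (DD, DA, AA), gated by the laser alternation (100 µs
  period, 50% donor duty): DD/DA only during donor windows, AA only
  during acceptor windows.  Default nominal rates put the delivered
  in-burst total at ~40 kHz.  Donor-only contaminants emit only DD,
  acceptor-only contaminants only AA; the default species mixture is
  70% doubly labelled, 18% donor-only, 12% acceptor-only.
* **Background** is homogeneous Poisson per stream (default 300 s⁻¹
  each).  All arrival times are floor-quantized to the clock, merged and
  sorted with same-tick ties broken in the fixed order DD < DA < AA;
  same-tick same-stream pile-up keeps one photon and logs the drop.

Two regime choices deserve justification because they differ from naive
"bright is better" settings:

1. **~1 photon per excitation half-window.**  At several photons per
   window, the globally best HMM explanation of the colour sequence is
   one that *tracks the laser alternation* as a fast (~2×10⁴ s⁻¹)
   pseudo-dynamic process — its likelihood exceeds the generating
   model's because the AA stream becomes perfectly predictable.  At
   ~40 kHz delivered rate against the 10 kHz alternation, interphoton
   times are comparable to the window length, window-tracking buys
   nothing, and the conformational solution dominates.  This is also
   the regime real µs-ALEX instruments operate in.
2. **Low occupancy (8 transits/s × 3 ms ≈ 2.4%).**  At high transit
   rates two molecules regularly occupy the spot together; coincident
   donor-only + acceptor-only transits pass the dual-channel search and
   masquerade as fast FRET dynamics, inflating fitted rates by tens of
   percent.  Low occupancy is precisely why single-molecule experiments
   are run at ~100 pM.

What the generator does **not** emulate: diffusion through a 3-D
Gaussian excitation volume (burst-size/brightness correlations), detector
dead time and afterpulsing, spectral crosstalk and γ-factor asymmetries,
triplet shelving of the donor.  Passing recovery tests on these
synthetics therefore establishes the *estimators* (search, BVA, HMM,
fits) are correct and unbiased under the stated model, not that any
particular instrument is free of systematic error.

## Burst analysis

Background rates are estimated per 50-s interval and per stream by a
censored-exponential MLE on the interphoton-delay tail: delays above
4× the median delay are treated as pure background and the rate is
1/(mean tail delay − threshold); intervals with fewer than 20 tail
delays fall back to the whole-acquisition estimate.  The burst search
slides an m = 10-photon window over one excitation channel and marks
photons covered by any window whose span is shorter than m/(F·bg) with
F = 15; maximal runs of ≥ m marked photons are bursts.  The dual-channel
search intersects, in time, bursts found independently in the
donor-excitation and acceptor-excitation channels (counts recomputed on
the intersection; the combination rule is a design choice — intersection
is the conservative standard).  Filters keep bursts with
n_DD + n_DA ≥ 15 **and** n_AA ≥ 15 (both inclusive).  E\* and S are
uncorrected (no γ/leakage/direct-excitation corrections — the analyses
track *changes* in E\*, not absolute distances).  Histograms select
S ∈ [0.2, 0.8] (closed interval) and bin E\* at width 0.035 over
[−0.1, 1.1].

## Burst variance analysis

Sub-bursts are consecutive, non-overlapping groups of n = 5
donor-excitation photons (remainder dropped).  The per-bin pooled SD of
sub-burst e\* values is compared to the binomial static limit
σ = √(E\*(1−E\*)/5); bursts are binned by E\* into 20 half-open bins of
width 0.05 (top bin closed) and only bins holding ≥ 2.5% of bursts
report an SD.  Pooling (rather than averaging per-burst SDs) weights
every sub-burst equally.

## Photon-by-photon HMM

The hidden state advances at every clock tick with per-tick transition
matrix A; between photons separated by Δt ticks the transition operator
is A^Δt, computed per unique Δt from the eigendecomposition
A = VΛV⁻¹.  Emission is a per-state categorical over photon colour
(DD, DA, AA); including the AA stream is what separates acceptor-dark
photophysics (S ≈ 1) from conformational states (S ≈ 0.5).

**Fitting** is exact EM.  The E-step needs the expected number of
tick-level i→j transitions inside each interphoton interval; summing the
posterior over the unobserved intermediate ticks gives, in the
eigenbasis, divided differences
Σ_{d=0}^{Δt−1} λ_k^d λ_l^{Δt−1−d} = (λ_k^Δt − λ_l^Δt)/(λ_k − λ_l)
(limit d·λ^{d−1} for coincident eigenvalues), so the cost per photon is
O(K⁴) regardless of Δt.  With exact expected counts the M-step is closed
form and the log-likelihood is non-decreasing — asserted at every
iteration.  Convergence: per-photon ΔLL < 1e−7 (default), cap 1000
iterations.  Initialization places conformational states at quantiles of
the burst E\* distribution plus one photophysics-like state
(E\* ≈ 0.05, S ≈ 0.95) when K ≥ 3; five restarts by default (the first
deterministic, the rest perturbed), best likelihood kept.  Degenerate
(defective) transition matrices are handled by a tiny jitter before
eigendecomposition.

**Rate cap.**  Fitted per-tick transition probabilities are constrained
below max_rate·clock (default max_rate = 2000 s⁻¹) by a KKT
water-filling M-step (pinned entries at the bound, remaining mass
redistributed proportionally), which still maximizes the constrained
M-step objective and so preserves EM monotonicity.  Rationale: switching
at or above the 10 kHz alternation frequency is not identifiable in ALEX
data — an unconstrained fit can lock onto the deterministic colour
gating itself.  The cap sits an order of magnitude above genuine
millisecond dynamics.

**Model selection** minimizes the integrated complete likelihood,
ICL = −[CLL(Viterbi path) − (d/2)·ln N_photons] with
d = (K−1) + K(K−1) + 2K free parameters — a BIC-type penalty on the
complete-data likelihood (the exact penalty form is a design choice).
Candidate models containing any transition rate below 1 s⁻¹ are flagged
physically unreasonable (undetectable within millisecond bursts) and
excluded from selection unless every model is flagged.

**Rates and K_closing.**  Per-second rate constants come from
Q = log(A)/clock_period projected to the nearest valid generator
(negative off-diagonals clipped, diagonal rebalanced); for per-tick
probabilities ≪ 1 this equals A_ij/clock to first order.  The
photophysical state is identified as the state with the highest S; of
the remaining conformational states the lower-E\* state is open, the
higher closed, making K_closing = k_open→closed/k_closed→open invariant
to label permutations.  Uncertainties: bursts are split in acquisition
order into near-equal subsets (~1850 by default, at least two), the
3-state model refitted per subset, σ(k) taken across subsets, and
σ(K)/K = √((σ(k_oc)/k_oc)² + (σ(k_co)/k_co)²).

## Chase kinetics

Time is in minutes, concentrations in µM.  Traces are normalized
fluorescence F (0 at t = 0, 1 at completion) and fitted by
A(1−e^{−kt}) or the biphasic sum with k_fast > k_slow enforced by
post-fit ordering; a sign-runs test on residuals flags systematic
misfit.  The **spontaneous/trap** model is
Sgt2–TA ⇌ Sgt2 + TA (k₁ = 0.015 min⁻¹, k₋₁ = 1 µM⁻¹min⁻¹) with
TA + CaM ⇌ CaM–TA (k₂ = 10 µM⁻¹min⁻¹, k₋₂ = 10 min⁻¹); readout
1 − [Sgt2–TA]/([Sgt2–TA]+[CaM–TA]+[TA]).  The **invasion** model is
Sgt2–TA + CaM ⇌ Sgt2–TA·CaM ⇌ Sgt2 + CaM–TA
(k₁ = 0.035 µM⁻¹min⁻¹, k₋₁ = 1 min⁻¹, k₂ = 10 min⁻¹,
k₋₂ = 20 µM⁻¹min⁻¹); readout
1 − [Sgt2–TA]/([Sgt2–TA]+[Sgt2–TA·CaM]+[CaM–TA]).  Integration uses
LSODA at rtol 1e−9 with total-TA conservation checked to 1e−7 relative
and negative concentrations rejected.  Apparent rates (k_obs) are
single-exponential fits over a fixed window (0–10 min default;
0–60 min for the slow trap mechanism), after renormalizing to the
window endpoint the way measured traces are normalized to their plateau.

A **combined** variant carries both pathways simultaneously; with
`irreversible_capture=True` the reverse of both capture steps is zeroed,
the large-chase-excess regime in which
k_obs = k_off + k_invade·[chase], so the ordinary-least-squares
y-intercept of k_obs versus [chase] reads off the intrinsic
dissociation rate.  With the equilibrium-matched reverse constants
active, approach-to-equilibrium backflow adds a concentration-dependent
term at low [chase] and the intercept overestimates k_off — which is why
the intercept analysis uses the irreversible regime.

The solubilization assay is fitted as the hyperbola
S_obsd = S_max·[C]/(K_soluble + [C]); a warning is issued when the data
do not reach 2×K_soluble (unsaturated, wide confidence interval).

## Problem sizes and benchmark conditions

Recovery benchmarks use ≥ 2000 filtered bursts per condition
(620 s simulated acquisition at the defaults), which puts the K_closing
estimator within a few percent of the generating ratio; the generating
conditions fix k_closed→open = 200 s⁻¹ and set k_open→closed from the
target equilibrium, since only the equilibrium constants (not the
individual rate constants) are specified for the measured conditions.
ICL selection replicates use ~500 bursts each (130 s), enough for the
three-state structure to dominate both the 2-state merge and 4/5-state
overfits.  Exhaustive-enumeration oracles check the forward likelihood
and Viterbi decoding to 1e−10 relative on instances of up to 10 photons
and 3 states, where K^n path sums are tractable.

## Known limitations

* Background photons inside bursts are not modelled by the HMM; at the
  default signal-to-background (~45:1 in-burst) they bias fitted rate
  constants upward by ~5–15% while leaving their ratio (K_closing)
  accurate to a few percent.
* The per-tick transition matrix treats photon colour as conditionally
  independent of the alternation phase given the state; the rate cap is
  the guard that keeps this approximation from being exploited.
* Dwell durations from Viterbi paths are photon-bounded (a dwell's
  boundary is known only to the nearest photon).
* The chase ODE models inherit the printed constants' internal tension
  between the stated overall exchange equilibrium and the individual
  rate values; conclusions drawn from them here are qualitative
  (concentration dependence) or use the irreversible-capture regime.
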