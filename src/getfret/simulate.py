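"""Synthetic µs-ALEX photon streams and ensemble chase traces.

The generator emulates the statistical structure a diffusion-based smFRET
experiment produces, so every downstream stage (burst search, E*/S, BVA,
photon-by-photon HMM, chase-kinetics fitting) can be exercised and
validated without experimental data:

* diffusing doubly-labelled molecules produce photon bursts over a steady
  background (bursts modelled as top-hat intensity windows placed by a
  Poisson process, with exponentially distributed transit durations);
* while in the confocal spot a molecule interconverts among conformational
  and photophysical states as a continuous-time Markov chain (millisecond
  open/closed dynamics, acceptor blinking with E* ~ 0 and S ~ 1);
* photons are emitted as Poisson processes whose per-stream rates depend on
  the current state, gated by the laser alternation (DD/DA only during
  donor-excitation windows, AA only during acceptor-excitation windows);
* donor-only and acceptor-only contaminant species emit into a single
  stream; per-stream background is homogeneous over the acquisition;
* all arrival times are quantized to the timestamp clock, merged and
  sorted, with same-tick ties broken by stream order DD < DA < AA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .photons import (
    AlternationScheme,
    PhotonStream,
    DD,
    DA,
    AA,
    DONOR_DET,
    ACCEPTOR_DET,
    DONOR_EXC,
    ACCEPTOR_EXC,
)

# species codes
DOUBLY_LABELLED, DONOR_ONLY, ACCEPTOR_ONLY = 0, 1, 2


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Full generative specification for a synthetic photon stream.

    ``state_rates`` is the square matrix of transition rate constants
    (s^-1) among conformational + photophysical states; off-diagonal entry
    (i, j) is the i -> j rate and the diagonal is ignored.  ``state_emission``
    holds, per state, the mean detected photon rate (s^-1) into streams
    (DD, DA, AA) while the molecule sits in the confocal spot and the
    corresponding laser is on.
    """

    duration: float = 60.0
    alternation_period: float = 100e-6
    donor_fraction_of_period: float = 0.5
    clock_period: float = 100e-9
    state_rates: np.ndarray = field(default_factory=lambda: np.zeros((1, 1)))
    state_emission: np.ndarray = field(
        default_factory=lambda: np.array([[32e3, 8e3, 40e3]])
    )
    burst_rate: float = 8.0
    burst_duration_mean: float = 3e-3
    background_rates: tuple[float, float, float] = (300.0, 300.0, 300.0)
    species_fractions: tuple[float, float, float] = (1.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.state_rates = np.asarray(self.state_rates, dtype=float)
        self.state_emission = np.asarray(self.state_emission, dtype=float)
        validate_rate_matrix(self.state_rates)
        if self.state_emission.shape != (self.state_rates.shape[0], 3):
            raise SimulationError("state_emission must be (n_states, 3)")
        if (self.state_emission < 0).any() or min(self.background_rates) < 0:
            raise SimulationError("emission/background rates must be >= 0")
        if self.burst_rate < 0 or self.burst_duration_mean <= 0 or self.duration <= 0:
            raise SimulationError("invalid burst/duration parameters")
        if not 0 < self.donor_fraction_of_period < 1:
            raise SimulationError("donor_fraction_of_period must be in (0, 1)")
        if self.clock_period > self.alternation_period / 100:
            raise SimulationError("clock_period must be <= alternation_period / 100")
        if abs(sum(self.species_fractions) - 1.0) > 1e-12:
            raise SimulationError("species_fractions must sum to 1")
        if min(self.species_fractions) < 0:
            raise SimulationError("species_fractions must be >= 0")

    @property
    def alternation(self) -> AlternationScheme:
        return AlternationScheme.square(
            self.alternation_period, self.donor_fraction_of_period
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["state_rates"] = self.state_rates.tolist()
        d["state_emission"] = self.state_emission.tolist()
        d["background_rates"] = list(self.background_rates)
        d["species_fractions"] = list(self.species_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["background_rates"] = tuple(d["background_rates"])
        d["species_fractions"] = tuple(d["species_fractions"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class StatePath:
    """A continuous-time Markov chain realization: dwell boundaries + states.

    ``boundaries`` has one more element than ``states``; dwell ``i`` spans
    ``[boundaries[i], boundaries[i+1])``.
    """

    boundaries: np.ndarray
    states: np.ndarray

    def state_at(self, t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.boundaries, t, side="right") - 1
        return self.states[np.clip(idx, 0, len(self.states) - 1)]

    def dwell_durations(self) -> np.ndarray:
        return np.diff(self.boundaries)


def validate_rate_matrix(rates: np.ndarray) -> None:
    rates = np.asarray(rates, dtype=float)
    if rates.ndim != 2 or rates.shape[0] != rates.shape[1]:
        raise SimulationError("rate matrix must be square")
    off = rates.copy()
    np.fill_diagonal(off, 0.0)
    if (off < 0).any():
        raise SimulationError("off-diagonal rates must be non-negative")


def stationary_distribution(rates: np.ndarray) -> np.ndarray:
    """Stationary distribution of the CTMC with the given rate matrix."""
    rates = np.asarray(rates, dtype=float)
    k = rates.shape[0]
    if k == 1:
        return np.ones(1)
    q = rates.copy()
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    # solve pi Q = 0 with sum(pi) = 1
    a = np.vstack([q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def simulate_state_path(
    rates: np.ndarray,
    duration: float,
    seed: int | np.random.Generator = 0,
    initial_state: int | None = None,
) -> StatePath:
    """Exact (Gillespie) realization of the conformational CTMC.

    The initial state is drawn from the stationary distribution of the rate
    matrix unless given — molecules are assumed to equilibrate between
    transits through the confocal spot.
    """
    validate_rate_matrix(rates)
    if duration <= 0:
        raise SimulationError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = np.asarray(rates, dtype=float)
    k = rates.shape[0]
    off = rates.copy()
    np.fill_diagonal(off, 0.0)
    exit_rates = off.sum(axis=1)

    if initial_state is None:
        state = int(rng.choice(k, p=stationary_distribution(rates)))
    else:
        state = int(initial_state)
    t = 0.0
    boundaries = [0.0]
    states = [state]
    while True:
        lam = exit_rates[state]
        if lam <= 0:
            break
        t += rng.exponential(1.0 / lam)
        if t >= duration:
            break
        state = int(rng.choice(k, p=off[state] / lam))
        boundaries.append(t)
        states.append(state)
    boundaries.append(duration)
    return StatePath(np.asarray(boundaries), np.asarray(states, dtype=np.int64))


def _poisson_times(rng: np.random.Generator, rate: float, t0: float, t1: float) -> np.ndarray:
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, n))


def _window_filter(times: np.ndarray, cfg: SimConfig, excitation: int) -> np.ndarray:
    """Keep photons whose alternation phase matches the excitation window."""
    phase = np.mod(times, cfg.alternation_period)
    split = cfg.alternation_period * cfg.donor_fraction_of_period
    if excitation == DONOR_EXC:
        return times[phase < split]
    return times[phase >= split]


def simulate_photon_stream(config: SimConfig) -> PhotonStream:
    """Generate a full synthetic photon stream per the config.

    Emission inside bursts is gated by the excitation alternation: the
    per-state DD/DA rates apply only during donor-excitation windows, the
    AA rate only during acceptor-excitation windows, so the delivered mean
    per-stream rate is the nominal rate times the window duty fraction.
    Background is delivered at the stated per-stream rate over the whole
    acquisition (window-gated with a duty-compensated intensity).
    """
    rng = np.random.default_rng(config.seed)
    cfg = config
    times_all: list[np.ndarray] = []
    streams_all: list[np.ndarray] = []

    # --- burst placement ---
    n_bursts = rng.poisson(cfg.burst_rate * cfg.duration)
    starts = np.sort(rng.uniform(0.0, cfg.duration, n_bursts))
    durations = rng.exponential(cfg.burst_duration_mean, n_bursts)
    species = rng.choice(3, size=n_bursts, p=np.asarray(cfg.species_fractions))

    truth_states: list[StatePath | None] = []
    don_rate_total = cfg.state_emission[:, DD] + cfg.state_emission[:, DA]
    for b in range(n_bursts):
        t0 = starts[b]
        t1 = min(t0 + durations[b], cfg.duration)
        if t1 <= t0:
            truth_states.append(None)
            continue
        sp = species[b]
        if sp == DOUBLY_LABELLED:
            path = simulate_state_path(cfg.state_rates, t1 - t0, rng)
            truth_states.append(path)
            for i, (d0, d1) in enumerate(zip(path.boundaries[:-1], path.boundaries[1:])):
                st = path.states[i]
                for stream in (DD, DA, AA):
                    rate = cfg.state_emission[st, stream]
                    tt = _poisson_times(rng, rate, t0 + d0, t0 + d1)
                    exc = DONOR_EXC if stream in (DD, DA) else ACCEPTOR_EXC
                    tt = _window_filter(tt, cfg, exc)
                    if tt.size:
                        times_all.append(tt)
                        streams_all.append(np.full(tt.size, stream, np.int8))
        elif sp == DONOR_ONLY:
            truth_states.append(None)
            # without an acceptor every donor-excitation photon is DD
            tt = _window_filter(_poisson_times(rng, don_rate_total[0], t0, t1), cfg, DONOR_EXC)
            if tt.size:
                times_all.append(tt)
                streams_all.append(np.full(tt.size, DD, np.int8))
        else:  # acceptor only
            truth_states.append(None)
            tt = _window_filter(
                _poisson_times(rng, cfg.state_emission[0, AA], t0, t1), cfg, ACCEPTOR_EXC
            )
            if tt.size:
                times_all.append(tt)
                streams_all.append(np.full(tt.size, AA, np.int8))

    # --- background: delivered per-stream rate over the full acquisition ---
    f_don = cfg.donor_fraction_of_period
    duty = {DD: f_don, DA: f_don, AA: 1.0 - f_don}
    for stream in (DD, DA, AA):
        bg = cfg.background_rates[stream]
        if bg <= 0:
            continue
        exc = DONOR_EXC if stream in (DD, DA) else ACCEPTOR_EXC
        tt = _window_filter(
            _poisson_times(rng, bg / duty[stream], 0.0, cfg.duration), cfg, exc
        )
        if tt.size:
            times_all.append(tt)
            streams_all.append(np.full(tt.size, stream, np.int8))

    if times_all:
        times = np.concatenate(times_all)
        streams = np.concatenate(streams_all)
    else:
        times = np.empty(0)
        streams = np.empty(0, np.int8)

    # --- quantize, sort (ties by stream order), drop same-tick pile-up ---
    ticks = np.floor(times / cfg.clock_period).astype(np.int64)
    order = np.lexsort((streams, ticks))
    ticks, streams = ticks[order], streams[order]
    if ticks.size:
        dup = np.zeros(ticks.size, bool)
        dup[1:] = (np.diff(ticks) == 0) & (np.diff(streams) == 0)
        n_dropped = int(dup.sum())
        ticks, streams = ticks[~dup], streams[~dup]
    else:
        n_dropped = 0

    detector = np.where(streams == DD, DONOR_DET, ACCEPTOR_DET).astype(np.int8)
    excitation = np.where(streams == AA, ACCEPTOR_EXC, DONOR_EXC).astype(np.int8)

    meta = {
        "seed": cfg.seed,
        "sim_config": cfg.to_dict(),
        "pileup_dropped": n_dropped,
        "alternation": {
            "period": cfg.alternation_period,
            "donor_window": [0.0, cfg.alternation_period * f_don],
            "acceptor_window": [cfg.alternation_period * f_don, cfg.alternation_period],
        },
        "truth": {
            "burst_starts": starts.tolist(),
            "burst_durations": durations.tolist(),
            "species": species.tolist(),
        },
    }
    return PhotonStream(ticks, detector, excitation, cfg.clock_period, cfg.duration, meta)


# ---------------------------------------------------------------------------
# Standard three-state configuration (open / closed / acceptor-dark)
# ---------------------------------------------------------------------------

def three_state_rates(
    k_open_to_closed: float,
    k_closed_to_open: float,
    k_to_dark: float = 50.0,
    k_from_dark: float = 500.0,
) -> np.ndarray:
    """Rate matrix for states (open, closed, dark).

    Acceptor blinking takes either conformational state to a dark state at
    ``k_to_dark``; recovery at ``k_from_dark`` returns to open/closed with
    equal probability (the chain is memoryless).
    """
    r = np.zeros((3, 3))
    r[0, 1] = k_open_to_closed
    r[1, 0] = k_closed_to_open
    r[0, 2] = r[1, 2] = k_to_dark
    r[2, 0] = r[2, 1] = k_from_dark / 2.0
    return r


def three_state_emission(
    e_open: float = 0.2,
    e_closed: float = 0.8,
    donor_rate: float = 40e3,
    acceptor_rate: float = 40e3,
) -> np.ndarray:
    """Per-state (DD, DA, AA) emission rates for (open, closed, dark).

    ``e_open``/``e_closed`` are the apparent FRET efficiencies of the two
    conformational states (DA fraction of donor-excitation photons).  The
    dark state routes all donor-excitation photons to DD and emits no AA.
    """
    rows = []
    for e in (e_open, e_closed):
        rows.append([donor_rate * (1 - e), donor_rate * e, acceptor_rate])
    rows.append([donor_rate, 0.0, 0.0])
    return np.asarray(rows)


def three_state_config(
    k_open_to_closed: float,
    k_closed_to_open: float,
    duration: float = 60.0,
    e_open: float = 0.2,
    e_closed: float = 0.8,
    species_fractions: tuple[float, float, float] = (0.70, 0.18, 0.12),
    seed: int = 0,
    **kwargs,
) -> SimConfig:
    """The standard study condition: two FRET states + acceptor blinking."""
    return SimConfig(
        duration=duration,
        state_rates=three_state_rates(k_open_to_closed, k_closed_to_open),
        state_emission=three_state_emission(e_open, e_closed),
        species_fractions=species_fractions,
        seed=seed,
        **kwargs,
    )


def simulate_chase_trace(model, times, noise_sd: float = 0.0, seed: int = 0):
    """Ensemble chase trace: ODE integration + i.i.d. Gaussian noise.

    ``model`` is a :class:`getfret.kinetics.ChaseModelSpec`; returns a
    :class:`getfret.kinetics.Trace` with noisy normalized fluorescence.
    """
    from .kinetics import simulate_release

    trace = simulate_release(model, times)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace.fluorescence = trace.fluorescence + rng.normal(0, noise_sd, trace.fluorescence.size)
    return trace
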