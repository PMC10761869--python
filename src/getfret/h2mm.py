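"""Multi-parameter photon-by-photon hidden Markov modelling (mpH²MM).

Fits K-state HMMs directly to the photon record of each burst: the hidden
conformational/photophysical state evolves at every clock tick with
per-tick transition matrix ``A``, and each photon emits a colour in
(DD, DA, AA) according to the current state's emission distribution ``B``.
Because the acceptor-excitation stream is part of the observation, states
arising from dye photophysics (acceptor blinking: E* ~ 0, S ~ 1) separate
from genuine FRET states (S ~ 0.5).

Model selection uses the Integrated Complete Likelihood (ICL, lower is
better); dwell sequences come from Viterbi decoding; and the open/closed
equilibrium constant is

    K_closing = k_open->closed / k_closed->open

with rate constants recovered from the per-tick transition matrix via the
matrix logarithm.  Uncertainties follow from refitting sequential burst
subsets and propagating the rate SDs through the ratio.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import logm

from ._h2mm_core import em_pass, forward_ll, viterbi_path
from .bursts import Burst
from .photons import PhotonStream, DD, DA, AA

logger = logging.getLogger(__name__)

_COLOURS = 3


class H2MMError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Photon data container
# ---------------------------------------------------------------------------

@dataclass
class BurstPhotonData:
    """Flattened photon colour/interval sequences for a burst set.

    ``colors`` holds the stream code (DD=0, DA=1, AA=2) of every analysis
    photon; ``deltas`` the tick separation from the previous photon of the
    same burst (>= 1; 0 for the first photon of each burst); ``ptr`` the
    burst offsets into the flat arrays.
    """

    colors: np.ndarray
    deltas: np.ndarray
    ptr: np.ndarray
    clock_period: float
    unique_deltas: np.ndarray = field(init=False)
    didx: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.colors = np.ascontiguousarray(self.colors, dtype=np.int64)
        self.deltas = np.ascontiguousarray(self.deltas, dtype=np.int64)
        self.ptr = np.ascontiguousarray(self.ptr, dtype=np.int64)
        interior = np.ones(self.colors.size, dtype=bool)
        interior[self.ptr[:-1][self.ptr[:-1] < self.colors.size]] = False
        vals = self.deltas[interior] if interior.any() else np.array([1], np.int64)
        self.unique_deltas, inv = np.unique(
            np.concatenate(([1], vals)), return_inverse=True
        )
        didx = np.zeros(self.colors.size, dtype=np.int64)
        didx[interior] = inv[1:]
        self.didx = didx

    @property
    def n_bursts(self) -> int:
        return int(self.ptr.size - 1)

    @property
    def n_photons(self) -> int:
        return int(self.colors.size)

    @classmethod
    def from_stream(
        cls, stream: PhotonStream, bursts: list[Burst]
    ) -> "BurstPhotonData":
        labels = stream.stream_labels()
        colors, deltas, ptr = [], [], [0]
        for b in bursts:
            lab = labels[b.istart:b.istop]
            ts = stream.timestamps[b.istart:b.istop]
            keep = lab != 3  # analysis photons only
            lab, ts = lab[keep], ts[keep]
            if lab.size == 0:
                continue
            d = np.empty(lab.size, np.int64)
            d[0] = 0
            d[1:] = np.maximum(np.diff(ts), 1)  # same-tick photons -> 1 tick
            colors.append(lab.astype(np.int64))
            deltas.append(d)
            ptr.append(ptr[-1] + lab.size)
        if not colors:
            raise H2MMError("no analysis photons in any burst")
        return cls(
            np.concatenate(colors), np.concatenate(deltas),
            np.asarray(ptr), stream.clock_period,
        )

    @classmethod
    def from_sequences(cls, seqs, clock_period: float) -> "BurstPhotonData":
        """Build from explicit (colors, deltas) pairs — handy for testing."""
        colors = np.concatenate([np.asarray(c, np.int64) for c, _ in seqs])
        deltas = np.concatenate([np.asarray(d, np.int64) for _, d in seqs])
        ptr = np.cumsum([0] + [len(c) for c, _ in seqs])
        return cls(colors, deltas, ptr, clock_period)

    def subset(self, burst_slice: slice) -> "BurstPhotonData":
        lo, hi, _ = burst_slice.indices(self.n_bursts)
        a, b = self.ptr[lo], self.ptr[hi]
        ptr = self.ptr[lo:hi + 1] - a
        return BurstPhotonData(
            self.colors[a:b], self.deltas[a:b], ptr, self.clock_period
        )

    def burst_es(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-burst (E*, S) from the photon colours."""
        nb = self.n_bursts
        e = np.full(nb, np.nan)
        s = np.full(nb, np.nan)
        for b in range(nb):
            c = self.colors[self.ptr[b]:self.ptr[b + 1]]
            ndd, nda, naa = np.sum(c == DD), np.sum(c == DA), np.sum(c == AA)
            if ndd + nda > 0:
                e[b] = nda / (ndd + nda)
            if ndd + nda + naa > 0:
                s[b] = (ndd + nda) / (ndd + nda + naa)
        return e, s


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class H2MMModel:
    """K-state photon-colour HMM with per-tick transition matrix.

    ``trans`` is the per-tick transition probability matrix A (row
    stochastic); ``obs`` the (K, 3) emission matrix over (DD, DA, AA);
    ``pi`` the burst-initial state distribution.
    """

    pi: np.ndarray
    trans: np.ndarray
    obs: np.ndarray
    clock_period: float

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, float)
        self.trans = np.asarray(self.trans, float)
        self.obs = np.asarray(self.obs, float)
        k = self.pi.size
        if self.trans.shape != (k, k) or self.obs.shape[0] != k:
            raise H2MMError("inconsistent model dimensions")
        for name, arr in (("pi", self.pi[None, :]), ("trans", self.trans), ("obs", self.obs)):
            if (arr < -1e-12).any():
                raise H2MMError(f"{name} has negative entries")
            if np.abs(arr.sum(axis=1) - 1.0).max() > 1e-8:
                raise H2MMError(f"rows of {name} must sum to 1")

    @property
    def n_states(self) -> int:
        return int(self.pi.size)

    def state_e_star(self) -> np.ndarray:
        d = self.obs[:, DD] + self.obs[:, DA]
        return np.where(d > 0, self.obs[:, DA] / np.where(d > 0, d, 1), np.nan)

    def state_s(self) -> np.ndarray:
        tot = self.obs.sum(axis=1)
        return (self.obs[:, DD] + self.obs[:, DA]) / np.where(tot > 0, tot, 1)

    def rate_matrix(self) -> np.ndarray:
        """Rate constants (s^-1) via the matrix log of the per-tick A.

        Q = logm(A) / clock_period, projected to the nearest valid
        generator: negative off-diagonals clipped to zero and the diagonal
        rebalanced.  For the small per-tick probabilities typical here
        this equals A_ij / clock_period to first order.
        """
        q = logm(self.trans).real / self.clock_period
        np.fill_diagonal(q, 0.0)
        q = np.clip(q, 0.0, None)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "trans_per_tick": self.trans.tolist(),
            "obs": self.obs.tolist(),
            "clock_period": self.clock_period,
            "rates_per_s": self.rate_matrix().tolist(),
            "state_e_star": self.state_e_star().tolist(),
            "state_s": self.state_s().tolist(),
        }


# ---------------------------------------------------------------------------
# Transition-operator tables (eigendecomposition, shared across kernels)
# ---------------------------------------------------------------------------

def _eig(a: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    jitter = 0.0
    rng = np.random.default_rng(12345)
    for _ in range(6):
        m = a if jitter == 0 else a + rng.uniform(-jitter, jitter, a.shape)
        w, v = np.linalg.eig(m)
        if np.linalg.cond(v) < 1e10:
            return w, v, np.linalg.inv(v)
        jitter = 1e-12 if jitter == 0 else jitter * 100
    return w, v, np.linalg.pinv(v)  # defective: best-effort


def operator_tables(
    a: np.ndarray, unique_deltas: np.ndarray, with_counts: bool = True
):
    """Per-unique-interval tables P[u]=A**dt_u and the count tensor H[u]."""
    w, v, vinv = _eig(a)
    ud = unique_deltas.astype(np.float64)
    wp = np.power(w[None, :], ud[:, None])  # (U, K)
    p = np.einsum("ik,uk,kj->uij", v, wp, vinv).real
    p = np.clip(p, 0.0, None)
    rows = p.sum(axis=2, keepdims=True)
    p /= np.where(rows > 0, rows, 1.0)
    if not with_counts:
        return np.ascontiguousarray(p), None
    den = w[:, None] - w[None, :]
    close = np.abs(den) < 1e-9
    den_safe = np.where(close, 1.0, den)
    g = (wp[:, :, None] - wp[:, None, :]) / den_safe[None, :, :]
    # repeated eigenvalue limit: d * lam^(d-1)
    dw = ud[:, None] * np.power(w[None, :], np.maximum(ud - 1.0, 0.0)[:, None])
    g = np.where(close[None, :, :], dw[:, :, None], g)
    x = np.einsum("pk,ki,ukl->upil", v, vinv, g)
    h = np.einsum("upil,jl,lq->upijq", x, v, vinv).real
    h *= a[None, None, :, :, None]
    return np.ascontiguousarray(p), np.ascontiguousarray(h)


# ---------------------------------------------------------------------------
# Likelihood / fitting
# ---------------------------------------------------------------------------

def loglikelihood(model: H2MMModel, data: BurstPhotonData) -> float:
    """Exact forward log-likelihood with A**dt interphoton operators."""
    p, _ = operator_tables(model.trans, data.unique_deltas, with_counts=False)
    return float(
        forward_ll(data.colors, data.didx, data.ptr, p, model.obs, model.pi)
    )


def _init_model(
    data: BurstPhotonData, k: int, rng: np.random.Generator, perturb: bool
) -> H2MMModel:
    """States at E* quantiles; last state is photophysics-like when K >= 3."""
    e_burst, s_burst = data.burst_es()
    e_burst = e_burst[np.isfinite(e_burst)]
    s_med = float(np.nanmedian(s_burst)) if np.isfinite(s_burst).any() else 0.5
    s_med = min(max(s_med, 0.2), 0.8)
    n_conf = k if k < 3 else k - 1
    q = (np.arange(n_conf) + 1.0) / (n_conf + 1.0)
    e_targets = (
        np.quantile(e_burst, q) if e_burst.size else np.linspace(0.2, 0.8, n_conf)
    )
    e_targets = list(e_targets) + ([0.05] if k >= 3 else [])
    s_targets = [s_med] * n_conf + ([0.95] if k >= 3 else [])
    if perturb:
        e_targets = [e + rng.normal(0, 0.08) for e in e_targets]
        s_targets = [s + rng.normal(0, 0.05) for s in s_targets]
    obs = np.empty((k, _COLOURS))
    for i, (e, s) in enumerate(zip(e_targets, s_targets)):
        e = min(max(e, 0.02), 0.98)
        s = min(max(s, 0.05), 0.98)
        obs[i] = (s * (1 - e), s * e, 1 - s)
    obs /= obs.sum(axis=1, keepdims=True)
    rate0 = 100.0 * (rng.lognormal(0, 0.5) if perturb else 1.0)
    p_tick = min(rate0 * data.clock_period, 0.5 / max(k - 1, 1))
    trans = np.full((k, k), p_tick)
    np.fill_diagonal(trans, 1.0 - p_tick * (k - 1))
    pi = np.full(k, 1.0 / k)
    return H2MMModel(pi, trans, obs, data.clock_period)


def _constrained_rows(counts: np.ndarray, p_max: float) -> np.ndarray:
    """Row-stochastic argmax of sum C_ij ln A_ij with off-diagonals <= p_max.

    KKT water-filling: off-diagonal entries whose proportional share
    exceeds the cap are pinned at the cap and the remaining mass is
    redistributed proportionally over the free entries (the diagonal is
    unconstrained).  Maximizing the constrained M-step objective keeps EM
    monotone as long as the previous matrix was feasible.
    """
    k = counts.shape[0]
    a = np.empty_like(counts, dtype=float)
    for i in range(k):
        c = counts[i]
        if c.sum() <= 0:
            a[i] = np.eye(k)[i]
            continue
        clipped = np.zeros(k, dtype=bool)
        for _ in range(k):
            free_mass = 1.0 - p_max * clipped.sum()
            c_free = np.where(clipped, 0.0, c)
            share = np.zeros(k)
            if c_free.sum() > 0:
                share = c_free / c_free.sum() * free_mass
            else:  # all off-diagonal counts clipped; rest on diagonal
                share[i] = free_mass
            viol = (share > p_max) & ~clipped
            viol[i] = False
            if not viol.any():
                a[i] = np.where(clipped, p_max, share)
                break
            clipped |= viol
        else:
            a[i] = np.where(clipped, p_max, share)
    return a


def fit_h2mm(
    data: BurstPhotonData,
    k: int,
    init: H2MMModel | str = "quantile",
    tol: float = 1e-7,
    max_iter: int = 1000,
    restarts: int = 5,
    seed: int = 0,
    max_rate: float | None = 2e3,
) -> tuple[H2MMModel, float]:
    """Baum-Welch-type EM with arrival-time-dependent transition operators.

    The E-step computes exact expected tick-level transition counts via the
    eigendecomposition divided-difference identity, so the per-tick ``A``
    M-step is closed form and the log-likelihood is non-decreasing (this is
    asserted each iteration).  Convergence: per-photon LL improvement below
    ``tol``.  ``restarts`` random initializations (the first is the
    deterministic quantile init) are fitted and the best LL kept.

    ``max_rate`` (s^-1) bounds the fitted transition rates.  In ALEX data
    the excitation lasers alternate at ~10 kHz, and an unconstrained HMM
    will lock onto that deterministic colour gating as a spurious fast
    "dynamics" state; switching faster than the alternation is not
    identifiable, so rates are kept well below it (default 2000 s^-1, a
    fifth of the standard 100 µs alternation frequency).  Pass ``None`` to disable.

    Returns ``(model, loglikelihood)``.
    """
    if data.n_bursts < 1 or k < 1:
        raise H2MMError("need at least one burst and K >= 1")
    rng = np.random.default_rng(seed)
    inits: list[H2MMModel]
    if isinstance(init, H2MMModel):
        inits = [init]
    else:
        inits = [
            _init_model(data, k, rng, perturb=(r > 0)) for r in range(max(restarts, 1))
        ]
    p_max = 1.0 if max_rate is None else max_rate * data.clock_period
    best: tuple[H2MMModel, float] | None = None
    for model in inits:
        fitted, ll = _em(data, model, tol, max_iter, p_max)
        if best is None or ll > best[1]:
            best = (fitted, ll)
    return best


def _em(
    data: BurstPhotonData, model: H2MMModel, tol: float, max_iter: int,
    p_max: float = 1.0,
) -> tuple[H2MMModel, float]:
    pi, a, b = model.pi.copy(), model.trans.copy(), model.obs.copy()
    k = a.shape[0]
    if p_max < 1.0:  # project the initial matrix into the feasible set
        off = ~np.eye(k, dtype=bool)
        a = np.where(off, np.minimum(a, p_max), 0.0)
        np.fill_diagonal(a, 1.0 - a.sum(axis=1))
    n_ph = data.n_photons
    ll_prev = -np.inf
    for it in range(max_iter):
        p, h = operator_tables(a, data.unique_deltas)
        ll, b_num, pi_num, trans_counts = em_pass(
            data.colors, data.didx, data.deltas, data.ptr, p, b, pi, h
        )
        if np.isfinite(ll_prev) and ll < ll_prev - 1e-8 * abs(ll_prev) - 1e-9:
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: {ll_prev} -> {ll}"
            )
        converged = np.isfinite(ll_prev) and (ll - ll_prev) / n_ph < tol
        ll_prev = ll
        # M-step
        pi = pi_num / max(pi_num.sum(), 1e-300)
        a = _constrained_rows(trans_counts, p_max)
        rows_b = b_num.sum(axis=1, keepdims=True)
        b = np.where(rows_b > 0, b_num / np.where(rows_b > 0, rows_b, 1), 1.0 / _COLOURS)
        b = np.clip(b, 1e-15, None)
        b /= b.sum(axis=1, keepdims=True)
        if converged:
            break
    fitted = H2MMModel(pi, a, b, data.clock_period)
    return fitted, loglikelihood(fitted, data)


# ---------------------------------------------------------------------------
# Model selection (ICL)
# ---------------------------------------------------------------------------

def n_free_parameters(k: int) -> int:
    return (k - 1) + k * (k - 1) + k * (_COLOURS - 1)


def icl(model: H2MMModel, data: BurstPhotonData) -> float:
    """Integrated complete likelihood (BIC-type penalty on the Viterbi path).

    ICL = -[ CLL(Viterbi) - (d/2) ln(N_photons) ]; lower is better.
    """
    states = viterbi_states(model, data)
    p, _ = operator_tables(model.trans, data.unique_deltas, with_counts=False)
    with np.errstate(divide="ignore"):
        logp = np.log(p)
        logb = np.log(model.obs)
        logpi = np.log(model.pi)
    cll = 0.0
    for bi in range(data.n_bursts):
        s, e = data.ptr[bi], data.ptr[bi + 1]
        st = states[s:e]
        cll += logpi[st[0]] + logb[st[0], data.colors[s]]
        if e - s > 1:
            cll += np.sum(logp[data.didx[s + 1:e], st[:-1], st[1:]])
            cll += np.sum(logb[st[1:], data.colors[s + 1:e]])
    d = n_free_parameters(model.n_states)
    return float(-(cll - 0.5 * d * np.log(data.n_photons)))


@dataclass
class ModelSelection:
    models: dict[int, H2MMModel]
    loglikelihoods: dict[int, float]
    icls: dict[int, float]
    flagged: dict[int, bool]  # contains rates too slow to detect (k << 1/s)
    best_k: int

    @property
    def best_model(self) -> H2MMModel:
        return self.models[self.best_k]


def select_model(
    data: BurstPhotonData,
    k_max: int = 5,
    slow_rate_threshold: float = 1.0,
    **fit_kwargs,
) -> ModelSelection:
    """Fit K = 1..k_max, pick the ICL-minimal physically reasonable model.

    Models containing any transition rate below ``slow_rate_threshold``
    (s^-1) are flagged as physically unreasonable — such slow exchange is
    undetectable within millisecond bursts; if every multi-state model is
    flagged the ICL minimum is returned with a warning.
    """
    models, lls, icls, flagged = {}, {}, {}, {}
    for k in range(1, k_max + 1):
        model, ll = fit_h2mm(data, k, **fit_kwargs)
        models[k], lls[k] = model, ll
        icls[k] = icl(model, data)
        if k == 1:
            flagged[k] = False
        else:
            q = model.rate_matrix()
            off = q[~np.eye(k, dtype=bool)]
            flagged[k] = bool((off < slow_rate_threshold).any())
    candidates = [k for k in icls if not flagged[k]]
    if candidates:
        best_k = min(candidates, key=lambda k: icls[k])
    else:
        best_k = min(icls, key=lambda k: icls[k])
        warnings.warn("all candidate models flagged as physically unreasonable")
    return ModelSelection(models, lls, icls, flagged, best_k)


# ---------------------------------------------------------------------------
# Viterbi dwells
# ---------------------------------------------------------------------------

@dataclass
class Dwell:
    burst_index: int
    state: int
    start: int  # photon index within the burst, half-open span
    stop: int
    n_dd: int
    n_da: int
    n_aa: int
    duration: float  # seconds

    @property
    def e_star(self) -> float:
        d = self.n_dd + self.n_da
        return self.n_da / d if d > 0 else np.nan

    @property
    def s(self) -> float:
        t = self.n_dd + self.n_da + self.n_aa
        return (self.n_dd + self.n_da) / t if t > 0 else np.nan


def viterbi_states(model: H2MMModel, data: BurstPhotonData) -> np.ndarray:
    p, _ = operator_tables(model.trans, data.unique_deltas, with_counts=False)
    with np.errstate(divide="ignore"):
        return viterbi_path(
            data.colors, data.didx, data.ptr,
            np.log(p), np.log(model.obs), np.log(model.pi),
        )


def viterbi_dwells(model: H2MMModel, data: BurstPhotonData) -> list[Dwell]:
    """Group consecutive same-state photons of each burst into dwells."""
    states = viterbi_states(model, data)
    dwells: list[Dwell] = []
    for bi in range(data.n_bursts):
        s, e = data.ptr[bi], data.ptr[bi + 1]
        st = states[s:e]
        col = data.colors[s:e]
        dt = data.deltas[s:e]
        bounds = np.concatenate(([0], np.nonzero(np.diff(st))[0] + 1, [e - s]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            c = col[a:b]
            dwells.append(
                Dwell(
                    burst_index=bi,
                    state=int(st[a]),
                    start=int(a),
                    stop=int(b),
                    n_dd=int(np.sum(c == DD)),
                    n_da=int(np.sum(c == DA)),
                    n_aa=int(np.sum(c == AA)),
                    duration=float(dt[a + 1:b].sum() * data.clock_period),
                )
            )
    return dwells


# ---------------------------------------------------------------------------
# K_closing and uncertainties
# ---------------------------------------------------------------------------

def identify_states(model: H2MMModel) -> tuple[int, int, int | None]:
    """(open, closed, dark) state indices by emission signature.

    The photophysical (acceptor-dark) state is the one with the highest
    stoichiometry (S ~ 1); among the remaining conformational states the
    lower-E* state is open and the higher-E* state closed.
    """
    k = model.n_states
    if k < 2:
        raise H2MMError("need at least two states to identify open/closed")
    e = model.state_e_star()
    s = model.state_s()
    if k == 2:
        dark = None
        conf = [0, 1]
    else:
        dark = int(np.argmax(s))
        conf = [i for i in range(k) if i != dark]
    e_conf = [(e[i], i) for i in conf]
    open_state = min(e_conf)[1]
    closed_state = max(e_conf)[1]
    return open_state, closed_state, dark


def conformational_rates(model: H2MMModel) -> tuple[float, float]:
    """(k_open->closed, k_closed->open) in s^-1."""
    o, c, _ = identify_states(model)
    q = model.rate_matrix()
    return float(q[o, c]), float(q[c, o])


def k_closing(model: H2MMModel) -> float:
    """Equilibrium constant of the open -> closed rearrangement."""
    k_oc, k_co = conformational_rates(model)
    if k_co <= 0:
        raise H2MMError("closed->open rate is not positive; K_closing undefined")
    return k_oc / k_co


def subset_uncertainty(
    data: BurstPhotonData,
    subset_size: int = 1850,
    k: int = 3,
    init: H2MMModel | str = "quantile",
    **fit_kwargs,
) -> dict:
    """Rate-constant SDs from sequential burst subsets (1700~2000 bursts).

    The burst set is split, in acquisition order, into near-equal subsets
    of about ``subset_size`` bursts; the K-state model is refitted per
    subset and the SD of each rate across subsets is reported, with the
    relative uncertainty on K_closing from error propagation through the
    rate ratio.
    """
    nb = data.n_bursts
    n_sub = nb // subset_size
    if n_sub < 2:
        raise H2MMError(
            f"only {nb} bursts: need >= 2 subsets of ~{subset_size}; collect more data"
        )
    edges = np.linspace(0, nb, n_sub + 1).astype(int)
    k_oc_list, k_co_list, kc_list = [], [], []
    for a, b in zip(edges[:-1], edges[1:]):
        sub = data.subset(slice(int(a), int(b)))
        model, _ = fit_h2mm(sub, k, init=init, **fit_kwargs)
        k_oc, k_co = conformational_rates(model)
        k_oc_list.append(k_oc)
        k_co_list.append(k_co)
        kc_list.append(k_oc / k_co if k_co > 0 else np.nan)
    k_oc_arr, k_co_arr = np.array(k_oc_list), np.array(k_co_list)
    mean_oc, mean_co = k_oc_arr.mean(), k_co_arr.mean()
    sd_oc = float(k_oc_arr.std(ddof=1))
    sd_co = float(k_co_arr.std(ddof=1))
    kc = mean_oc / mean_co
    rel = np.sqrt((sd_oc / mean_oc) ** 2 + (sd_co / mean_co) ** 2)
    return {
        "n_subsets": int(n_sub),
        "k_open_to_closed": float(mean_oc),
        "k_closed_to_open": float(mean_co),
        "sigma_k_open_to_closed": sd_oc,
        "sigma_k_closed_to_open": sd_co,
        "K_closing": float(kc),
        "sigma_K_closing": float(kc * rel),
        "subset_K_closing": [float(x) for x in kc_list],
    }


# ---------------------------------------------------------------------------
# Bundled result
# ---------------------------------------------------------------------------

@dataclass
class H2MMResult:
    model: H2MMModel
    loglikelihood: float
    icl: float
    k_open_to_closed: float
    k_closed_to_open: float
    k_closing: float
    uncertainties: dict | None = None
    dwells: list[Dwell] | None = None

    def to_dict(self) -> dict:
        d = {
            "model": self.model.to_dict(),
            "loglikelihood": self.loglikelihood,
            "icl": self.icl,
            "k_open_to_closed_per_s": self.k_open_to_closed,
            "k_closed_to_open_per_s": self.k_closed_to_open,
            "K_closing": self.k_closing,
        }
        if self.uncertainties is not None:
            d["uncertainties"] = self.uncertainties
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def analyze_bursts(
    data: BurstPhotonData,
    k: int = 3,
    with_dwells: bool = True,
    with_uncertainty: bool = False,
    subset_size: int = 1850,
    **fit_kwargs,
) -> H2MMResult:
    """Fit the K-state model and assemble rates, K_closing and dwells."""
    model, ll = fit_h2mm(data, k, **fit_kwargs)
    k_oc, k_co = conformational_rates(model)
    unc = None
    if with_uncertainty:
        sub_kwargs = dict(fit_kwargs)
        sub_kwargs["restarts"] = 1
        unc = subset_uncertainty(data, subset_size, k, init=model, **sub_kwargs)
    return H2MMResult(
        model=model,
        loglikelihood=ll,
        icl=icl(model, data),
        k_open_to_closed=k_oc,
        k_closed_to_open=k_co,
        k_closing=k_oc / k_co if k_co > 0 else np.nan,
        uncertainties=unc,
        dwells=viterbi_dwells(model, data) if with_dwells else None,
    )
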