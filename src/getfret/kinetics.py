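"""Ensemble chase kinetics of chaperone-substrate handover.

A preformed chaperone-substrate complex (Sgt2-TA) is chased with an excess
competitor (CaM, cpSRP43, unlabelled chaperone) and substrate release is
followed as recovery of donor fluorescence, normalized so F = 0 at t = 0
and F = 1 at completion.  Two mass-action mechanisms distinguish how the
chase acts:

* spontaneous / trap:  Sgt2-TA <-> Sgt2 + TA;  TA + CaM <-> CaM-TA.
  Observed release is rate-limited by spontaneous dissociation and
  independent of chase concentration.
* invasion:  Sgt2-TA + CaM <-> Sgt2-TA.CaM <-> Sgt2 + CaM-TA.
  The chase attacks the complex directly, so release accelerates linearly
  with chase concentration.

A combined variant carries both pathways; the y-intercept of the fitted
k_obs-versus-[chase] line then reports the intrinsic dissociation rate.
Time is in minutes and concentrations in µM throughout (a printed
second-order constant of, e.g., 0.035e6 M^-1 min^-1 is 0.035 µM^-1 min^-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit
from scipy.stats import linregress

__all__ = [
    "Trace", "ExpFitResult", "ChaseModelSpec", "SolubilizationFit",
    "fit_single_exp", "fit_double_exp", "simulate_release",
    "kobs_vs_chase", "fit_solubilization", "measure_kobs",
]


class KineticsError(ValueError):
    pass


@dataclass
class Trace:
    """Normalized fluorescence time course (time in minutes)."""

    time: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.fluorescence = np.asarray(self.fluorescence, float)
        if self.time.size != self.fluorescence.size:
            raise KineticsError("time/fluorescence length mismatch")
        if self.time.size > 1 and not (np.diff(self.time) > 0).all():
            raise KineticsError("times must be strictly increasing")


def single_exp(t, a, k):
    return a * (1.0 - np.exp(-k * t))


def double_exp(t, a_fast, k_fast, a_slow, k_slow):
    return a_fast * (1.0 - np.exp(-k_fast * t)) + a_slow * (1.0 - np.exp(-k_slow * t))


@dataclass
class ExpFitResult:
    model: str  # "single" | "double"
    a: float | None = None
    k: float | None = None
    a_fast: float | None = None
    k_fast: float | None = None
    a_slow: float | None = None
    k_slow: float | None = None
    stderr: dict = field(default_factory=dict)
    covariance: np.ndarray | None = None
    residual_structure: bool = False


def _residual_structure(residuals: np.ndarray) -> bool:
    """Sign-runs test: too few runs means the fit misses systematic shape."""
    r = residuals[residuals != 0]
    n = r.size
    if n < 8:
        return False
    signs = r > 0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n1, n2 = int(signs.sum()), int((~signs).sum())
    if n1 == 0 or n2 == 0:
        return True
    mu = 2 * n1 * n2 / n + 1
    var = (mu - 1) * (mu - 2) / (n - 1)
    if var <= 0:
        return False
    z = (runs - mu) / np.sqrt(var)
    return bool(z < -2.0)


def fit_single_exp(trace: Trace) -> ExpFitResult:
    """Least-squares fit of A(1 - e^{-kt}); rates in min^-1."""
    if trace.time.size < 5:
        raise KineticsError("need at least 5 points for a single-exponential fit")
    t, f = trace.time, trace.fluorescence
    a0 = max(f[-1], 1e-3)
    half = t[np.searchsorted(f, a0 / 2)] if (f >= a0 / 2).any() else t[-1] / 2
    k0 = np.log(2) / max(half, t[1] - t[0])
    try:
        popt, pcov = curve_fit(
            single_exp, t, f, p0=(a0, k0), maxfev=20000,
            bounds=((0, 0), (np.inf, np.inf)),
        )
    except RuntimeError as exc:
        raise KineticsError(f"single-exponential fit did not converge: {exc}") from exc
    resid = f - single_exp(t, *popt)
    err = np.sqrt(np.diag(pcov))
    return ExpFitResult(
        model="single", a=float(popt[0]), k=float(popt[1]),
        stderr={"a": float(err[0]), "k": float(err[1])},
        covariance=pcov, residual_structure=_residual_structure(resid),
    )


def fit_double_exp(trace: Trace) -> ExpFitResult:
    """Biphasic fit A_f(1-e^{-k_f t}) + A_s(1-e^{-k_s t}), k_fast > k_slow."""
    if trace.time.size < 8:
        raise KineticsError("need at least 8 points for a double-exponential fit")
    t, f = trace.time, trace.fluorescence
    a_tot = max(f[-1], 1e-3)
    k0 = np.log(2) / max(t[-1] / 4, t[1] - t[0])
    try:
        popt, pcov = curve_fit(
            double_exp, t, f, p0=(a_tot / 2, k0 * 10, a_tot / 2, k0 / 10),
            maxfev=50000, bounds=((0, 0, 0, 0), (np.inf,) * 4),
        )
    except RuntimeError as exc:
        raise KineticsError(f"double-exponential fit did not converge: {exc}") from exc
    a1, kf, a2, ks = popt
    err = np.sqrt(np.diag(pcov))
    if kf < ks:  # enforce k_fast > k_slow by swapping phases
        a1, kf, a2, ks = a2, ks, a1, kf
        err = err[[2, 3, 0, 1]]
    total = a1 + a2
    if total > 0 and min(a1, a2) / total < 0.01:
        warnings.warn("one phase amplitude < 1%: a single exponential is adequate")
    if kf > 0 and abs(kf - ks) / kf < 1e-3:
        warnings.warn("rate constants degenerate; phases not identifiable — "
                      "consider a single-exponential fit")
    resid = f - double_exp(t, a1, kf, a2, ks)
    return ExpFitResult(
        model="double", a_fast=float(a1), k_fast=float(kf),
        a_slow=float(a2), k_slow=float(ks),
        stderr={"a_fast": float(err[0]), "k_fast": float(err[1]),
                "a_slow": float(err[2]), "k_slow": float(err[3])},
        covariance=pcov, residual_structure=_residual_structure(resid),
    )


# ---------------------------------------------------------------------------
# Mass-action chase models
# ---------------------------------------------------------------------------

@dataclass
class ChaseModelSpec:
    """Rate constants (min^-1 or µM^-1 min^-1) + initial concentrations (µM).

    Variants: ``spontaneous`` (trap mechanism), ``invasion`` (direct
    complex attack), ``combined`` (both pathways active, for
    k_obs-vs-chase intercept analysis).
    """

    variant: str
    rates: dict[str, float]
    conc: dict[str, float]

    def __post_init__(self) -> None:
        if self.variant not in ("spontaneous", "invasion", "combined"):
            raise KineticsError(f"unknown variant {self.variant!r}")
        if any(v < 0 for v in self.rates.values()):
            raise KineticsError("rate constants must be >= 0")
        if any(v < 0 for v in self.conc.values()):
            raise KineticsError("concentrations must be >= 0")

    @classmethod
    def spontaneous(cls, cam_uM: float, sgt2_ta_uM: float = 0.05,
                    k1: float = 0.015, km1: float = 1.0,
                    k2: float = 10.0, km2: float = 10.0) -> "ChaseModelSpec":
        """Trap mechanism with the standard constants (k1 in min^-1,
        km1/k2 in µM^-1 min^-1, km2 in min^-1)."""
        return cls(
            "spontaneous",
            {"k1": k1, "km1": km1, "k2": k2, "km2": km2},
            {"sgt2_ta": sgt2_ta_uM, "sgt2": 0.0, "ta": 0.0,
             "cam": cam_uM, "cam_ta": 0.0},
        )

    @classmethod
    def invasion(cls, cam_uM: float, sgt2_ta_uM: float = 0.05,
                 k1: float = 0.035, km1: float = 1.0,
                 k2: float = 10.0, km2: float = 20.0) -> "ChaseModelSpec":
        """Invasion mechanism (k1/km2 in µM^-1 min^-1, km1/k2 in min^-1)."""
        return cls(
            "invasion",
            {"k1": k1, "km1": km1, "k2": k2, "km2": km2},
            {"sgt2_ta": sgt2_ta_uM, "cam": cam_uM, "sgt2_ta_cam": 0.0,
             "sgt2": 0.0, "cam_ta": 0.0},
        )

    @classmethod
    def combined(cls, cam_uM: float, sgt2_ta_uM: float = 0.05,
                 spont_k1: float = 0.018, spont_km1: float = 1.0,
                 trap_k2: float = 10.0, trap_km2: float = 10.0,
                 inv_k1: float = 0.035, inv_km1: float = 1.0,
                 inv_k2: float = 10.0, inv_km2: float = 20.0,
                 irreversible_capture: bool = False) -> "ChaseModelSpec":
        """Both pathways: spontaneous dissociation + trap, plus invasion.

        ``irreversible_capture`` zeroes the reverse of both capture steps
        (chase-bound TA never returns), the regime of a large chase excess
        where the observed rate is the sum of the two parallel release
        pathways, k_obs = k_off + k_invade [chase] — the regime assumed
        when reading the intrinsic k_off off the y-intercept.
        """
        if irreversible_capture:
            trap_km2 = 0.0
            inv_km2 = 0.0
        return cls(
            "combined",
            {"spont_k1": spont_k1, "spont_km1": spont_km1,
             "trap_k2": trap_k2, "trap_km2": trap_km2,
             "inv_k1": inv_k1, "inv_km1": inv_km1,
             "inv_k2": inv_k2, "inv_km2": inv_km2},
            {"sgt2_ta": sgt2_ta_uM, "sgt2": 0.0, "ta": 0.0, "cam": cam_uM,
             "sgt2_ta_cam": 0.0, "cam_ta": 0.0},
        )

    def total_ta(self, y: np.ndarray) -> float:
        names = self.species()
        idx = [i for i, n in enumerate(names) if n in ("sgt2_ta", "ta", "sgt2_ta_cam", "cam_ta")]
        return float(np.sum(y[idx]))

    def species(self) -> list[str]:
        if self.variant == "spontaneous":
            return ["sgt2_ta", "sgt2", "ta", "cam", "cam_ta"]
        if self.variant == "invasion":
            return ["sgt2_ta", "cam", "sgt2_ta_cam", "sgt2", "cam_ta"]
        return ["sgt2_ta", "sgt2", "ta", "cam", "sgt2_ta_cam", "cam_ta"]

    def rhs(self, _t: float, y: np.ndarray) -> np.ndarray:
        r = self.rates
        if self.variant == "spontaneous":
            st, sg, ta, cam, ct = y
            v1 = r["k1"] * st - r["km1"] * sg * ta
            v2 = r["k2"] * ta * cam - r["km2"] * ct
            return np.array([-v1, v1, v1 - v2, -v2, v2])
        if self.variant == "invasion":
            st, cam, stc, sg, ct = y
            v1 = r["k1"] * st * cam - r["km1"] * stc
            v2 = r["k2"] * stc - r["km2"] * sg * ct
            return np.array([-v1, -v1, v1 - v2, v2, v2])
        st, sg, ta, cam, stc, ct = y
        vs = r["spont_k1"] * st - r["spont_km1"] * sg * ta
        vt = r["trap_k2"] * ta * cam - r["trap_km2"] * ct
        vi1 = r["inv_k1"] * st * cam - r["inv_km1"] * stc
        vi2 = r["inv_k2"] * stc - r["inv_km2"] * sg * ct
        return np.array([-vs - vi1, vs + vi2, vs - vt, -vt - vi1, vi1 - vi2, vt + vi2])

    def readout(self, y: np.ndarray) -> np.ndarray:
        """Normalized fluorescence: fraction of TA no longer on Sgt2."""
        names = self.species()
        st = y[names.index("sgt2_ta")]
        denom = np.zeros_like(st)
        for n in ("sgt2_ta", "ta", "sgt2_ta_cam", "cam_ta"):
            if n in names:
                denom = denom + y[names.index(n)]
        with np.errstate(invalid="ignore", divide="ignore"):
            f = 1.0 - st / denom
        return np.where(denom > 0, f, 0.0)


def simulate_release(model: ChaseModelSpec, times) -> Trace:
    """Stiff-capable integration of the mass-action model -> Trace.

    Conserves total TA to 1e-9 relative; aborts on negative concentrations
    beyond integrator tolerance.
    """
    times = np.asarray(times, float)
    names = model.species()
    y0 = np.array([model.conc.get(n, 0.0) for n in names])
    t_span = (min(0.0, times[0]), times[-1])
    sol = solve_ivp(
        model.rhs, t_span, y0, t_eval=times, method="LSODA",
        rtol=1e-9, atol=1e-12,
    )
    if not sol.success:
        raise KineticsError(f"ODE integration failed: {sol.message}")
    if (sol.y < -1e-8).any():
        raise KineticsError("negative concentrations beyond tolerance")
    total0 = model.total_ta(y0)
    if total0 > 0:
        drift = np.abs(model.total_ta(sol.y[:, -1:]) - total0) / total0
        if drift > 1e-7:
            raise KineticsError(f"TA mass conservation violated: drift {drift:.2e}")
    return Trace(times, model.readout(sol.y))


def measure_kobs(
    model: ChaseModelSpec, window: tuple[float, float] = (0.0, 10.0), n_points: int = 60
) -> float:
    """Apparent single-exponential release rate over the fitting window.

    The trace is renormalized to its window endpoint before fitting, the
    same way measured traces are normalized to the reaction plateau.
    """
    t = np.linspace(window[0], window[1], n_points)
    t[0] = max(t[0], 1e-6)
    trace = simulate_release(model, t)
    f_end = trace.fluorescence[-1]
    if f_end <= 0:
        raise KineticsError("no fluorescence change in window; k_obs undefined")
    return fit_single_exp(Trace(trace.time, trace.fluorescence)).k


def kobs_vs_chase(concentrations, k_obs_values) -> dict:
    """OLS line through k_obs([chase]); intercept = intrinsic k_off."""
    c = np.asarray(concentrations, float)
    k = np.asarray(k_obs_values, float)
    if c.size < 3:
        raise KineticsError("need at least 3 chase concentrations")
    res = linregress(c, k)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "slope_stderr": float(res.stderr),
        "intercept_stderr": float(res.intercept_stderr),
        "r_value": float(res.rvalue),
    }


# ---------------------------------------------------------------------------
# Turbidity / solubilization
# ---------------------------------------------------------------------------

@dataclass
class SolubilizationFit:
    s_max: float       # % soluble TA at saturation
    k_soluble: float   # µM chaperone for half-maximal solubilization
    stderr: dict
    saturated: bool    # data reach beyond K_soluble (CI meaningful)


def fit_solubilization(chaperone_concs, s_obsd) -> SolubilizationFit:
    """Hyperbolic fit S = S_max [C] / (K_soluble + [C])."""
    c = np.asarray(chaperone_concs, float)
    s = np.asarray(s_obsd, float)
    if c.size < 4:
        raise KineticsError("need at least 4 concentrations")
    popt, pcov = curve_fit(
        lambda x, smax, kd: smax * x / (kd + x), c, s,
        p0=(max(s.max(), 1.0), max(np.median(c), 1e-3)),
        maxfev=20000, bounds=((0, 1e-9), (np.inf, np.inf)),
    )
    err = np.sqrt(np.diag(pcov))
    saturated = c.max() >= 2 * popt[1]
    if not saturated:
        warnings.warn("no saturation in data: K_soluble confidence interval is wide")
    return SolubilizationFit(
        s_max=float(popt[0]), k_soluble=float(popt[1]),
        stderr={"s_max": float(err[0]), "k_soluble": float(err[1])},
        saturated=bool(saturated),
    )
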