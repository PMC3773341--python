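"""Current-voltage relationships and descriptive model fits.

Builds i-v curves from grouped traces (peak or window-mean statistic),
fits single-channel conductance and reversal by ordinary least squares,
evaluates Nernst equilibrium potentials, fits Boltzmann G/Gmax activation
curves, computes the paired holding-potential subtraction i-v, and fits
single-exponential inactivation time constants and Hill inhibition
dose-response curves (IC50).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .sim_channels import CurrentTrace

__all__ = [
    "IVCurve",
    "FitResult",
    "build_iv",
    "fit_conductance",
    "nernst_potential",
    "gv_boltzmann",
    "subtract_iv",
    "fit_inactivation_tau",
    "fit_hill_inhibition",
]

GAS_CONSTANT = 8.31446261815324      # J / (mol K)
FARADAY = 96485.33212                # C / mol
DEFAULT_TEMPERATURE = 295.0          # K, room temperature


@dataclass
class IVCurve:
    """Per-potential current statistic with sample size and s.e.m."""

    v: np.ndarray      # mV, strictly increasing
    i: np.ndarray      # pA
    n: np.ndarray      # sweeps per point
    sem: np.ndarray    # pA

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        self.n = np.asarray(self.n, dtype=np.int64)
        self.sem = np.asarray(self.sem, dtype=float)
        if not (self.v.size == self.i.size == self.n.size == self.sem.size):
            raise ValueError("v, i, n, sem must have equal length")
        if np.any(np.diff(self.v) <= 0):
            raise ValueError("voltages must be strictly increasing")
        if np.any(self.n < 1):
            raise ValueError("each point needs n >= 1")


@dataclass
class FitResult:
    """Named parameters of a converged (or flagged) model fit."""

    parameters: dict[str, float]
    stderr: dict[str, float] = field(default_factory=dict)
    residual_norm: float = float("nan")
    converged: bool = True
    message: str = ""

    def __getitem__(self, key: str) -> float:
        return self.parameters[key]


# ---------------------------------------------------------------------------
# i-v construction
# ---------------------------------------------------------------------------

def build_iv(traces: Mapping[float, Sequence[CurrentTrace]],
             window: tuple[float, float], statistic: str = "mean") -> IVCurve:
    """Per-potential statistic of grouped traces over a time window.

    ``statistic='mean'`` averages the window; ``'peak'`` takes the sample
    of largest absolute amplitude in the window (signed), appropriate for
    transient currents such as the T-type component.
    """
    if statistic not in ("mean", "peak"):
        raise ValueError("statistic must be 'mean' or 'peak'")
    if len(traces) < 2:
        raise ValueError("need traces at >= 2 distinct potentials")
    vs, iv, ns, sems = [], [], [], []
    for v in sorted(traces):
        group = list(traces[v])
        if not group:
            raise ValueError(f"no traces at {v} mV")
        vals = []
        for tr in group:
            lo = int(round(window[0] / tr.sampling_interval))
            hi = int(round(window[1] / tr.sampling_interval))
            if lo < 0 or hi > tr.samples.size or hi <= lo:
                raise ValueError("window outside trace")
            seg = tr.samples[lo:hi]
            if statistic == "mean":
                vals.append(float(seg.mean()))
            else:
                vals.append(float(seg[np.argmax(np.abs(seg))]))
        vals = np.asarray(vals)
        vs.append(v)
        iv.append(vals.mean())
        ns.append(vals.size)
        sems.append(vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0)
    return IVCurve(np.array(vs), np.array(iv), np.array(ns), np.array(sems))


def subtract_iv(iv_hp80: IVCurve, iv_hp40: IVCurve) -> IVCurve:
    """Pointwise HP -80 minus HP -40 difference with s.e.m. in quadrature."""
    if iv_hp80.v.size != iv_hp40.v.size or not np.allclose(iv_hp80.v, iv_hp40.v):
        raise ValueError("voltage grids must be identical")
    return IVCurve(iv_hp80.v.copy(),
                   iv_hp80.i - iv_hp40.i,
                   np.minimum(iv_hp80.n, iv_hp40.n),
                   np.hypot(iv_hp80.sem, iv_hp40.sem))


# ---------------------------------------------------------------------------
# linear conductance and Nernst
# ---------------------------------------------------------------------------

def fit_conductance(iv: IVCurve,
                    v_window: tuple[float, float] = (-10.0, 60.0)) -> FitResult:
    """OLS line through the i-v points inside ``v_window``.

    Returns ``gamma`` (pS; the slope in pA/mV is nS) and the reversal
    potential ``e_rev = -intercept/slope`` (mV).  The default window is
    the linear part of the asymmetric-K+ single-channel curve.
    """
    mask = (iv.v >= v_window[0]) & (iv.v <= v_window[1])
    v, i = iv.v[mask], iv.i[mask]
    if v.size < 3:
        raise ValueError("need >= 3 points inside the fit window")
    if np.ptp(v) == 0:
        raise ValueError("singular design: all points at one voltage")
    (slope, intercept), cov = np.polyfit(v, i, 1, cov=True)
    resid = i - (slope * v + intercept)
    se_slope, se_int = np.sqrt(np.diag(cov))
    gamma = slope * 1e3                       # pA/mV -> pS
    e_rev = -intercept / slope
    # first-order propagation for e_rev
    se_e = abs(e_rev) * np.hypot(se_int / abs(intercept) if intercept else 0.0,
                                 se_slope / abs(slope))
    return FitResult({"gamma": gamma, "e_rev": e_rev},
                     {"gamma": se_slope * 1e3, "e_rev": float(se_e)},
                     float(np.linalg.norm(resid)))


def nernst_potential(c_out: float, c_in: float, valence: int = 1,
                     temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Nernst equilibrium potential (mV): (RT/zF) ln(c_out/c_in)."""
    if c_out <= 0 or c_in <= 0:
        raise ValueError("concentrations must be > 0")
    if valence == 0:
        raise ValueError("valence must be nonzero")
    return (GAS_CONSTANT * temperature / (valence * FARADAY)
            * np.log(c_out / c_in) * 1e3)


# ---------------------------------------------------------------------------
# nonlinear fits (multi-start least squares)
# ---------------------------------------------------------------------------

def _multistart_fit(f, x, y, starts, bounds=(-np.inf, np.inf)):
    """curve_fit from several data-driven starts; best residual norm wins."""
    best = None
    for p0 in starts:
        try:
            popt, pcov = optimize.curve_fit(f, x, y, p0=p0, bounds=bounds,
                                            maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rn = float(np.linalg.norm(y - f(x, *popt)))
        if best is None or rn < best[2]:
            best = (popt, pcov, rn)
    return best


def gv_boltzmann(iv: IVCurve, e_rev: float) -> FitResult:
    """Boltzmann fit of the normalized conductance-voltage curve.

    Chord conductance ``G(V) = I/(V - e_rev)`` is fitted with
    ``G = gmax / (1 + exp(-(V - v_half)/slope))``; the reported curve is
    normalized by the fitted gmax, so G/Gmax lies in [0, ~1].
    """
    mask = iv.v != e_rev
    v = iv.v[mask]
    g = iv.i[mask] / (v - e_rev)
    if v.size < 4:
        raise ValueError("need >= 4 points away from the reversal potential")

    def boltz(vv, gmax, vh, k):
        return gmax / (1.0 + np.exp(-(vv - vh) / k))

    gmax0 = float(np.max(np.abs(g)))
    vh0 = float(v[np.argmin(np.abs(g - 0.5 * gmax0))])
    span = max(np.ptp(v), 1.0)
    starts = [(gmax0, vh0, s) for s in (span / 10, span / 4, span / 20)]
    best = _multistart_fit(boltz, v, g, starts,
                           bounds=([0, -200, 0.1], [np.inf, 200, 200]))
    if best is None:
        return FitResult({}, converged=False, message="Boltzmann fit failed")
    popt, pcov, rn = best
    se = np.sqrt(np.diag(pcov))
    return FitResult({"gmax": popt[0], "v_half": popt[1], "slope": popt[2]},
                     {"gmax": se[0], "v_half": se[1], "slope": se[2]}, rn)


def fit_inactivation_tau(trace: CurrentTrace,
                         window: tuple[float, float]) -> FitResult:
    """Single-exponential decay fit ``I(t) = A exp(-t/tau) + C`` in a window.

    ``t`` is measured from the window start.  Non-decaying input (amplitude
    indistinguishable from zero, or best tau at the bound) is flagged via
    ``converged=False`` rather than raised.
    """
    dt = trace.sampling_interval
    lo, hi = (int(round(w / dt)) for w in window)
    if hi - lo < 10:
        raise ValueError("window must contain >= 10 samples")
    if lo < 0 or hi > trace.samples.size:
        raise ValueError("window outside trace")
    y = trace.samples[lo:hi]
    t = np.arange(y.size) * dt

    def expdec(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    a0 = float(y[0] - y[-1])
    c0 = float(y[-1])
    span = t[-1] if t[-1] > 0 else 1.0
    starts = [(a0, s, c0) for s in (span / 5, span / 2, span * 2)]
    best = _multistart_fit(expdec, t, y, starts,
                           bounds=([-np.inf, dt, -np.inf],
                                   [np.inf, 1e7, np.inf]))
    if best is None:
        return FitResult({}, converged=False, message="exponential fit failed")
    popt, pcov, rn = best
    se = np.sqrt(np.diag(pcov))
    scale = max(float(np.ptp(y)), abs(popt[2]), 1e-12)
    ok = abs(popt[0]) > 0.01 * scale and popt[1] < 0.99e7
    return FitResult({"amplitude": popt[0], "tau": popt[1], "offset": popt[2]},
                     {"amplitude": se[0], "tau": se[1], "offset": se[2]},
                     rn, converged=bool(ok),
                     message="" if ok else "no resolvable decay")


def fit_hill_inhibition(concentrations: Sequence[float],
                        responses: Sequence[float]) -> FitResult:
    """Hill inhibition fit ``response = 1 / (1 + (c/IC50)^n)``.

    ``responses`` are fractions of the control current, expected in
    [0, 1.2]; by construction the response at c = IC50 is 0.5 for any n.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.size < 4:
        raise ValueError("need >= 4 concentrations spanning the transition")
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    if np.any((y < 0) | (y > 1.2)):
        raise ValueError("responses must lie in [0, 1.2]")

    def hill(cc, ic50, n):
        return 1.0 / (1.0 + (cc / ic50) ** n)

    ic0 = float(c[np.argmin(np.abs(y - 0.5))])
    starts = [(ic0, 1.0), (np.exp(np.log(c).mean()), 1.5), (ic0, 0.7)]
    best = _multistart_fit(hill, c, y, starts,
                           bounds=([c.min() / 1e3, 0.1], [c.max() * 1e3, 10]))
    if best is None:
        return FitResult({}, converged=False, message="Hill fit failed")
    popt, pcov, rn = best
    se = np.sqrt(np.diag(pcov))
    return FitResult({"ic50": popt[0], "hill_n": popt[1]},
                     {"ic50": se[0], "hill_n": se[1]}, rn)
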