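"""Stochastic and deterministic simulation of BK / Cav3.2 channel gating.

This module is the synthetic-data generator for the package: it produces
single-channel and macroscopic current records for a large-conductance
Ca2+- and voltage-activated K+ channel (BK, ~186 pS in symmetric K+), a
transient low-voltage-activated T-type Ca2+ conductance (Cav3.2, m^2 h
kinetics, fully inactivated at a sustained -40 mV holding potential), and
their coupling through the local Ca2+ concentration in a shared membrane
nanodomain.  It also samples per-patch channel occupancy counts under
uniform or clustered channel placement, and synthesizes Fura-2 ratio
series from a Ca2+ time course.

Gating model
------------
BK channels follow a two-state C<->O Markov scheme with Boltzmann voltage
dependence of the rates,

    alpha(V, Ca) = a0 * exp(+(V - Vh(Ca)) / s)
    beta(V, Ca)  = b0 * exp(-(V - Vh(Ca)) / s)
    Vh(Ca)       = Vh_ref - d * log10(Ca / Ca_ref)

so the stationary open probability is a Boltzmann in V with half-activation
Vh(Ca) and effective slope s/2, and raising Ca shifts activation negative
by ``d`` millivolts per decade.  Cav3.2 channels are Hodgkin-Huxley m^2 h:
deterministically integrated gate variables for macroscopic currents, or
three independent stochastic binary gates (two activation, one
inactivation) per channel for single-channel records.

All stochastic operations take an integer seed and are bit-reproducible.
Currents follow the outward-positive sign convention; unitary current is
``gamma * (V - E_rev)`` with gamma in pS, V in mV and i in pA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "VoltageProtocol",
    "GatingParamsBK",
    "GatingParamsT",
    "CouplingParams",
    "Fura2Calibration",
    "OpenCountSeries",
    "CurrentTrace",
    "Cav32Result",
    "CoupledPatchResult",
    "PairedSweepSet",
    "simulate_gating",
    "synthesize_current",
    "simulate_cav32",
    "simulate_coupled_patch",
    "simulate_coupled_ensemble",
    "run_paired_hp_protocol",
    "sample_patch_counts",
    "simulate_fura2",
    "bk_stationary_po",
    "bk_v_half",
    "t_gate_steady_state",
    "unitary_current",
]

DEFAULT_DT = 0.05  # ms; fixed integration step, adequate for >=1 ms dwells


# ---------------------------------------------------------------------------
# protocol and parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoltageProtocol:
    """Piecewise-constant command-voltage protocol.

    Parameters
    ----------
    segments
        Ordered ``(level_mV, duration_ms)`` pairs.
    sampling_interval
        Sample spacing in ms.  Time axes start at 0 and samples belong to
        the half-open interval ``[start, end)`` of their segment.
    """

    segments: tuple[tuple[float, float], ...]
    sampling_interval: float = DEFAULT_DT
    label: str = ""

    def __post_init__(self) -> None:
        segs = tuple((float(v), float(d)) for v, d in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("protocol needs at least one segment")
        if any(d <= 0 for _, d in segs):
            raise ValueError("segment durations must be > 0")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.segments))

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration / self.sampling_interval))

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sampling_interval

    def voltages(self) -> np.ndarray:
        """Per-sample command voltage (mV)."""
        bounds = np.cumsum([d for _, d in self.segments])
        idx = np.searchsorted(bounds, self.times(), side="right")
        idx = np.minimum(idx, len(self.segments) - 1)
        levels = np.array([v for v, _ in self.segments])
        return levels[idx]

    def segment_onset(self, i: int) -> float:
        """Start time (ms) of segment ``i``."""
        return float(sum(d for _, d in self.segments[:i]))


def step_protocol(hp: float, test: float, *, pre: float = 20.0,
                  duration: float = 500.0, dt: float = DEFAULT_DT,
                  label: str = "") -> VoltageProtocol:
    """Holding-potential segment followed by a single test pulse."""
    return VoltageProtocol(((hp, pre), (test, duration)), dt, label)


@dataclass(frozen=True)
class GatingParamsBK:
    """Two-state BK gating parameters.

    Defaults are calibrated so that, at strongly buffered Ca2+ (~10 nM),
    the stationary activation curve has Vh = +20 mV with an effective
    8 mV slope: open probability is below 0.05 at -20 mV, currents first
    become visible near -10 mV, and activation exceeds 0.5 by +30 mV.
    The Ca2+ sensitivity is a -40 mV/decade shift of Vh.

    The base rates set the *envelope* kinetics of activation — the slow
    effective relaxation that in a real BK channel includes Ca2+
    (un)binding — not the fast intraburst flicker, which a two-state
    scheme cannot carry simultaneously.  They are calibrated so that the
    ensemble open probability of a nanodomain-coupled patch peaks a few
    tens of ms after a depolarization that admits a transient T-type
    Ca2+ flux.
    """

    unitary_conductance: float = 186.0   # pS, symmetric 150/150 K+
    reversal: float = 0.0                # mV, symmetric K+
    opening_rate_at_v0: float = 0.0025   # 1/ms at V = Vh(Ca)
    closing_rate_at_v0: float = 0.0025   # 1/ms at V = Vh(Ca)
    voltage_sensitivity: float = 16.0    # mV per e-fold of each rate
    v_half_ca_ref: float = 20.0          # mV at ca_ref
    ca_shift_per_decade: float = 40.0    # mV leftward per decade of Ca
    ca_ref: float = 10.0                 # nM

    def __post_init__(self) -> None:
        if self.unitary_conductance <= 0:
            raise ValueError("conductance must be > 0")
        if self.opening_rate_at_v0 <= 0 or self.closing_rate_at_v0 <= 0:
            raise ValueError("rates must be > 0")
        if self.voltage_sensitivity <= 0:
            raise ValueError("voltage_sensitivity must be > 0")


@dataclass(frozen=True)
class GatingParamsT:
    """Cav3.2 (T-type) m^2 h gating parameters.

    Defaults give an activation threshold near -50 mV and essentially
    complete steady-state inactivation at -40 mV (h_inf(-40) < 0.002),
    as required of a T-type conductance that is silenced by a -40 mV
    holding potential.
    """

    unitary_conductance: float = 7.0     # pS (at ~100 mM external divalent)
    macroscopic_conductance: float = 3.0  # nS, whole-cell g_T
    reversal: float = 60.0               # mV
    act_v_half: float = -45.0            # mV
    act_slope: float = 6.0               # mV
    act_tau: float = 3.0                 # ms
    inact_v_half: float = -72.0          # mV
    inact_slope: float = 5.0             # mV
    inact_tau: float = 25.0              # ms

    def __post_init__(self) -> None:
        if self.act_slope <= 0 or self.inact_slope <= 0:
            raise ValueError("slopes must be > 0")
        if self.act_tau <= 0 or self.inact_tau <= 0:
            raise ValueError("taus must be > 0")
        # calibration constraint: full steady-state inactivation at -40 mV
        h40 = 1.0 / (1.0 + np.exp((-40.0 - self.inact_v_half) / self.inact_slope))
        if h40 >= 0.05:
            raise ValueError(
                f"steady-state availability at -40 mV is {h40:.3f}; "
                "a T-type parameter set must satisfy h_inf(-40) < 0.05")


@dataclass(frozen=True)
class CouplingParams:
    """Nanodomain coupling of open Cav3.2 channels to BK channels.

    The local Ca2+ seen by BK channels is algebraic and instantaneous:
    ``ca_bulk + ca_per_open_t_channel * (open T count)``.  In the high-EGTA
    regime (10 mM) the coupling increment is multiplied by
    ``bulk_attenuation_high_egta``; with 0.1 mM EGTA (low regime) it is
    passed through unchanged.
    """

    ca_bulk: float = 10.0                   # nM
    ca_per_open_t_channel: float = 2000.0   # nM per simultaneously open channel
    egta_regime: str = "low"                # "low" (0.1 mM) or "high" (10 mM)
    bulk_attenuation_high_egta: float = 0.05

    def __post_init__(self) -> None:
        if self.ca_per_open_t_channel < 0:
            raise ValueError("ca_per_open_t_channel must be >= 0")
        if self.egta_regime not in ("low", "high"):
            raise ValueError("egta_regime must be 'low' or 'high'")
        if not 0.0 <= self.bulk_attenuation_high_egta <= 1.0:
            raise ValueError("bulk_attenuation_high_egta must lie in [0, 1]")

    @property
    def increment_per_open_channel(self) -> float:
        """Effective nM of local Ca2+ contributed per open T channel."""
        if self.egta_regime == "high":
            return self.ca_per_open_t_channel * self.bulk_attenuation_high_egta
        return self.ca_per_open_t_channel


@dataclass(frozen=True)
class Fura2Calibration:
    """Constants of the ratiometric Fura-2 calibration (R = F340/F380)."""

    r_min: float = 0.3
    r_max: float = 6.0
    kd: float = 224.0   # nM
    beta: float = 5.0   # F380(free) / F380(bound)

    def __post_init__(self) -> None:
        if not self.r_min < self.r_max:
            raise ValueError("r_min must be < r_max")
        if self.kd <= 0 or self.beta <= 0:
            raise ValueError("kd and beta must be > 0")


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class OpenCountSeries:
    """Ground-truth number of simultaneously open channels per sample."""

    sampling_interval: float
    counts: np.ndarray          # int, 0..n_channels
    n_channels: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if self.counts.size and (
                self.counts.min() < 0 or self.counts.max() > self.n_channels):
            raise ValueError("counts must lie in [0, n_channels]")

    def times(self) -> np.ndarray:
        return np.arange(self.counts.size) * self.sampling_interval

    @property
    def open_fraction(self) -> float:
        """Time-averaged fraction of open channels (NPo / N)."""
        if self.n_channels == 0:
            return 0.0
        return float(self.counts.mean() / self.n_channels)


@dataclass
class CurrentTrace:
    """Sampled membrane current (pA, outward positive)."""

    sampling_interval: float
    samples: np.ndarray
    configuration: str = "outside_out"   # whole_cell | outside_out | cell_attached
    protocol: VoltageProtocol | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.configuration not in ("whole_cell", "outside_out", "cell_attached"):
            raise ValueError(f"unknown configuration {self.configuration!r}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")
        if self.protocol is not None and self.samples.size != self.protocol.n_samples:
            raise ValueError(
                f"trace length {self.samples.size} inconsistent with protocol "
                f"({self.protocol.n_samples} samples)")

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.sampling_interval


@dataclass
class Cav32Result:
    trace: CurrentTrace
    m: np.ndarray               # activation gate (deterministic mean)
    h: np.ndarray               # inactivation gate (deterministic mean)
    open_counts: OpenCountSeries | None = None   # single-channel mode only

    @property
    def open_probability(self) -> np.ndarray:
        return self.m ** 2 * self.h


@dataclass
class CoupledPatchResult:
    trace: CurrentTrace
    bk_counts: OpenCountSeries
    t_counts: OpenCountSeries
    local_ca: np.ndarray        # nM, per sample


@dataclass
class PairedSweepSet:
    """Sweeps of the paired HP -80 / HP -40 cell-attached protocol."""

    sweeps_hp80: list[CurrentTrace]
    sweeps_hp40: list[CurrentTrace]
    bk_counts_hp80: np.ndarray   # (n_samples, n_sweeps)
    bk_counts_hp40: np.ndarray
    t_counts_hp80: np.ndarray
    t_counts_hp40: np.ndarray
    protocol: VoltageProtocol
    n_bk: int
    n_t: int
    bk_unitary_amplitude: float = 0.0   # pA at the test potential
    test_potential: float = -20.0


# ---------------------------------------------------------------------------
# closed-form helpers (used both by the simulator and as test oracles)
# ---------------------------------------------------------------------------

def bk_v_half(params: GatingParamsBK, ca: float | np.ndarray) -> np.ndarray:
    """Ca2+-dependent half-activation voltage Vh(Ca), mV."""
    ca = np.asarray(ca, dtype=float)
    if np.any(ca <= 0):
        raise ValueError("Ca2+ concentration must be > 0 nM")
    return params.v_half_ca_ref - params.ca_shift_per_decade * np.log10(ca / params.ca_ref)


def bk_rates(params: GatingParamsBK, v, ca):
    vh = bk_v_half(params, ca)
    x = (np.asarray(v, dtype=float) - vh) / params.voltage_sensitivity
    x = np.clip(x, -60.0, 60.0)
    return params.opening_rate_at_v0 * np.exp(x), params.closing_rate_at_v0 * np.exp(-x)


def bk_stationary_po(params: GatingParamsBK, v, ca):
    """Stationary open probability alpha/(alpha+beta) of the C<->O chain."""
    a, b = bk_rates(params, v, ca)
    return a / (a + b)


def t_gate_steady_state(params: GatingParamsT, v):
    """Steady-state activation m_inf and availability h_inf at voltage v."""
    v = np.asarray(v, dtype=float)
    m = 1.0 / (1.0 + np.exp(-(v - params.act_v_half) / params.act_slope))
    h = 1.0 / (1.0 + np.exp((v - params.inact_v_half) / params.inact_slope))
    return m, h


def unitary_current(gamma_ps: float, v_mv, e_rev_mv: float):
    """Single-channel current in pA: gamma (pS) x driving force (mV)."""
    return gamma_ps * (np.asarray(v_mv, dtype=float) - e_rev_mv) * 1e-3


# ---------------------------------------------------------------------------
# BK stochastic gating
# ---------------------------------------------------------------------------

def _step_two_state(state: np.ndarray, p_open: np.ndarray, p_close: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """One transition step of independent two-state channels (in place)."""
    u = rng.random(state.shape)
    opened = (~state) & (u < p_open)
    closed = state & (u < p_close)
    state[opened] = True
    state[closed] = False
    return state


def _two_state_step_probs(alpha, beta, dt: float):
    """Exact two-state transition probabilities over one step.

    The matrix exponential of the C<->O generator gives
    ``P(C->O) = p_inf * w`` and ``P(O->C) = (1 - p_inf) * w`` with
    ``p_inf = alpha/(alpha+beta)`` and ``w = 1 - exp(-(alpha+beta) dt)``,
    so the chain's stationary distribution is exact at any step size
    (the naive ``1 - exp(-rate dt)`` pair biases it once rate*dt ~ 1).
    """
    total = alpha + beta
    w = -np.expm1(-total * dt)
    p_inf = alpha / total
    return p_inf * w, (1.0 - p_inf) * w


def simulate_gating(params: GatingParamsBK, protocol: VoltageProtocol,
                    ca: float | np.ndarray, n_channels: int,
                    seed: int) -> OpenCountSeries:
    """Simulate ``n_channels`` independent BK channels along a protocol.

    ``ca`` is the local Ca2+ (nM), a scalar or a per-sample series.  The
    channels start from their stationary distribution at the first sample,
    and evolve with the exact two-state transition probabilities for each
    fixed step (see :func:`_two_state_step_probs`).
    """
    if n_channels < 0:
        raise ValueError("n_channels must be >= 0")
    n = protocol.n_samples
    ca_arr = np.broadcast_to(np.asarray(ca, dtype=float), (n,))
    if np.any(ca_arr <= 0):
        raise ValueError("Ca2+ concentration must be > 0 nM")
    counts = np.zeros(n, dtype=np.int64)
    if n_channels == 0:
        return OpenCountSeries(protocol.sampling_interval, counts, 0, seed)

    v = protocol.voltages()
    alpha, beta = bk_rates(params, v, ca_arr)
    dt = protocol.sampling_interval
    p_open, p_close = _two_state_step_probs(alpha, beta, dt)

    rng = np.random.default_rng(seed)
    state = rng.random(n_channels) < (alpha[0] / (alpha[0] + beta[0]))
    counts[0] = state.sum()
    for t in range(1, n):
        _step_two_state(state, p_open[t - 1], p_close[t - 1], rng)
        counts[t] = state.sum()
    return OpenCountSeries(dt, counts, n_channels, seed)


def synthesize_current(openings: OpenCountSeries, unitary_conductance: float,
                       reversal: float, protocol: VoltageProtocol,
                       noise_sd: float = 0.0, seed: int = 0,
                       configuration: str = "outside_out") -> CurrentTrace:
    """Ohmic current from an open-count series plus white Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if openings.counts.size != protocol.n_samples:
        raise ValueError("open-count series length does not match protocol")
    i = unitary_current(unitary_conductance, protocol.voltages(), reversal)
    samples = i * openings.counts
    if noise_sd > 0:
        samples = samples + np.random.default_rng(seed).normal(
            0.0, noise_sd, samples.shape)
    return CurrentTrace(protocol.sampling_interval, samples, configuration, protocol)


# ---------------------------------------------------------------------------
# Cav3.2 simulation
# ---------------------------------------------------------------------------

def _integrate_t_gates(params: GatingParamsT, protocol: VoltageProtocol):
    """Deterministic exponential-Euler integration of m and h.

    Gates start at their steady state for the first segment level, which
    stands in for an arbitrarily long conditioning at that potential.
    """
    v = protocol.voltages()
    m_inf, h_inf = t_gate_steady_state(params, v)
    dt = protocol.sampling_interval
    km = 1.0 - np.exp(-dt / params.act_tau)
    kh = 1.0 - np.exp(-dt / params.inact_tau)
    m = np.empty_like(m_inf)
    h = np.empty_like(h_inf)
    m[0], h[0] = m_inf[0], h_inf[0]
    for t in range(1, v.size):
        m[t] = m[t - 1] + (m_inf[t] - m[t - 1]) * km
        h[t] = h[t - 1] + (h_inf[t] - h[t - 1]) * kh
    return m, h


def _stochastic_t_counts(params: GatingParamsT, protocol: VoltageProtocol,
                         n_channels: int, rng: np.random.Generator,
                         shape_extra: tuple[int, ...] = ()) -> np.ndarray:
    """Stochastic m^2 h channel openings as three independent binary gates.

    Each channel carries two activation gates (open rate m_inf/tau_m,
    close rate (1-m_inf)/tau_m) and one inactivation gate, so the ensemble
    open fraction relaxes to m_inf^2 h_inf exactly.  Returns the per-sample
    open-channel count with shape ``(n_samples, *shape_extra)``.
    """
    n = protocol.n_samples
    v = protocol.voltages()
    m_inf, h_inf = t_gate_steady_state(params, v)
    dt = protocol.sampling_interval
    # exact per-step flip probabilities for binary gates relaxing to x_inf
    # with time constant tau (on rate x_inf/tau, off rate (1-x_inf)/tau)
    wm = -np.expm1(-dt / params.act_tau)
    wh = -np.expm1(-dt / params.inact_tau)
    p_m_on, p_m_off = m_inf * wm, (1.0 - m_inf) * wm
    p_h_on, p_h_off = h_inf * wh, (1.0 - h_inf) * wh

    shape = shape_extra + (n_channels,)
    m1 = rng.random(shape) < m_inf[0]
    m2 = rng.random(shape) < m_inf[0]
    hg = rng.random(shape) < h_inf[0]
    counts = np.zeros((n,) + shape_extra, dtype=np.int64)
    counts[0] = (m1 & m2 & hg).sum(axis=-1)
    for t in range(1, n):
        _step_two_state(m1, p_m_on[t - 1], p_m_off[t - 1], rng)
        _step_two_state(m2, p_m_on[t - 1], p_m_off[t - 1], rng)
        _step_two_state(hg, p_h_on[t - 1], p_h_off[t - 1], rng)
        counts[t] = (m1 & m2 & hg).sum(axis=-1)
    return counts


def simulate_cav32(params: GatingParamsT, protocol: VoltageProtocol,
                   mode: str = "macroscopic", seed: int = 0,
                   n_channels: int = 1, noise_sd: float = 0.0) -> Cav32Result:
    """Simulate a Cav3.2 current along a protocol.

    ``macroscopic`` mode integrates dm/dt and dh/dt and emits
    ``I = g * m^2 h * (V - E_rev)`` (nS x mV = pA, inward negative below
    the reversal).  ``single_channel`` mode draws stochastic gate openings
    and emits the unitary ohmic current.
    """
    m, h = _integrate_t_gates(params, protocol)
    v = protocol.voltages()
    if mode == "macroscopic":
        samples = params.macroscopic_conductance * m ** 2 * h * (v - params.reversal)
        if noise_sd > 0:
            samples = samples + np.random.default_rng(seed).normal(
                0.0, noise_sd, samples.shape)
        trace = CurrentTrace(protocol.sampling_interval, samples,
                             "whole_cell", protocol)
        return Cav32Result(trace, m, h)
    if mode == "single_channel":
        rng = np.random.default_rng(seed)
        counts = _stochastic_t_counts(params, protocol, n_channels, rng)
        series = OpenCountSeries(protocol.sampling_interval, counts,
                                 n_channels, seed)
        trace = synthesize_current(series, params.unitary_conductance,
                                   params.reversal, protocol, noise_sd,
                                   seed + 1, "cell_attached")
        return Cav32Result(trace, m, h, series)
    raise ValueError("mode must be 'macroscopic' or 'single_channel'")


# ---------------------------------------------------------------------------
# coupled BK / Cav3.2 patch
# ---------------------------------------------------------------------------

def simulate_coupled_ensemble(bk: GatingParamsBK, t: GatingParamsT,
                              coupling: CouplingParams, n_bk: int, n_t: int,
                              protocol: VoltageProtocol, n_sweeps: int,
                              seed: int):
    """Vectorized ensemble of independent coupled patches.

    At every time step the local Ca2+ seen by the patch's BK channels is
    ``ca_bulk + increment * (open T count)`` (increment attenuated in the
    high-EGTA regime); the BK transition rates for the next step are
    evaluated at that local Ca2+.  Returns
    ``(bk_counts, t_counts, local_ca)`` with shape ``(n_samples, n_sweeps)``.
    """
    if n_bk < 0 or n_t < 0:
        raise ValueError("channel counts must be >= 0")
    n = protocol.n_samples
    v = protocol.voltages()
    dt = protocol.sampling_interval
    rng = np.random.default_rng(seed)

    # --- T channels: three binary gates per channel --------------------
    if n_t > 0:
        t_counts = _stochastic_t_counts(t, protocol, n_t, rng, (n_sweeps,))
    else:
        t_counts = np.zeros((n, n_sweeps), dtype=np.int64)

    local_ca = coupling.ca_bulk + coupling.increment_per_open_channel * t_counts

    # --- BK channels driven by the per-sweep local Ca ------------------
    bk_counts = np.zeros((n, n_sweeps), dtype=np.int64)
    if n_bk > 0:
        a0, b0 = bk_rates(bk, v[0], local_ca[0])          # (n_sweeps,)
        state = rng.random((n_sweeps, n_bk)) < (a0 / (a0 + b0))[:, None]
        bk_counts[0] = state.sum(axis=1)
        for k in range(1, n):
            a, b = bk_rates(bk, v[k - 1], local_ca[k - 1])
            p_open, p_close = _two_state_step_probs(a, b, dt)
            _step_two_state(state, p_open[:, None], p_close[:, None], rng)
            bk_counts[k] = state.sum(axis=1)
    return bk_counts, t_counts, local_ca


def simulate_coupled_patch(bk: GatingParamsBK, t: GatingParamsT,
                           coupling: CouplingParams, n_bk: int, n_t: int,
                           protocol: VoltageProtocol, seed: int,
                           noise_sd: float = 0.0) -> CoupledPatchResult:
    """Single coupled patch: composite BK + Cav3.2 current with ground truth."""
    bk_c, t_c, ca = simulate_coupled_ensemble(
        bk, t, coupling, n_bk, n_t, protocol, 1, seed)
    bk_series = OpenCountSeries(protocol.sampling_interval, bk_c[:, 0],
                                max(n_bk, 1) if n_bk else 0, seed)
    t_series = OpenCountSeries(protocol.sampling_interval, t_c[:, 0],
                               max(n_t, 1) if n_t else 0, seed)
    v = protocol.voltages()
    samples = (unitary_current(bk.unitary_conductance, v, bk.reversal) * bk_c[:, 0]
               + unitary_current(t.unitary_conductance, v, t.reversal) * t_c[:, 0])
    if noise_sd > 0:
        samples = samples + np.random.default_rng(seed + 1).normal(
            0.0, noise_sd, samples.shape)
    trace = CurrentTrace(protocol.sampling_interval, samples,
                         "cell_attached", protocol)
    return CoupledPatchResult(trace, bk_series, t_series, ca[:, 0])


def run_paired_hp_protocol(bk: GatingParamsBK, t: GatingParamsT,
                           coupling: CouplingParams, n_bk: int = 4,
                           n_t: int = 4, test_potential: float = -20.0,
                           test_duration: float = 500.0,
                           pre_duration: float = 20.0,
                           dt: float = DEFAULT_DT, n_sweeps: int = 500,
                           seed: int = 0, noise_sd: float = 0.0,
                           t_reversal_cell_attached: float = 120.0,
                           bk_reversal_cell_attached: float = -86.5) -> PairedSweepSet:
    """Paired cell-attached protocol: HP -80 -> test, then HP -40 -> test.

    Each arm starts from the gating steady state at its holding potential,
    which stands in for the 10 s conditioning of the recorded protocol
    (at -40 mV the T availability has already collapsed, h_inf < 0.002).
    With ~100 mM external divalent in the pipette the unitary T current
    reversal sits near +120 mV, giving ~1 pA unitary current at -20 mV;
    the 5/150 mM K+ gradient across the patch puts the BK reversal near
    the K+ Nernst potential of -86.5 mV, so BK openings are large outward
    events at the test potential.
    """
    t_ca = replace(t, reversal=t_reversal_cell_attached)
    bk_ca = replace(bk, reversal=bk_reversal_cell_attached)
    seeds = np.random.SeedSequence(seed).spawn(4)
    out: dict[float, tuple] = {}
    for hp, ss in zip((-80.0, -40.0), seeds[:2]):
        proto = step_protocol(hp, test_potential, pre=pre_duration,
                              duration=test_duration, dt=dt,
                              label=f"HP {hp:g} mV")
        bk_c, t_c, _ = simulate_coupled_ensemble(
            bk_ca, t_ca, coupling, n_bk, n_t, proto, n_sweeps,
            int(ss.generate_state(1)[0] % 2**31))
        v = proto.voltages()
        i = (unitary_current(bk_ca.unitary_conductance, v,
                             bk_ca.reversal)[:, None] * bk_c
             + unitary_current(t_ca.unitary_conductance, v,
                               t_ca.reversal)[:, None] * t_c)
        if noise_sd > 0:
            nrng = np.random.default_rng(int(ss.generate_state(2)[1] % 2**31))
            i = i + nrng.normal(0.0, noise_sd, i.shape)
        sweeps = [CurrentTrace(dt, i[:, j], "cell_attached", proto)
                  for j in range(n_sweeps)]
        out[hp] = (sweeps, bk_c, t_c, proto)
    amp = float(unitary_current(bk_ca.unitary_conductance, test_potential,
                                bk_ca.reversal))
    return PairedSweepSet(out[-80.0][0], out[-40.0][0],
                          out[-80.0][1], out[-40.0][1],
                          out[-80.0][2], out[-40.0][2],
                          out[-80.0][3], n_bk, n_t, amp, test_potential)


# ---------------------------------------------------------------------------
# patch occupancy sampling
# ---------------------------------------------------------------------------

def sample_patch_counts(n_channels: int, membrane_area: float,
                        patch_area: float, placement: str = "uniform",
                        n_patches: int = 1, seed: int = 0,
                        cluster_rate: float | None = None,
                        mean_cluster_size: float | None = None):
    """Sample per-patch channel counts under a placement model.

    ``uniform`` places every channel independently and uniformly on the
    membrane, so a patch of area x on a membrane of area y sees
    ``Binomial(n_channels, x/y)`` channels.  ``clustered`` draws cluster
    centres as a Poisson process with intensity ``cluster_rate`` (per um^2)
    and ``Poisson(mean_cluster_size)`` channels per cluster, all of which
    fall inside one patch footprint together.

    Returns a :class:`bkcav.cluster_stats.PatchCountTable`.
    """
    from .cluster_stats import PatchCountTable

    if patch_area <= 0 or membrane_area <= 0 or patch_area > membrane_area:
        raise ValueError("need 0 < patch_area <= membrane_area")
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    if n_channels < 0:
        raise ValueError("n_channels must be >= 0")
    rng = np.random.default_rng(seed)
    if placement == "uniform":
        counts = rng.binomial(n_channels, patch_area / membrane_area,
                              size=n_patches)
    elif placement == "clustered":
        if cluster_rate is None or mean_cluster_size is None:
            raise ValueError(
                "clustered placement needs cluster_rate and mean_cluster_size")
        n_clusters = rng.poisson(cluster_rate * patch_area, size=n_patches)
        counts = np.array([
            rng.poisson(mean_cluster_size, size=k).sum() if k else 0
            for k in n_clusters], dtype=np.int64)
    else:
        raise ValueError("placement must be 'uniform' or 'clustered'")
    return PatchCountTable(counts, patch_area)


# ---------------------------------------------------------------------------
# Fura-2 ratio synthesis
# ---------------------------------------------------------------------------

def simulate_fura2(ca: np.ndarray, calibration: Fura2Calibration,
                   noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Fluorescence ratio R = F340/F380 for a Ca2+ series (nM).

    The mapping ``R = (Rmin + (Ca/(Kd*beta))*Rmax) / (1 + Ca/(Kd*beta))``
    is the exact algebraic inverse of the ratiometric conversion in
    :func:`bkcav.calcium_tools.grynkiewicz`: R(0) = Rmin and R -> Rmax as
    Ca -> infinity.
    """
    ca = np.asarray(ca, dtype=float)
    if np.any(ca < 0):
        raise ValueError("Ca2+ concentrations must be >= 0")
    x = ca / (calibration.kd * calibration.beta)
    r = (calibration.r_min + x * calibration.r_max) / (1.0 + x)
    if noise_sd > 0:
        r = r + np.random.default_rng(seed).normal(0.0, noise_sd, r.shape)
    return r
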