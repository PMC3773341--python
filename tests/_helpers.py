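"""Shared test utilities: generators for fitted scenarios and oracles."""

from __future__ import annotations

import numpy as np

from bkcav import iv_analysis
from bkcav.sim_channels import (GatingParamsBK, VoltageProtocol,
                                simulate_gating, synthesize_current,
                                unitary_current)

# fast-flicker BK variant: convenient dwell times for idealization and
# amplitude-estimation scenarios (stationary curve identical to default)
FAST_BK = GatingParamsBK(opening_rate_at_v0=0.5, closing_rate_at_v0=0.5)


def simulated_single_channel_iv(gamma: float, e_rev: float,
                                voltages, ca: float = 1e4,
                                n_sweeps: int = 50, sweep_ms: float = 100.0,
                                noise_sd: float = 1.0, seed: int = 0,
                                dt: float = 0.1) -> iv_analysis.IVCurve:
    """Measured unitary-current i-v from simulated noisy sweeps.

    At each potential the unitary amplitude is estimated as the mean
    current over the ground-truth open samples minus the mean over the
    closed samples (the closed-level baseline), averaged across sweeps —
    the standard amplitude readout of a single-channel i-v.  A high local
    Ca2+ keeps the channel active at every potential.
    """
    params = GatingParamsBK(
        unitary_conductance=gamma, reversal=e_rev,
        opening_rate_at_v0=0.5, closing_rate_at_v0=0.5)
    rng_seeds = np.random.SeedSequence(seed).generate_state(
        2 * len(list(voltages)) * n_sweeps).astype(np.int64)
    vs, amps, ns, sems = [], [], [], []
    k = 0
    for v in voltages:
        proto = VoltageProtocol(((float(v), sweep_ms),), dt)
        est = []
        for _ in range(n_sweeps):
            ser = simulate_gating(params, proto, ca, 1, int(rng_seeds[k]))
            tr = synthesize_current(ser, gamma, e_rev, proto, noise_sd,
                                    int(rng_seeds[k + 1]))
            k += 2
            open_mask = ser.counts > 0
            if open_mask.any() and (~open_mask).any():
                est.append(tr.samples[open_mask].mean()
                           - tr.samples[~open_mask].mean())
            elif open_mask.any():
                est.append(tr.samples[open_mask].mean())
        est = np.asarray(est)
        vs.append(float(v))
        amps.append(est.mean())
        ns.append(est.size)
        sems.append(est.std(ddof=1) / np.sqrt(est.size))
    return iv_analysis.IVCurve(np.array(vs), np.array(amps),
                               np.array(ns), np.array(sems))


def henderson_integral_oracle(pipette, bath, temperature=295.0) -> float:
    """Independent junction-potential oracle by numerical path integration.

    Integrates the diffusion-potential ODE
    ``dphi = -(RT/F) * (sum_i z_i u_i dc_i) / (sum_i z_i^2 u_i c_i)``
    along the linear mixture path from the pipette to the bath
    composition — the assumption under which the closed-form expression
    is exact — using fine trapezoidal quadrature.
    """
    ions = {}
    for sol in (pipette, bath):
        for s in sol.species:
            ions[s.name] = (s.valence, s.limiting_equivalent_conductance)
    names = sorted(ions)
    z = np.array([ions[n][0] for n in names], dtype=float)
    u = np.array([ions[n][1] for n in names]) / np.abs(z)
    cp = np.array([pipette.concentration_of(n) for n in names])
    cb = np.array([bath.concentration_of(n) for n in names])
    x = np.linspace(0.0, 1.0, 20001)
    c = cp[None, :] + x[:, None] * (cb - cp)[None, :]
    dc = (cb - cp)[None, :]
    integrand = (z * u * dc).sum(axis=1) / (z * z * u * c).sum(axis=1)
    rt_f = 8.31446261815324 * temperature / 96485.33212 * 1e3
    return float(-rt_f * np.trapezoid(integrand, x))


def fisher_enumeration_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive two-sided Fisher p over all tables with fixed margins."""
    from math import comb

    n = a + b + c + d
    r1, c1 = a + b, a + c

    def prob(x):
        return (comb(r1, x) * comb(n - r1, c1 - x)) / comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-9))
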