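"""Liquid junction potentials and the resting-membrane-potential model.

Two jobs live here.  First, the generalized Henderson equation over an
arbitrary ion list (with a pinned table of limiting equivalent
conductances) computes liquid junction potentials, the LJP change on a
bath exchange, and the corrected resting membrane potential
``RMP = recorded - LJP``.  Second, a steady-state whole-cell conductance
model — Ca2+- and voltage-dependent BK activation, a T-type window
conductance coupled to BK through nanodomain Ca2+, and an ohmic leak —
finds the zero-current membrane potentials and demonstrates how the
BK/Cav3.2 feedback loop parks the resting potential near the optimum of
the T-type window current: hyperpolarization closes T channels, the local
Ca2+ seen by BK falls, BK deactivates and the membrane depolarizes back;
depolarization inactivates T channels with the same restoring effect.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import optimize

from .sim_channels import (CouplingParams, GatingParamsBK, GatingParamsT,
                           bk_stationary_po, t_gate_steady_state)

__all__ = [
    "IonSpecies",
    "SolutionSpec",
    "MembraneModel",
    "MOBILITY_TABLE",
    "henderson_ljp",
    "bath_exchange_ljp_change",
    "correct_rmp",
    "window_current",
    "steady_state_rmp",
    "rmp_perturbation",
    "standard_pipette",
    "hbss_bath",
    "high_k_bath",
    "ctl_model",
    "ne_model",
    "a1h_model",
]

GAS_CONSTANT = 8.31446261815324
FARADAY = 96485.33212
DEFAULT_TEMPERATURE = 295.0


def _load_mobility_table() -> dict[str, tuple[int, float]]:
    """Pinned limiting equivalent conductances (S cm^2 eq^-1) by ion name."""
    table: dict[str, tuple[int, float]] = {}
    path = resources.files("bkcav").joinpath("data/mobilities.csv")
    with path.open() as fh:
        for row in csv.DictReader(fh):
            table[row["ion"]] = (int(row["valence"]),
                                 float(row["limiting_equivalent_conductance"]))
    return table


MOBILITY_TABLE = _load_mobility_table()


@dataclass(frozen=True)
class IonSpecies:
    name: str
    concentration: float        # mM
    valence: int
    limiting_equivalent_conductance: float   # S cm^2 eq^-1

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.valence == 0:
            raise ValueError("valence must be nonzero")
        if self.limiting_equivalent_conductance <= 0:
            raise ValueError("limiting conductance must be > 0")


@dataclass
class SolutionSpec:
    """Ionic composition of a solution for Nernst/Henderson computations."""

    species: list[IonSpecies]
    label: str = ""

    def __post_init__(self) -> None:
        if not any(s.valence > 0 and s.concentration > 0 for s in self.species):
            raise ValueError("solution needs at least one cation")
        if not any(s.valence < 0 and s.concentration > 0 for s in self.species):
            raise ValueError("solution needs at least one anion")

    @classmethod
    def from_concentrations(cls, conc: dict[str, float],
                            label: str = "") -> "SolutionSpec":
        """Build a spec from ``{ion name: mM}`` using the pinned table."""
        species = []
        for name, c in conc.items():
            if name not in MOBILITY_TABLE:
                raise KeyError(
                    f"ion {name!r} is not in the pinned mobility table")
            z, lam = MOBILITY_TABLE[name]
            species.append(IonSpecies(name, c, z, lam))
        return cls(species, label)

    @property
    def charge_imbalance(self) -> float:
        """Net charge (mEq) of the stated composition; bookkeeping only."""
        return sum(s.valence * s.concentration for s in self.species)

    def concentration_of(self, name: str) -> float:
        return sum(s.concentration for s in self.species if s.name == name)


# ---------------------------------------------------------------------------
# Henderson liquid junction potential
# ---------------------------------------------------------------------------

def henderson_ljp(pipette: SolutionSpec, bath: SolutionSpec,
                  temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Generalized Henderson junction potential, bath relative to pipette (mV).

    Ion mobilities are ``lambda_i / |z_i|`` from each species' limiting
    equivalent conductance.  A K-gluconate pipette against a NaCl-rich
    bath gives a positive value of roughly +10 to +15 mV (the mobile K+
    outruns the sluggish gluconate, charging the bath side positive),
    matching the convention of the standard junction-potential software.
    Concentrations are used as activities.
    """
    ions: dict[str, tuple[int, float]] = {}
    for sol in (pipette, bath):
        for s in sol.species:
            prev = ions.get(s.name)
            if prev is not None and prev != (s.valence,
                                             s.limiting_equivalent_conductance):
                raise ValueError(f"inconsistent parameters for ion {s.name!r}")
            ions[s.name] = (s.valence, s.limiting_equivalent_conductance)
    num = den = s_p = s_b = 0.0
    for name, (z, lam) in ions.items():
        u = lam / abs(z)
        cp = pipette.concentration_of(name)
        cb = bath.concentration_of(name)
        num += z * u * (cb - cp)
        den += z * z * u * (cb - cp)
        s_p += z * z * u * cp
        s_b += z * z * u * cb
    rt_f = GAS_CONSTANT * temperature / FARADAY * 1e3   # mV
    if s_p <= 0 or s_b <= 0:
        raise ValueError("solutions must have positive ionic strength")
    if den == 0.0:
        return 0.0
    return float(-rt_f * (num / den) * np.log(s_b / s_p))


def bath_exchange_ljp_change(bath_old: SolutionSpec, bath_new: SolutionSpec,
                             temperature: float = DEFAULT_TEMPERATURE) -> float:
    """LJP variation (mV) when the bath is exchanged during a recording.

    With the pipette sealed to the cell and the junction zeroed in the
    original bath, the offset that appears on perfusing a new bath is the
    Henderson potential of the new solution against the old one — the
    junction that physically forms at the (uncorrected) reference
    electrode.  Exchanging a 145 mM Na+ / 5 mM K+ bath for a
    0 mM Na+ / 150 mM K+ bath at constant chloride gives about -4 mV.
    """
    return henderson_ljp(bath_old, bath_new, temperature)


def correct_rmp(recorded: float, ljp: float) -> float:
    """Junction-corrected membrane potential: recorded minus LJP (mV)."""
    if not (np.isfinite(recorded) and np.isfinite(ljp)):
        raise ValueError("inputs must be finite")
    return recorded - ljp


# --- the recorded solutions ------------------------------------------------
# HEPES is carried at 50% of its nominal concentration as the anion, its
# approximate ionization at pH 7.2-7.4.

def standard_pipette() -> SolutionSpec:
    """Whole-cell pipette: 130 K-gluconate, 10 NaCl, 10 HEPES, 1 MgCl2."""
    return SolutionSpec.from_concentrations(
        {"K": 130.0, "Gluconate": 130.0, "Na": 10.0, "Cl": 12.0,
         "Mg": 1.0, "HEPES": 5.0}, label="K-gluconate pipette")


def hbss_bath() -> SolutionSpec:
    """Standard bath (HBSS-like): 145 Na+, 5 K+, constant Cl-."""
    return SolutionSpec.from_concentrations(
        {"Na": 145.0, "K": 5.0, "Cl": 156.0, "Mg": 1.0, "Ca": 2.0,
         "HEPES": 5.0}, label="standard bath (145 Na / 5 K)")


def high_k_bath() -> SolutionSpec:
    """Potassium-substituted bath: 0 Na+, 150 K+, chloride unchanged."""
    return SolutionSpec.from_concentrations(
        {"Na": 0.0, "K": 150.0, "Cl": 156.0, "Mg": 1.0, "Ca": 2.0,
         "HEPES": 5.0}, label="high-K bath (0 Na / 150 K)")


# ---------------------------------------------------------------------------
# steady-state whole-cell model
# ---------------------------------------------------------------------------

@dataclass
class MembraneModel:
    """Steady-state whole-cell conductance model.

    BK activation is the stationary Boltzmann of the gating parameters at
    the local Ca2+; the T-type conductance contributes its steady window
    current ``g_t * m_inf^2 h_inf * (V - e_ca)``; the leak is ohmic.  The
    local Ca2+ seen by BK follows the nanodomain coupling rule evaluated
    at the expected number of open T channels,
    ``ca_bulk + increment * (g_t/gamma_T) * m_inf^2 h_inf``.
    """

    capacitance: float = 65.0           # pF
    g_bk_max: float = 1.8               # nS
    g_t_max: float = 0.0                # nS
    g_leak: float = 0.5                 # nS
    e_k: float = -81.0                  # mV, from tail-current reversals
    e_ca: float = 60.0                  # mV
    e_leak: float = 0.0                 # mV, nonselective background
    bk_params: GatingParamsBK = field(default_factory=GatingParamsBK)
    t_gates: GatingParamsT = field(default_factory=GatingParamsT)
    coupling: CouplingParams = field(default_factory=lambda: CouplingParams(
        ca_bulk=100.0))

    def __post_init__(self) -> None:
        if min(self.g_bk_max, self.g_t_max, self.g_leak) < 0:
            raise ValueError("conductances must be >= 0")
        if self.capacitance <= 0:
            raise ValueError("capacitance must be > 0")

    @property
    def n_t_channels(self) -> float:
        """Expected T channel count behind g_t_max at the unitary conductance."""
        return self.g_t_max * 1e3 / self.t_gates.unitary_conductance

    def local_ca(self, v) -> np.ndarray:
        m, h = t_gate_steady_state(self.t_gates, v)
        open_t = self.n_t_channels * m ** 2 * h
        return self.coupling.ca_bulk + \
            self.coupling.increment_per_open_channel * open_t

    def total_current(self, v) -> np.ndarray:
        """Steady net membrane current (pA, outward positive) at voltage v."""
        v = np.asarray(v, dtype=float)
        po = bk_stationary_po(self.bk_params, v, self.local_ca(v))
        i_bk = self.g_bk_max * po * (v - self.e_k)
        m, h = t_gate_steady_state(self.t_gates, v)
        i_t = self.g_t_max * m ** 2 * h * (v - self.e_ca)
        i_leak = self.g_leak * (v - self.e_leak)
        return i_bk + i_t + i_leak


def window_current(t: GatingParamsT, g_t_max: float, e_ca: float,
                   v_grid) -> np.ndarray:
    """Steady T-type window current ``g m_inf^2 h_inf (V - e_ca)`` (pA).

    Nonzero only where the activation and availability curves overlap
    (roughly -60 to -25 mV for the default gates); identically small at a
    sustained -40 mV because h_inf(-40) < 0.05.
    """
    m, h = t_gate_steady_state(t, v_grid)
    return g_t_max * m ** 2 * h * (np.asarray(v_grid, dtype=float) - e_ca)


def steady_state_rmp(model: MembraneModel,
                     v_range: tuple[float, float] = (-100.0, 20.0),
                     grid_step: float = 0.05) -> list[float]:
    """All stable zero-current potentials of the model, ascending (mV).

    Roots are bracketed on a fine grid and refined by Brent's method; a
    root is stable when the net current-voltage slope there is positive
    (net outward current above, net inward below).  Multiple stable roots
    (bistability) are all returned, never collapsed.
    """
    v = np.arange(v_range[0], v_range[1] + grid_step / 2, grid_step)
    i = model.total_current(v)
    roots: list[float] = []
    sign = np.sign(i)
    for k in np.flatnonzero(np.diff(sign) != 0):
        if sign[k] == 0:
            continue
        r = optimize.brentq(lambda x: float(model.total_current(x)),
                            v[k], v[k + 1], xtol=1e-8)
        roots.append(float(r))
    for k in np.flatnonzero(sign == 0):
        roots.append(float(v[k]))
    if not roots:
        raise ValueError("no zero-current potential in the search range")
    eps = 1e-4
    stable = [r for r in sorted(set(roots))
              if model.total_current(r + eps) > model.total_current(r - eps)]
    if not stable:
        raise ValueError("no stable zero-current potential in the search range")
    return stable


def rmp_perturbation(model: MembraneModel, conductance: str,
                     scale: float) -> float:
    """RMP shift (mV) when one conductance is scaled by ``scale``.

    ``conductance`` is one of ``g_bk_max``, ``g_t_max``, ``g_leak``.  The
    baseline is the most negative stable root; the perturbed state is the
    stable root nearest the baseline (continuation of the physiological
    state).  Positive return = depolarization.
    """
    if conductance not in ("g_bk_max", "g_t_max", "g_leak"):
        raise ValueError(f"unknown conductance {conductance!r}")
    if scale < 0:
        raise ValueError("scale must be >= 0")
    base = steady_state_rmp(model)[0]
    kwargs = {f.name: getattr(model, f.name)
              for f in model.__dataclass_fields__.values()}
    kwargs[conductance] = kwargs[conductance] * scale
    perturbed_model = MembraneModel(**kwargs)
    try:
        roots = steady_state_rmp(perturbed_model)
    except ValueError as exc:
        raise ValueError(
            f"stable root disappeared under {conductance} x {scale}") from exc
    nearest = min(roots, key=lambda r: abs(r - base))
    return nearest - base


# --- calibrated cell-line models -------------------------------------------
# Conductances are calibrated so the no-T model rests near -32 mV, a
# moderate T conductance (endogenous Cav3.2) rests near -41 mV and a large
# T conductance (Cav3.2 overexpression) near -55 mV, reproducing the
# strict ordering CTL > NE > alpha1H of the recorded lines.

def ctl_model(egta_regime: str = "low") -> MembraneModel:
    """Control-like cell: BK + leak, no functional T-type conductance."""
    return MembraneModel(g_t_max=0.0, coupling=CouplingParams(
        ca_bulk=100.0, ca_per_open_t_channel=2000.0, egta_regime=egta_regime))


def ne_model(egta_regime: str = "low") -> MembraneModel:
    """Neuroendocrine-like cell: moderate endogenous Cav3.2 conductance."""
    return MembraneModel(g_t_max=0.5, coupling=CouplingParams(
        ca_bulk=100.0, ca_per_open_t_channel=2000.0, egta_regime=egta_regime))


def a1h_model(egta_regime: str = "low") -> MembraneModel:
    """Cav3.2-overexpressing cell: large T-type conductance."""
    return MembraneModel(g_t_max=3.0, coupling=CouplingParams(
        ca_bulk=100.0, ca_per_open_t_channel=2000.0, egta_regime=egta_regime))
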