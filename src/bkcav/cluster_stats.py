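"""Cluster-size statistics of channels counted in membrane patches.

A patch pipette samples a small area x of a membrane of area y carrying n
channels.  If channels are placed independently and uniformly, the number
of channels seen in one patch is Binomial(n, x/y) — for large n at fixed
mean occupancy lambda = n*x/y, Poisson(lambda).  This module turns
per-patch channel counts into the channel-weighted cluster-size
distribution ("what fraction of all channels sit in a patch of k
channels"), evaluates the uniform-placement null in closed form, measures
tail fractions (e.g. the proportion of channels in clusters of >= 6),
tests observed tables against the null by parametric Monte Carlo, applies
Fisher's exact test to 2x2 contingency tables, and converts mean
channels-per-patch into a membrane density and whole-cell channel count
via the specific membrane capacitance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PatchCountTable",
    "ClusterDistribution",
    "PlacementNullParams",
    "channel_weighted_distribution",
    "binomial_null",
    "tail_fraction",
    "clustering_test",
    "fisher_exact_2x2",
    "density_and_total",
    "SPECIFIC_CAPACITANCE",
]

# specific membrane capacitance, pF per um^2 (the classic 1 uF/cm^2)
SPECIFIC_CAPACITANCE = 0.01


@dataclass
class PatchCountTable:
    """Channels-per-patch counts for a set of equal-area patches."""

    counts: np.ndarray
    patch_area: float = 2.0   # um^2, from the patch-pipette tip size

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.size < 1:
            raise ValueError("need at least one patch")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")
        if self.patch_area <= 0:
            raise ValueError("patch_area must be > 0")

    @property
    def n_patches(self) -> int:
        return int(self.counts.size)

    @property
    def total_channels(self) -> int:
        return int(self.counts.sum())

    @property
    def mean_per_patch(self) -> float:
        return float(self.counts.mean())


@dataclass
class ClusterDistribution:
    """Channel-weighted cluster-size distribution over k >= 1.

    ``channel_weighted_proportion[j]`` is the fraction of all channels
    that lie in a patch of exactly ``k_values[j]`` channels; it sums to 1.
    ``empty_patch_fraction`` is the fraction of patches with no channel.
    """

    k_values: np.ndarray
    channel_weighted_proportion: np.ndarray
    empty_patch_fraction: float

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=np.int64)
        self.channel_weighted_proportion = np.asarray(
            self.channel_weighted_proportion, dtype=float)
        if np.any(self.k_values < 1):
            raise ValueError("k_values must be >= 1")
        p = self.channel_weighted_proportion
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be >= 0 and sum to 1")

    def proportion_at(self, k: int) -> float:
        hit = self.k_values == k
        return float(self.channel_weighted_proportion[hit].sum())


@dataclass
class PlacementNullParams:
    """Uniform-placement null: n channels on area y sampled with patches x.

    Either give ``n_total`` with the two areas (occupancy is exactly
    Binomial(n_total, x/y)) or give ``mean_occupancy`` directly (occupancy
    is Poisson(lambda), the large-n limit).
    """

    n_total: int | None = None
    patch_area: float = 2.0
    membrane_area: float = 6500.0
    mean_occupancy: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.patch_area <= self.membrane_area:
            raise ValueError("need 0 < patch_area <= membrane_area")
        if self.mean_occupancy is None:
            if self.n_total is None or self.n_total < 0:
                raise ValueError("give n_total >= 0 or mean_occupancy")
        elif self.mean_occupancy <= 0:
            raise ValueError("mean_occupancy must be > 0")

    @property
    def occupancy_mean(self) -> float:
        if self.mean_occupancy is not None:
            return float(self.mean_occupancy)
        return self.n_total * self.patch_area / self.membrane_area

    def occupancy_pmf(self, k: np.ndarray) -> np.ndarray:
        """pmf of the patch occupancy K under the null."""
        if self.mean_occupancy is not None:
            return stats.poisson.pmf(k, self.mean_occupancy)
        return stats.binom.pmf(k, self.n_total,
                               self.patch_area / self.membrane_area)


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------

def channel_weighted_distribution(table: PatchCountTable) -> ClusterDistribution:
    """Empirical channel-weighted cluster-size distribution.

    proportion(k) = k * (#patches with count k) / (total channels); the
    fraction of empty patches is reported separately.
    """
    total = table.total_channels
    if total == 0:
        raise ValueError("all counts are zero; distribution undefined")
    occ = np.bincount(table.counts)
    k = np.arange(occ.size)
    weighted = k * occ / total
    keep = (k >= 1) & (occ > 0)
    return ClusterDistribution(k[keep], weighted[keep],
                               float(occ[0] / table.n_patches))


def binomial_null(params: PlacementNullParams,
                  k_max: int | None = None) -> ClusterDistribution:
    """Closed-form channel-weighted distribution of the placement null.

    Occupancy K is Binomial(n, x/y) (or Poisson(lambda)); the probability
    that a channel lies in a patch of k channels is k*P(K=k)/E[K].
    ``k_max`` must leave tail mass below 1e-9 (chosen automatically when
    omitted).
    """
    lam = params.occupancy_mean
    if lam <= 0:
        raise ValueError("null mean occupancy must be > 0")
    if k_max is None:
        k_max = int(stats.poisson.ppf(1.0 - 1e-12, lam)) + 20
    k = np.arange(k_max + 1)
    pmf = params.occupancy_pmf(k)
    weighted = k * pmf
    norm = weighted.sum()
    tail_mass = 1.0 - pmf.sum()
    if tail_mass > 1e-9:
        raise ValueError(f"k_max={k_max} leaves occupancy tail mass "
                         f"{tail_mass:.2e} > 1e-9")
    return ClusterDistribution(k[1:], weighted[1:] / norm, float(pmf[0]))


def tail_fraction(dist: ClusterDistribution, k_min: int) -> float:
    """Percentage of channels in clusters of ``k_min`` channels or more."""
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    mask = dist.k_values >= k_min
    return 100.0 * float(dist.channel_weighted_proportion[mask].sum())


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def _weighted_vector(counts: np.ndarray, k_max: int) -> np.ndarray:
    """Channel-weighted proportions over k = 1..k_max (tail lumped at k_max)."""
    counts = np.minimum(counts, k_max)
    occ = np.bincount(counts, minlength=k_max + 1)
    k = np.arange(k_max + 1)
    w = (k * occ).astype(float)
    total = w.sum()
    return w[1:] / total


def clustering_test(observed: PatchCountTable, null: PlacementNullParams,
                    n_boot: int = 999, seed: int = 0):
    """Parametric Monte-Carlo test of uniform placement.

    The statistic is the total-variation distance between the observed and
    null channel-weighted cluster-size distributions.  Null patch tables
    of the observed size are resampled from the occupancy law and the
    p-value is ``(1 + #{stat* >= stat}) / (n_boot + 1)``.  A Monte-Carlo
    test is used instead of a chi-square because the tail bins have small
    expected counts.
    """
    if n_boot < 999:
        raise ValueError("n_boot must be >= 999")
    if observed.total_channels == 0:
        raise ValueError("degenerate observed table (no channels)")
    lam = null.occupancy_mean
    k_max = max(int(observed.counts.max()),
                int(stats.poisson.ppf(1.0 - 1e-9, lam))) + 5
    null_w = np.zeros(k_max)
    nd = binomial_null(null, k_max=max(k_max, int(
        stats.poisson.ppf(1.0 - 1e-12, lam)) + 20))
    for kv, p in zip(nd.k_values, nd.channel_weighted_proportion):
        null_w[min(kv, k_max) - 1] += p

    def tv(counts):
        return 0.5 * float(np.abs(_weighted_vector(counts, k_max) - null_w).sum())

    stat = tv(observed.counts)
    rng = np.random.default_rng(seed)
    n_p = observed.n_patches
    exceed = 0
    for _ in range(n_boot):
        while True:
            if null.mean_occupancy is not None:
                c = rng.poisson(lam, n_p)
            else:
                c = rng.binomial(null.n_total,
                                 null.patch_area / null.membrane_area, n_p)
            if c.sum() > 0:
                break
        if tv(c) >= stat - 1e-15:
            exceed += 1
    p_value = (1 + exceed) / (n_boot + 1)
    return stat, p_value


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums the hypergeometric probabilities of all tables with the observed
    margins that are no more probable than the observed one.
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError("cells must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("all margins must be positive")
    return float(stats.fisher_exact([[a, b], [c, d]],
                                    alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# density and whole-cell totals
# ---------------------------------------------------------------------------

def density_and_total(mean_per_patch: float, patch_area: float = 2.0,
                      capacitance: float = 65.0,
                      specific_capacitance: float = SPECIFIC_CAPACITANCE,
                      density_override: float | None = None) -> dict[str, float]:
    """Channel density, membrane area and whole-cell channel count.

    density = mean_per_patch / patch_area (per um^2); the membrane area
    follows from the cell capacitance at the specific capacitance of
    0.01 pF/um^2; the total count is density x area.  ``density_override``
    substitutes a (possibly rounded) density for the final product, as
    when a density "around 1 per um^2" over 6500 um^2 is quoted as 6500
    channels.
    """
    if mean_per_patch <= 0 or patch_area <= 0:
        raise ValueError("mean_per_patch and patch_area must be > 0")
    if capacitance <= 0 or specific_capacitance <= 0:
        raise ValueError("capacitance values must be > 0")
    density = mean_per_patch / patch_area
    membrane_area = capacitance / specific_capacitance
    used = density if density_override is None else density_override
    return {
        "density": density,
        "density_used": used,
        "membrane_area": membrane_area,
        "total_channels": int(round(used * membrane_area)),
    }
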