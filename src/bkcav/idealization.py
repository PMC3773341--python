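"""Idealization of single-channel records and ensemble open probability.

Converts noisy current traces into piecewise-constant integer open-level
sequences (half-amplitude threshold crossing with hysteresis and a dead
time), estimates the number of channels in a patch as the maximum number
of simultaneously open levels, and computes the ensemble open probability
Po(t) by the paired holding-potential subtraction: averaged sweeps from an
HP of -40 mV (T-type channels inactivated) are subtracted from averaged
sweeps from an HP of -80 mV, and the difference is normalized by the
number of channels times the unitary current.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sim_channels import CurrentTrace, OpenCountSeries

__all__ = [
    "IdealizedRecord",
    "PoSeries",
    "idealize",
    "estimate_channel_count",
    "npo_timecourse",
    "ensemble_po_subtraction",
]

logger = logging.getLogger(__name__)

# fractional hysteresis beyond the half-amplitude threshold; a level switch
# requires the signal to cross (k +/- (0.5 + margin)) * amplitude
HYSTERESIS_MARGIN = 0.05
DEFAULT_DEAD_TIME = 0.3  # ms


@dataclass
class IdealizedRecord:
    """Piecewise-constant open-level sequence.

    ``segments`` are contiguous half-open intervals ``(start_ms, end_ms,
    level)`` covering the trace; adjacent segments differ in level.
    """

    segments: list[tuple[float, float, int]]
    unitary_amplitude: float
    baseline: float
    sampling_interval: float

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("record needs at least one segment")
        prev_end = None
        for start, end, level in self.segments:
            if end <= start:
                raise ValueError("segments must have positive duration")
            if level < 0:
                raise ValueError("levels must be >= 0")
            if prev_end is not None and abs(start - prev_end) > 1e-9:
                raise ValueError("segments must be contiguous")
            prev_end = end

    @property
    def duration(self) -> float:
        return self.segments[-1][1] - self.segments[0][0]

    @property
    def max_level(self) -> int:
        return max(level for _, _, level in self.segments)

    def levels(self) -> np.ndarray:
        """Per-sample level sequence reconstructed from the segments."""
        n = int(round(self.duration / self.sampling_interval))
        t = self.segments[0][0] + np.arange(n) * self.sampling_interval
        bounds = np.array([end for _, end, _ in self.segments])
        idx = np.searchsorted(bounds, t, side="right")
        idx = np.minimum(idx, len(self.segments) - 1)
        lv = np.array([level for _, _, level in self.segments])
        return lv[idx]

    def time_averaged_level(self) -> float:
        dur = np.array([e - s for s, e, _ in self.segments])
        lv = np.array([l for _, _, l in self.segments])
        return float((dur * lv).sum() / dur.sum())


@dataclass
class PoSeries:
    """Ensemble open probability per sample, in [0, 1]."""

    sampling_interval: float
    po: np.ndarray
    n_channels: int
    n_sweeps: int
    n_clipped: int = 0   # samples whose negative subtraction value was clipped

    def __post_init__(self) -> None:
        self.po = np.asarray(self.po, dtype=float)
        if np.any(self.po < 0) or np.any(self.po > 1):
            raise ValueError("po must lie in [0, 1] elementwise")

    def times(self) -> np.ndarray:
        return np.arange(self.po.size) * self.sampling_interval

    def peak_time(self, smooth_ms: float = 0.0) -> float:
        """Time (ms) of the Po maximum, optionally boxcar-smoothed."""
        po = self.po
        if smooth_ms > 0:
            w = max(1, int(round(smooth_ms / self.sampling_interval)))
            po = np.convolve(po, np.ones(w) / w, mode="same")
        return float(np.argmax(po) * self.sampling_interval)


def _raw_levels(x: np.ndarray, amplitude: float, baseline: float) -> np.ndarray:
    """Half-amplitude level assignment with hysteresis (sequential)."""
    rel = (x - baseline) / amplitude
    levels = np.empty(x.size, dtype=np.int64)
    level = max(int(round(rel[0])), 0)
    levels[0] = level
    up = level + 0.5 + HYSTERESIS_MARGIN
    dn = level - 0.5 - HYSTERESIS_MARGIN
    for i in range(1, rel.size):
        r = rel[i]
        if r > up or r < dn:
            level = max(int(round(r)), 0)
            up = level + 0.5 + HYSTERESIS_MARGIN
            dn = level - 0.5 - HYSTERESIS_MARGIN
        levels[i] = level
    return levels


def _levels_to_segments(levels: np.ndarray, dt: float):
    change = np.flatnonzero(np.diff(levels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [levels.size]))
    return [(s * dt, e * dt, int(levels[s])) for s, e in zip(starts, ends)]


def _merge_short_segments(segments, dead_time: float):
    """Merge events shorter than the dead time into their neighbours.

    Repeatedly absorbs the shortest sub-dead-time segment into the longer
    adjacent segment (joining runs of equal level), so brief undetectable
    excursions are treated as part of the surrounding dwell.
    """
    segs = list(segments)
    while len(segs) > 1:
        durations = [e - s for s, e, _ in segs]
        idx = int(np.argmin(durations))
        if durations[idx] >= dead_time:
            break
        s, e, _ = segs[idx]
        left = segs[idx - 1] if idx > 0 else None
        right = segs[idx + 1] if idx + 1 < len(segs) else None
        if left is None:
            target = idx + 1
        elif right is None:
            target = idx - 1
        else:
            target = idx - 1 if (left[1] - left[0]) >= (right[1] - right[0]) else idx + 1
        if target < idx:
            segs[target] = (segs[target][0], e, segs[target][2])
        else:
            segs[target] = (s, segs[target][1], segs[target][2])
        del segs[idx]
        # join runs of equal level created by the merge
        joined = [segs[0]]
        for seg in segs[1:]:
            if seg[2] == joined[-1][2]:
                joined[-1] = (joined[-1][0], seg[1], seg[2])
            else:
                joined.append(seg)
        segs = joined
    return segs


def idealize(trace: CurrentTrace, unitary_amplitude: float,
             baseline: float | None = None,
             dead_time: float = DEFAULT_DEAD_TIME) -> IdealizedRecord:
    """Idealize a trace into integer open levels.

    The level at each sample is the rounded multiple of
    ``unitary_amplitude`` above ``baseline`` (clipped at 0); a level switch
    requires crossing the half-amplitude threshold with a small hysteresis
    margin, and events shorter than ``dead_time`` (ms) are merged into
    their neighbours.  If ``baseline`` is not given it is taken as the
    median of the first protocol segment (the holding period); without a
    protocol it defaults to 0.

    Indistinguishably low signal-to-noise input is not detected here; the
    caller is responsible for supplying a resolvable amplitude.
    """
    if unitary_amplitude == 0:
        raise ValueError("unitary_amplitude must be nonzero")
    if dead_time < 0:
        raise ValueError("dead_time must be >= 0")
    x = trace.samples
    if baseline is None:
        if trace.protocol is not None and len(trace.protocol.segments) > 1:
            n0 = int(round(trace.protocol.segments[0][1]
                           / trace.protocol.sampling_interval))
            baseline = float(np.median(x[:max(n0, 1)]))
        else:
            baseline = 0.0
    levels = _raw_levels(x, unitary_amplitude, baseline)
    segs = _levels_to_segments(levels, trace.sampling_interval)
    if dead_time > 0:
        segs = _merge_short_segments(segs, dead_time)
    return IdealizedRecord(segs, unitary_amplitude, baseline,
                           trace.sampling_interval)


def estimate_channel_count(records: Sequence[IdealizedRecord]) -> int:
    """Number of channels in a patch: maximum simultaneous open level.

    This is the counting rule used at the potential of maximal open
    probability (usually +20 mV).  It is biased downward for short
    records — a channel that never opens is never counted — and the bias
    is deliberately left uncorrected.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one idealized record")
    return max(r.max_level for r in records)


def npo_timecourse(records: Sequence[IdealizedRecord]) -> np.ndarray:
    """Pointwise mean open level (NPo) across stimulus-aligned records."""
    records = list(records)
    if not records:
        raise ValueError("need at least one idealized record")
    levels = [r.levels() for r in records]
    n = {lv.size for lv in levels}
    if len(n) != 1:
        raise ValueError("records must be aligned (equal length)")
    return np.mean(levels, axis=0)


def ensemble_po_subtraction(sweeps_hp80: Sequence[CurrentTrace],
                            sweeps_hp40: Sequence[CurrentTrace],
                            n_channels: int,
                            unitary_amplitude: float) -> PoSeries:
    """Open probability of the T-type-coupled BK component.

    ``Po(t) = (mean80(t) - mean40(t)) / (n_channels * unitary_amplitude)``
    where the means are ensemble averages of the sweeps in each arm.
    Negative samples of the subtraction (noise, or spontaneous activity in
    the -40 mV arm) are clipped to 0 and the number of clipped samples is
    logged and reported.
    """
    s80, s40 = list(sweeps_hp80), list(sweeps_hp40)
    if not s80 or not s40:
        raise ValueError("both sweep sets must be non-empty")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if unitary_amplitude == 0:
        raise ValueError("unitary_amplitude must be nonzero")
    geom = {(tr.samples.size, tr.sampling_interval) for tr in s80 + s40}
    if len(geom) != 1:
        raise ValueError("sweeps must share length and sampling interval")
    (n_samples, dt), = geom
    mean80 = np.mean([tr.samples for tr in s80], axis=0)
    mean40 = np.mean([tr.samples for tr in s40], axis=0)
    po = (mean80 - mean40) / (n_channels * unitary_amplitude)
    n_clipped = int(np.sum(po < 0))
    if n_clipped:
        logger.info("ensemble_po_subtraction: clipped %d negative samples "
                    "(%.1f%% of trace)", n_clipped, 100 * n_clipped / po.size)
    po = np.clip(po, 0.0, 1.0)
    return PoSeries(dt, po, n_channels, len(s80), n_clipped)
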