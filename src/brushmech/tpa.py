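"""Texture profile analysis of double-compression force-time traces.

A TPA test compresses a disk-shaped specimen twice and records force vs
time.  After baseline correction (median of the pre-contact samples) the
trace is segmented into exactly two cycles at returns to baseline, each
cycle split at its force peak into a compression (loading) and withdrawal
(unloading) phase.  Three dimensionless texture metrics follow from
trapezoidal areas of the force-time signal:

* cohesiveness = (A2_down + A2_up) / (A1_down + A1_up), the second-cycle
  work fraction;
* resilience = A1_up / A1_down, the energy returned during first-cycle
  withdrawal;
* springiness = (cycle-2 contact-to-peak time) / (cycle-1 contact-to-peak
  time), the time-based convention.

A perfectly elastic specimen scores 1 on all three.  The metrics are
invariant to positive force rescaling and to time shifts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: contact / cycle-boundary threshold, as a fraction of the global force peak
CONTACT_THRESHOLD_FRAC = 0.01


class TraceError(ValueError):
    """Invalid TPA trace input."""


class MetricError(RuntimeError):
    """TPA metrics are undefined for this input (e.g. zero first-cycle area)."""


@dataclass(frozen=True)
class TPATrace:
    """Raw (time, displacement, force) record of a double compression."""

    time: np.ndarray  # s
    displacement: np.ndarray  # mm
    force: np.ndarray  # N
    strain_pct: float = 50.0
    specimen: str = ""
    diameter_mm: float = 8.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        d = np.asarray(self.displacement, dtype=float)
        f = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "displacement", d)
        object.__setattr__(self, "force", f)
        if not (t.ndim == d.ndim == f.ndim == 1) or not (t.size == d.size == f.size):
            raise TraceError("time, displacement, force must be 1-D arrays of equal length")
        if t.size < 7:
            raise TraceError("a two-cycle trace needs at least 7 samples")
        if np.any(np.diff(t) <= 0.0):
            raise TraceError("time must be strictly increasing")
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(d)) or np.any(~np.isfinite(f)):
            raise TraceError("trace contains non-finite values")


@dataclass(frozen=True)
class Cycle:
    """One compression-withdrawal cycle on the baseline-corrected signal."""

    time: np.ndarray
    force: np.ndarray
    peak_index: int

    @property
    def contact_time(self) -> float:
        return float(self.time[0])

    @property
    def peak_time(self) -> float:
        return float(self.time[self.peak_index])

    @property
    def peak_force(self) -> float:
        return float(self.force[self.peak_index])

    @property
    def area_down(self) -> float:
        """Loading (compression) work proxy, N*s: area up to the peak."""
        return float(np.trapezoid(self.force[: self.peak_index + 1], self.time[: self.peak_index + 1]))

    @property
    def area_up(self) -> float:
        """Unloading (withdrawal) work proxy, N*s: area after the peak."""
        if self.peak_index >= self.time.size - 1:
            return 0.0
        return float(np.trapezoid(self.force[self.peak_index :], self.time[self.peak_index :]))


@dataclass(frozen=True)
class TPACycleSet:
    first: Cycle
    second: Cycle
    baseline: float
    threshold: float


@dataclass(frozen=True)
class TPAResult:
    springiness: float
    resilience: float
    cohesiveness: float
    areas: tuple[float, float, float, float]  # (A1_down, A1_up, A2_down, A2_up), N*s
    peaks: tuple[float, float]  # (P1, P2), N

    def to_dict(self) -> dict:
        return {
            "springiness": self.springiness,
            "resilience": self.resilience,
            "cohesiveness": self.cohesiveness,
            "areas_Ns": {
                "A1_down": self.areas[0],
                "A1_up": self.areas[1],
                "A2_down": self.areas[2],
                "A2_up": self.areas[3],
            },
            "peaks_N": {"P1": self.peaks[0], "P2": self.peaks[1]},
        }


def _baseline_correct(trace: TPATrace) -> tuple[np.ndarray, float, float]:
    """Return (corrected force, baseline, threshold).

    Baseline is the median of the samples preceding first contact, found
    iteratively: an initial threshold from the raw signal locates the
    pre-contact region, whose median then fixes the baseline.
    """
    f = trace.force
    peak = float(np.max(f))
    rough_thr = float(np.min(f)) + CONTACT_THRESHOLD_FRAC * (peak - float(np.min(f)))
    pre = np.nonzero(f > rough_thr)[0]
    n_pre = int(pre[0]) if pre.size else f.size
    baseline = float(np.median(f[:n_pre])) if n_pre > 0 else float(np.min(f))
    corrected = f - baseline
    gpeak = float(np.max(corrected))
    if gpeak <= 0:
        raise TraceError("trace has no force excursion above baseline")
    return corrected, baseline, CONTACT_THRESHOLD_FRAC * gpeak


def segment_cycles(trace: TPATrace) -> TPACycleSet:
    """Split a baseline-corrected trace into its two compression cycles.

    A cycle is a maximal run of samples above the contact threshold (1% of
    the global corrected peak), extended by one boundary sample on each
    side so the force-time area of traces that touch baseline exactly is
    integrated without truncation.  Raises :class:`TraceError` with the
    detected count when the trace does not contain exactly two cycles.
    """
    f, baseline, thr = _baseline_correct(trace)
    above = f > thr
    # maximal runs of above-threshold samples
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = [int(e) + 1 for e in edges if not above[e]]
    ends = [int(e) for e in edges if above[e]]
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above) - 1)
    regions = list(zip(starts, ends))
    if len(regions) != 2:
        raise TraceError(f"expected exactly 2 compression cycles, detected {len(regions)}")
    cycles = []
    for s, e in regions:
        s_ext = max(s - 1, 0)
        e_ext = min(e + 1, f.size - 1)
        seg_t = trace.time[s_ext : e_ext + 1]
        seg_f = np.clip(f[s_ext : e_ext + 1], 0.0, None)
        cycles.append(Cycle(time=seg_t, force=seg_f, peak_index=int(np.argmax(seg_f))))
    return TPACycleSet(first=cycles[0], second=cycles[1], baseline=baseline, threshold=thr)


def tpa_metrics(cycles: TPACycleSet) -> TPAResult:
    """Compute springiness, resilience, cohesiveness from segmented cycles."""
    c1, c2 = cycles.first, cycles.second
    a1d, a1u = c1.area_down, c1.area_up
    a2d, a2u = c2.area_down, c2.area_up
    if a1d + a1u <= 0.0:
        raise MetricError("first-cycle area is zero; TPA metrics undefined")
    if a1d <= 0.0:
        raise MetricError("first-cycle compression area is zero; resilience undefined")
    t1 = c1.peak_time - c1.contact_time
    if t1 <= 0.0:
        raise MetricError("first-cycle contact-to-peak time is zero; springiness undefined")
    return TPAResult(
        springiness=(c2.peak_time - c2.contact_time) / t1,
        resilience=a1u / a1d,
        cohesiveness=(a2d + a2u) / (a1d + a1u),
        areas=(a1d, a1u, a2d, a2u),
        peaks=(c1.peak_force, c2.peak_force),
    )


def analyze_trace(trace: TPATrace) -> TPAResult:
    """Segment and score a raw trace in one call."""
    return tpa_metrics(segment_cycles(trace))
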