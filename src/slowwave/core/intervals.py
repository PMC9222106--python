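"""Interval algebra on half-open interval sets."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import EventTable, IntervalSet

__all__ = ["interval_intersect", "interval_union", "duty_cycle", "events_in_intervals", "EventMembership"]


def interval_intersect(a: IntervalSet, b: IntervalSet, label: str | None = None) -> IntervalSet:
    """Point-set intersection of two interval sets (merged, sorted)."""
    out = []
    i = j = 0
    A, B = a.intervals, b.intervals
    while i < len(A) and j < len(B):
        s = max(A[i, 0], B[j, 0])
        e = min(A[i, 1], B[j, 1])
        if s < e:
            out.append((s, e))
        # advance whichever interval ends first
        if A[i, 1] <= B[j, 1]:
            i += 1
        else:
            j += 1
    return IntervalSet(out, label=label or a.label)


def interval_union(a: IntervalSet, b: IntervalSet, label: str | None = None) -> IntervalSet:
    rows = list(map(tuple, a.intervals)) + list(map(tuple, b.intervals))
    return IntervalSet(rows, label=label or a.label)


def duty_cycle(iv: IntervalSet, t_lo: float, t_hi: float) -> float:
    """Fraction of [t_lo, t_hi) covered by ``iv``."""
    if t_lo >= t_hi:
        raise ValueError("t_lo must be < t_hi")
    return iv.clip(t_lo, t_hi).total_duration / (t_hi - t_lo)


@dataclass
class EventMembership:
    """Result of :func:`events_in_intervals`.

    ``fraction`` is ``None`` (with ``defined=False``) when the event table
    is empty — an empty table is *not* a zero fraction.
    """

    inside: np.ndarray
    fraction: float | None
    defined: bool

    @property
    def n(self) -> int:
        return self.inside.size


def events_in_intervals(ev: EventTable, iv: IntervalSet) -> EventMembership:
    """Which events have their peak inside some interval, and the fraction."""
    if len(ev) == 0:
        return EventMembership(inside=np.zeros(0, dtype=bool), fraction=None, defined=False)
    inside = iv.contains(ev.t_peak)
    return EventMembership(inside=inside, fraction=float(inside.mean()), defined=True)
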