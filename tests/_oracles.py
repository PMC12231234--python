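"""Independent naive reference implementations used only by tests.

These deliberately share no code with the package: plain-Python double
loops, bisect-based interval lookup, and dict-based group-bys, so that
agreement with the vectorised implementations is meaningful.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from collections import defaultdict


def naive_rdhw(hs: list[float], window: int = 84, gate: float = 1.0) -> list[float]:
    """O(n * window) double-loop accumulation of gated HotSpots, degC-weeks."""
    out = []
    for i in range(len(hs)):
        total = 0.0
        for j in range(max(0, i - window + 1), i + 1):
            v = hs[j]
            if v is not None and not math.isnan(v) and v >= gate:
                total += v
        out.append(total / 7.0)
    return out


# lower rDHW edge -> level reached on rDHW alone (hs >= 1 only gates AL1/Warning)
_RDHW_LEVELS = [(8.0, "AL2"), (12.0, "AL3"), (16.0, "AL4"), (20.0, "AL5")]


def naive_alert(hs: float, rdhw: float) -> str:
    """Interval lookup on the alert table, built with bisect not masks."""
    if math.isnan(rdhw):
        return "Unclassified"
    edges = [e for e, _ in _RDHW_LEVELS]
    k = bisect_right(edges, rdhw)
    if k > 0:
        return _RDHW_LEVELS[k - 1][1]
    if hs >= 1.0:
        return "AL1" if rdhw >= 4.0 else "Warning"
    if hs > 0.0:
        return "Watch"
    return "NoStress"


def naive_burst_means(samples: list[tuple]) -> dict:
    """Group (timestamp, value) samples by 30-min slot; return slot -> mean."""
    groups = defaultdict(list)
    for ts, v in samples:
        slot = ts.replace(minute=(0 if ts.minute < 30 else 30), second=0, microsecond=0)
        groups[slot].append(v)
    return {slot: sum(v) / len(v) for slot, v in groups.items()}


def naive_daily_stats(values_by_day: dict) -> dict:
    """day -> (mean, max, min) from lists of burst values."""
    return {
        day: (sum(v) / len(v), max(v), min(v)) for day, v in values_by_day.items() if v
    }


def circular_mean_deg(angles_deg) -> float:
    s = sum(math.sin(math.radians(a)) for a in angles_deg)
    c = sum(math.cos(math.radians(a)) for a in angles_deg)
    return math.degrees(math.atan2(s, c)) % 360.0
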