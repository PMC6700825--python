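"""Standardized blood-pressure protocol: per-arm reading series to a final MAP.

Mean arterial pressure (MAP) is computed per reading as
``(systolic + 2 * diastolic) / 3``.  Each arm's MAP is the average of the last
two recorded readings, which the measurement protocol expects to be a *stable*
pair: consecutive readings differing by at most 10 mmHg systolic and 6 mmHg
diastolic.  The final MAP is the higher of the two arm MAPs.

Recorded series are assumed to end at the stable pair (measurement continues
until stability is reached); if the final pair is nevertheless unstable the
MAP is still computed but flagged ``stable=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "BPSeries",
    "MapResult",
    "map_from_reading",
    "is_stable",
    "arm_map",
    "final_map",
    "parse_bp_series",
    "format_bp_series",
    "SYSTOLIC_STABILITY_MMHG",
    "DIASTOLIC_STABILITY_MMHG",
]

#: Maximum between-reading variation still considered stable (mmHg).
SYSTOLIC_STABILITY_MMHG = 10.0
DIASTOLIC_STABILITY_MMHG = 6.0

Reading = tuple[float, float]  # (systolic, diastolic), mmHg


def _validate_reading(reading: Reading) -> None:
    systolic, diastolic = reading
    if not diastolic > 0:
        raise ValueError(f"diastolic pressure must be positive, got {diastolic}")
    if not systolic > diastolic:
        raise ValueError(
            f"systolic ({systolic}) must exceed diastolic ({diastolic}) mmHg"
        )


@dataclass(frozen=True)
class BPSeries:
    """An ordered series of (systolic, diastolic) readings from one arm."""

    arm: str
    readings: tuple[Reading, ...]

    def __post_init__(self) -> None:
        if self.arm not in ("left", "right"):
            raise ValueError(f"arm must be 'left' or 'right', got {self.arm!r}")
        for reading in self.readings:
            _validate_reading(reading)


@dataclass(frozen=True)
class MapResult:
    """Final MAP with the per-arm values and the stability flag."""

    map_left: float
    map_right: float
    final_map: float
    stable: bool


def map_from_reading(systolic: float, diastolic: float) -> float:
    """MAP of a single reading: one third systolic plus two thirds diastolic."""
    _validate_reading((systolic, diastolic))
    return (systolic + 2.0 * diastolic) / 3.0


def is_stable(prev: Reading, nxt: Reading) -> bool:
    """Whether two consecutive readings satisfy the stability criterion."""
    d_sys = abs(nxt[0] - prev[0])
    d_dia = abs(nxt[1] - prev[1])
    return d_sys <= SYSTOLIC_STABILITY_MMHG and d_dia <= DIASTOLIC_STABILITY_MMHG


def arm_map(series: BPSeries | Sequence[Reading]) -> tuple[float, bool]:
    """MAP of one arm: mean per-reading MAP over the last two readings.

    Returns ``(map_mmhg, stable)``.  ``stable`` reports whether the final
    pair meets the stability criterion; an unstable pair is computed anyway
    (with a warning) because recorded series are taken as final.
    """
    readings = series.readings if isinstance(series, BPSeries) else tuple(series)
    if len(readings) < 2:
        raise ValueError(f"need at least 2 readings for an arm MAP, got {len(readings)}")
    last, prev = readings[-1], readings[-2]
    stable = is_stable(prev, last)
    if not stable:
        warnings.warn(
            "final reading pair exceeds stability bounds "
            f"(|dS|<={SYSTOLIC_STABILITY_MMHG}, |dD|<={DIASTOLIC_STABILITY_MMHG}); "
            "MAP computed anyway",
            stacklevel=2,
        )
    value = (map_from_reading(*prev) + map_from_reading(*last)) / 2.0
    return value, stable


def final_map(left: BPSeries, right: BPSeries) -> MapResult:
    """Final MAP: the higher of the two arm MAPs; unstable if either arm is."""
    map_l, stable_l = arm_map(left)
    map_r, stable_r = arm_map(right)
    return MapResult(
        map_left=map_l,
        map_right=map_r,
        final_map=max(map_l, map_r),
        stable=stable_l and stable_r,
    )


def parse_bp_series(text: str, arm: str = "left") -> BPSeries:
    """Parse the cohort-file dialect ``"S/D;S/D;..."`` into a :class:`BPSeries`."""
    readings = []
    for i, token in enumerate(str(text).strip().split(";")):
        parts = token.split("/")
        if len(parts) != 2:
            raise ValueError(f"malformed reading {token!r} at position {i}")
        try:
            readings.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise ValueError(f"non-numeric reading {token!r} at position {i}") from exc
    return BPSeries(arm=arm, readings=tuple(readings))


def format_bp_series(readings: Iterable[Reading]) -> str:
    """Inverse of :func:`parse_bp_series` (full float precision preserved)."""
    return ";".join(f"{s:.10g}/{d:.10g}" for s, d in readings)
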