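"""Vertebral body wedging angles and combined lumbar wedging.

The wedging angle of a vertebral body is

    theta = arctan((D - V) / L)

where D is the dorsal body height, V the ventral body height and L the
dorsoventral body length, all in mm; theta is expressed in degrees.
Positive angles (dorsal taller than ventral) are ventral/kyphotic
wedging; negative angles are dorsal/lordotic wedging, the pattern that
produces lumbar lordosis when it dominates the caudal levels. Summing
per-level angles over L2-L5 gives the combined lumbar wedging value used
to compare whole columns.

Which dorsoventral length enters the denominator (superior endplate,
inferior endplate, or their mean) is a reporting policy; ``superior`` is
the default and the policy used is recorded on every result.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np

from .datatypes import (
    LumbarSeries,
    Measurement,
    MissingDataError,
    VertebralBodyGeometry,
    LEVELS,
)

__all__ = [
    "LengthPolicy",
    "WedgingAngle",
    "WedgingProfile",
    "wedging_angle",
    "combined_wedging",
    "wedging_profile",
    "round_half_away",
]

#: Default level range for combined wedging, matching comparative practice
#: of summing over the last four lumbar levels of a five-lumbar column.
DEFAULT_COMBINED_LEVELS = ("L2", "L3", "L4", "L5")


class LengthPolicy(str, enum.Enum):
    """Choice of dorsoventral length L in the wedging formula."""

    SUPERIOR = "superior"
    INFERIOR = "inferior"
    MEAN = "mean"


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of printed tables).

    Python's builtin ``round`` rounds half to even; comparative tables
    round 0.05 up in magnitude, so -11.15 prints as -11.2.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).copy_abs().quantize(q, rounding=ROUND_HALF_UP)) * (
        -1.0 if x < 0 else 1.0
    )


@dataclass(frozen=True)
class WedgingAngle:
    """A signed per-level wedging angle in degrees."""

    level: str
    angle: float
    length_policy_used: LengthPolicy
    estimated: bool = False

    def rounded(self, ndigits: int = 1) -> float:
        return round_half_away(self.angle, ndigits)


@dataclass(frozen=True)
class WedgingProfile:
    """Per-level angles plus the combined sum and the wedging transition.

    ``transition`` is the first adjacent level pair (cranial, caudal)
    where the angle changes from positive (kyphotic) to non-positive
    (lordotic); ``None`` when no such pair exists.
    """

    angles: tuple[WedgingAngle, ...]
    combined: Optional[float]
    combined_levels: tuple[str, ...]
    transition: Optional[tuple[str, str]]


def _length(
    geometry: VertebralBodyGeometry, policy: LengthPolicy
) -> tuple[float, bool]:
    sup = geometry.sup_dv_diameter
    inf = geometry.inf_dv_diameter
    if policy is LengthPolicy.SUPERIOR:
        if sup is None:
            raise MissingDataError("sup_dv_diameter missing for superior policy")
        return sup.value, sup.estimated
    if policy is LengthPolicy.INFERIOR:
        if inf is None:
            raise MissingDataError("inf_dv_diameter missing for inferior policy")
        return inf.value, inf.estimated
    if sup is None or inf is None:
        raise MissingDataError(
            "both dorsoventral diameters required for mean policy"
        )
    return 0.5 * (sup.value + inf.value), sup.estimated or inf.estimated


def wedging_angle(
    geometry: VertebralBodyGeometry,
    policy: LengthPolicy = LengthPolicy.SUPERIOR,
    level: str = "",
) -> WedgingAngle:
    """Compute the wedging angle of one vertebral body.

    Raises
    ------
    MissingDataError
        If either height, or the diameter(s) the policy needs, is absent.
    """
    policy = LengthPolicy(policy)
    missing = [
        name
        for name, m in (
            ("ventral_height", geometry.ventral_height),
            ("dorsal_height", geometry.dorsal_height),
        )
        if m is None
    ]
    if missing:
        where = f" at {level}" if level else ""
        raise MissingDataError(f"missing {', '.join(missing)}{where}")
    v = geometry.ventral_height
    d = geometry.dorsal_height
    length, length_est = _length(geometry, policy)
    angle = float(np.degrees(np.arctan2(d.value - v.value, length)))
    return WedgingAngle(
        level=level,
        angle=angle,
        length_policy_used=policy,
        estimated=v.estimated or d.estimated or length_est,
    )


def combined_wedging(
    angles: dict[str, float] | Sequence[float],
    levels: Sequence[str] = DEFAULT_COMBINED_LEVELS,
) -> float:
    """Sum per-level wedging angles over a level range (default L2-L5).

    ``angles`` may be a mapping level -> degrees or a plain sequence in
    level order. Every requested level must be present: columns missing
    a level are excluded from combined wedging rather than imputed.
    """
    if isinstance(angles, dict):
        missing = [lv for lv in levels if lv not in angles or angles[lv] is None]
        if missing:
            raise MissingDataError(
                f"combined wedging over {list(levels)} needs angles for "
                f"{missing}"
            )
        values = [angles[lv] for lv in levels]
    else:
        values = list(angles)
        if len(values) != len(levels):
            raise MissingDataError(
                f"expected {len(levels)} angles for levels {list(levels)}, "
                f"got {len(values)}"
            )
    return float(np.sum(values))


def wedging_profile(
    series: LumbarSeries,
    policy: LengthPolicy = LengthPolicy.SUPERIOR,
    combined_levels: Sequence[str] = DEFAULT_COMBINED_LEVELS,
) -> WedgingProfile:
    """Per-level wedging angles, combined wedging, and the transition level.

    Levels whose measurements are incomplete are skipped for the
    per-level profile; combined wedging is reported only when every
    level in ``combined_levels`` is computable.
    """
    angles: list[WedgingAngle] = []
    for level in series.present_levels:
        geom = series.geometry(level)
        try:
            angles.append(wedging_angle(geom, policy, level=level))
        except MissingDataError:
            continue
    if len(angles) < 2:
        raise MissingDataError(
            f"{series.specimen.specimen_id}: fewer than two computable levels"
        )
    by_level = {a.level: a.angle for a in angles}
    try:
        combined = combined_wedging(by_level, combined_levels)
    except MissingDataError:
        combined = None
    transition: Optional[tuple[str, str]] = None
    for a, b in zip(angles, angles[1:]):
        if LEVELS.index(b.level) != LEVELS.index(a.level) + 1:
            continue  # only adjacent anatomical levels define a transition
        if a.angle > 0 and b.angle <= 0:
            transition = (a.level, b.level)
            break
    return WedgingProfile(
        angles=tuple(angles),
        combined=combined,
        combined_levels=tuple(combined_levels),
        transition=transition,
    )
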