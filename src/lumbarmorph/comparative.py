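"""Group summaries, 95% prediction intervals, and fossil classification.

Extant comparative samples (humans by sex, *Pan*, *Gorilla*, *Pongo*)
are summarized per vertebral level and for combined wedging; a 95%
prediction interval is constructed as mean ± 1.96·SD, and fossil values
are classified as inside or outside each group's interval. Intervals are
closed: a value exactly on a bound counts as inside.

Two interval modes exist because published summary tables print mean
and SD at one decimal: ``computed`` derives the interval from the
(unrounded) mean/SD it is given, while ``printed`` carries bounds taken
verbatim from a published table. The mode is recorded on the interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .wedging import round_half_away

__all__ = [
    "GroupSummary",
    "PredictionInterval",
    "FossilClassification",
    "summarize_group",
    "prediction_interval",
    "classify_fossil",
    "load_reference_summaries",
    "load_fossil_angles",
    "load_mh2_measurements",
]

#: z multiplier of the 95% prediction interval construction.
Z_95 = 1.96


class InsufficientDataError(ValueError):
    """Too few observations for the requested summary."""


@dataclass(frozen=True)
class GroupSummary:
    """Per-group, per-variable summary statistics (degrees)."""

    group: str
    variable: str
    n: int
    mean: float
    sd: float
    min: float
    max: float


@dataclass(frozen=True)
class PredictionInterval:
    """A 95% prediction interval, mean ± 1.96·SD."""

    group: str
    variable: str
    lower: float
    upper: float
    z: float = Z_95
    mode: str = "computed"  # "computed" from mean/sd, or "printed" bounds

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(
                f"{self.group}/{self.variable}: lower {self.lower} exceeds "
                f"upper {self.upper}"
            )

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    def rounded(self, ndigits: int = 1) -> tuple[float, float]:
        return (
            round_half_away(self.lower, ndigits),
            round_half_away(self.upper, ndigits),
        )


@dataclass(frozen=True)
class GroupVerdict:
    """Inside/outside verdict against one group's interval.

    ``margin`` is the signed distance to the nearest violated bound:
    zero when inside, negative magnitude below the lower bound,
    positive above the upper bound.
    """

    group: str
    inside: bool
    margin: float
    interval: PredictionInterval


@dataclass(frozen=True)
class FossilClassification:
    fossil_id: str
    variable: str
    value: float
    verdicts: tuple[GroupVerdict, ...]

    @property
    def outside_all(self) -> bool:
        return all(not v.inside for v in self.verdicts)

    @property
    def inside_all(self) -> bool:
        return all(v.inside for v in self.verdicts)

    def verdict(self, group: str) -> GroupVerdict:
        for v in self.verdicts:
            if v.group == group:
                return v
        raise KeyError(group)


def summarize_group(
    values: Sequence[float], group: str, variable: str
) -> GroupSummary:
    """Mean, sample SD (n−1), min and max of one group's values.

    Raises :class:`InsufficientDataError` for n < 2 and rejects missing
    values (no imputation).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(
            f"{group}/{variable}: need at least 2 values, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{group}/{variable}: missing or non-finite values")
    return GroupSummary(
        group=group,
        variable=variable,
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        min=float(arr.min()),
        max=float(arr.max()),
    )


def prediction_interval(
    summary: GroupSummary, mode: str = "computed"
) -> PredictionInterval:
    """95% prediction interval mean ± 1.96·SD from a group summary."""
    half = Z_95 * summary.sd
    return PredictionInterval(
        group=summary.group,
        variable=summary.variable,
        lower=summary.mean - half,
        upper=summary.mean + half,
        mode=mode,
    )


def classify_fossil(
    fossil_id: str,
    value: float,
    intervals: Sequence[PredictionInterval],
    variable: str = "",
) -> FossilClassification:
    """Classify one fossil value against a set of group intervals.

    Intervals are closed; the margin is 0 inside and the signed distance
    to the violated bound outside.
    """
    if not intervals:
        raise ValueError("at least one prediction interval is required")
    verdicts = []
    for pi in intervals:
        if pi.contains(value):
            verdicts.append(GroupVerdict(pi.group, True, 0.0, pi))
        elif value < pi.lower:
            verdicts.append(GroupVerdict(pi.group, False, value - pi.lower, pi))
        else:
            verdicts.append(GroupVerdict(pi.group, False, value - pi.upper, pi))
    return FossilClassification(
        fossil_id=fossil_id,
        variable=variable or (intervals[0].variable if intervals else ""),
        value=value,
        verdicts=tuple(verdicts),
    )


# ---------------------------------------------------------------------------
# Bundled reference tables (transcribed comparative summaries), so the
# classification pipeline runs with no external downloads.


def _data_path(name: str):
    return resources.files("lumbarmorph.data").joinpath(name)


def load_reference_summaries() -> pd.DataFrame:
    """Published wedging summary statistics for the extant samples.

    Columns: group, variable (L2..L5, combined), n, mean, sd,
    pi_lower, pi_upper, min, max. ``pi_lower``/``pi_upper`` are the
    bounds as printed (1 dp), for use in ``printed`` interval mode.
    """
    with resources.as_file(_data_path("extant_wedging_summaries.csv")) as p:
        return pd.read_csv(p)


def load_fossil_angles() -> pd.DataFrame:
    """Published per-level and combined wedging angles of fossil hominins.

    Columns: fossil_id, adult (bool), L2..L5, combined; absent levels
    are NaN.
    """
    with resources.as_file(_data_path("fossil_wedging_angles.csv")) as p:
        return pd.read_csv(p)


def load_mh2_measurements():
    """The bundled MH2 lumbar measurement table as LumbarSeries."""
    from .io import read_measurements

    with resources.as_file(_data_path("mh2_measurements.csv")) as p:
        return read_measurements(p)


def reference_intervals(
    variable: str,
    groups: Optional[Sequence[str]] = None,
    mode: str = "printed",
) -> list[PredictionInterval]:
    """Prediction intervals for the bundled extant summaries.

    ``mode='printed'`` uses the published interval bounds verbatim;
    ``mode='computed'`` rebuilds mean ± 1.96·SD from the printed
    mean/SD (which can differ in the last decimal).
    """
    table = load_reference_summaries()
    sub = table[table["variable"] == variable]
    if groups is not None:
        sub = sub[sub["group"].isin(groups)]
    out = []
    for row in sub.itertuples(index=False):
        if mode == "printed":
            out.append(
                PredictionInterval(
                    group=row.group,
                    variable=variable,
                    lower=float(row.pi_lower),
                    upper=float(row.pi_upper),
                    mode="printed",
                )
            )
        else:
            summary = GroupSummary(
                group=row.group,
                variable=variable,
                n=int(row.n),
                mean=float(row.mean),
                sd=float(row.sd),
                min=float(row.min),
                max=float(row.max),
            )
            out.append(prediction_interval(summary))
    return out
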