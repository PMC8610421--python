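"""Pyramidal configuration of the neural arch: the inter-articular facet index.

Modern humans show a caudally progressive widening of the lumbar
inter-articular facet spacing ("pyramidal configuration"), which
accommodates imbrication of the inferior articular facets during lumbar
hyperextension. The index quantifying it divides the maximum
inter-facet width at the lumbosacral level by that of the lumbar
vertebra three levels higher: L2 vs L5 in five-lumbar columns
(hominins), L1 vs L4 in four-lumbar great apes. Index > 1 means caudal
widening (pyramidal); 1 means parallel spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datatypes import LumbarSeries, MissingDataError

__all__ = ["FacetIndexResult", "select_index_levels", "facet_index", "facet_index_for_series"]


class UnsupportedConfigurationError(ValueError):
    """Columns with three lumbar vertebrae are excluded from the index."""


@dataclass(frozen=True)
class FacetIndexResult:
    specimen_id: str
    upper_level: str
    lower_level: str
    upper_width: float
    lower_width: float
    index: float
    estimated: bool = False

    def rounded(self, ndigits: int = 2) -> float:
        from .wedging import round_half_away

        return round_half_away(self.index, ndigits)


def select_index_levels(series: LumbarSeries) -> tuple[str, str]:
    """Pick the (upper, lower) levels entering the facet index.

    The lower level is the last lumbar (lumbosacral joint); the upper
    one sits three levels higher: (L2, L5) for five-lumbar columns,
    (L1, L4) for four-lumbar columns. Three-lumbar individuals are
    excluded (no level three above the last lumbar exists).
    """
    count = series.specimen.lumbar_count
    if count == 5:
        return ("L2", "L5")
    if count == 4:
        return ("L1", "L4")
    raise UnsupportedConfigurationError(
        f"{series.specimen.specimen_id}: columns with {count} lumbar "
        "vertebrae are not supported by the facet index"
    )


def facet_index(
    upper_width: float,
    lower_width: float,
    specimen_id: str = "",
    upper_level: str = "",
    lower_level: str = "",
    estimated: bool = False,
) -> FacetIndexResult:
    """lower_width / upper_width at full precision."""
    if upper_width <= 0 or lower_width <= 0:
        raise ValueError(
            f"{specimen_id or 'facet index'}: widths must be positive, got "
            f"upper={upper_width}, lower={lower_width}"
        )
    return FacetIndexResult(
        specimen_id=specimen_id,
        upper_level=upper_level,
        lower_level=lower_level,
        upper_width=float(upper_width),
        lower_width=float(lower_width),
        index=float(lower_width) / float(upper_width),
        estimated=estimated,
    )


def facet_index_for_series(series: LumbarSeries) -> FacetIndexResult:
    """Facet index from a measurement series, using max inter-IAF widths.

    Estimated input widths (incomplete structures) propagate
    ``estimated=True`` to the result.
    """
    upper_level, lower_level = select_index_levels(series)
    for level in (upper_level, lower_level):
        if level not in series.levels:
            raise MissingDataError(
                f"{series.specimen.specimen_id}: level {level} absent"
            )
    upper = series.facets(upper_level).max_inter_IAF
    lower = series.facets(lower_level).max_inter_IAF
    missing = [
        lv
        for lv, m in ((upper_level, upper), (lower_level, lower))
        if m is None
    ]
    if missing:
        raise MissingDataError(
            f"{series.specimen.specimen_id}: max inter-IAF width missing at "
            f"{', '.join(missing)}"
        )
    return facet_index(
        upper.value,
        lower.value,
        specimen_id=series.specimen.specimen_id,
        upper_level=upper_level,
        lower_level=lower_level,
        estimated=upper.estimated or lower.estimated,
    )
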