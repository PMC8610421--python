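"""Domain types for lumbar vertebral morphometrics.

Linear measurements are in millimetres, angles in degrees, throughout the
package. Missing values are represented explicitly (``None``), never as
zero. Measured-but-estimated values (printed in parentheses in comparative
osteology tables, typically because the structure is incomplete) carry an
``estimated`` flag that propagates into derived quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "Measurement",
    "SpecimenInfo",
    "VertebralBodyGeometry",
    "FacetWidths",
    "LumbarSeries",
    "LandmarkConfiguration",
    "LandmarkSet",
    "LEVELS",
]

#: Canonical lumbar level labels, cranial to caudal.
LEVELS = ("L1", "L2", "L3", "L4", "L5")


class ValidationError(ValueError):
    """Input violates a structural invariant of the data model."""


class MissingDataError(ValueError):
    """A computation requires a measurement that is absent."""


@dataclass(frozen=True)
class Measurement:
    """A single linear measurement with provenance.

    Parameters
    ----------
    value : float
        The measurement in millimetres; must be positive.
    estimated : bool
        True when the measurement was estimated from incomplete anatomy
        (parenthesized in source tables).
    """

    value: float
    estimated: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.value) or self.value <= 0:
            raise ValidationError(
                f"measurement must be positive and finite, got {self.value!r}"
            )


@dataclass(frozen=True)
class SpecimenInfo:
    """Identity and sampling metadata for one individual."""

    specimen_id: str
    taxon: str
    group: str
    sex: Optional[str] = None
    lumbar_count: int = 5
    is_fossil: bool = False

    def __post_init__(self) -> None:
        if self.lumbar_count not in (3, 4, 5):
            raise ValidationError(
                f"{self.specimen_id}: lumbar_count must be 3, 4 or 5, "
                f"got {self.lumbar_count}"
            )


@dataclass(frozen=True)
class VertebralBodyGeometry:
    """Vertebral body heights and dorsoventral diameters for one level.

    ``ventral_height`` and ``dorsal_height`` are the craniocaudal heights of
    the body at its ventral and dorsal margins; ``sup_dv_diameter`` and
    ``inf_dv_diameter`` are the dorsoventral lengths of the superior and
    inferior endplates. Any field may be ``None`` (not preserved).
    """

    ventral_height: Optional[Measurement] = None
    dorsal_height: Optional[Measurement] = None
    sup_dv_diameter: Optional[Measurement] = None
    inf_dv_diameter: Optional[Measurement] = None


@dataclass(frozen=True)
class FacetWidths:
    """Maximum mediolateral spans of the paired articular facets."""

    max_inter_IAF: Optional[Measurement] = None
    max_inter_SAF: Optional[Measurement] = None


@dataclass
class LumbarSeries:
    """Ordered per-level measurements for one specimen's lumbar column.

    ``levels`` maps level labels ("L1".."L5") to
    ``(VertebralBodyGeometry, FacetWidths)`` pairs. Levels must be
    contiguous from the first present level and may not exceed the
    specimen's lumbar count.
    """

    specimen: SpecimenInfo
    levels: dict[str, tuple[VertebralBodyGeometry, FacetWidths]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        unknown = set(self.levels) - set(LEVELS)
        if unknown:
            raise ValidationError(
                f"{self.specimen.specimen_id}: unknown levels {sorted(unknown)}"
            )
        if len(self.levels) > self.specimen.lumbar_count:
            raise ValidationError(
                f"{self.specimen.specimen_id}: {len(self.levels)} levels exceed "
                f"lumbar_count {self.specimen.lumbar_count}"
            )
        present = [lv for lv in LEVELS if lv in self.levels]
        if present:
            first = LEVELS.index(present[0])
            expected = list(LEVELS[first : first + len(present)])
            if present != expected:
                raise ValidationError(
                    f"{self.specimen.specimen_id}: levels {present} are not "
                    "contiguous"
                )

    @property
    def present_levels(self) -> list[str]:
        return [lv for lv in LEVELS if lv in self.levels]

    def geometry(self, level: str) -> VertebralBodyGeometry:
        return self.levels[level][0]

    def facets(self, level: str) -> FacetWidths:
        return self.levels[level][1]

    @property
    def last_lumbar(self) -> str:
        """Label of the last (most caudal) lumbar level of this column."""
        return f"L{self.specimen.lumbar_count}"


@dataclass
class LandmarkConfiguration:
    """A single specimen's ordered 3D landmark configuration (mm)."""

    specimen: SpecimenInfo
    coordinates: np.ndarray  # (k, 3)
    landmark_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValidationError(
                f"{self.specimen.specimen_id}: coordinates must be (k, 3), "
                f"got {self.coordinates.shape}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValidationError(
                f"{self.specimen.specimen_id}: non-finite coordinates"
            )
        self.landmark_labels = tuple(self.landmark_labels)
        if len(self.landmark_labels) != len(self.coordinates):
            raise ValidationError(
                f"{self.specimen.specimen_id}: {len(self.landmark_labels)} labels "
                f"for {len(self.coordinates)} landmarks"
            )

    @property
    def n_landmarks(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class LandmarkSet:
    """Same-cardinality landmark configurations sharing one label order."""

    configurations: list[LandmarkConfiguration]
    landmark_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.landmark_labels = tuple(self.landmark_labels)
        for cfg in self.configurations:
            if cfg.landmark_labels != self.landmark_labels:
                raise ValidationError(
                    f"{cfg.specimen.specimen_id}: landmark labels differ from "
                    "the shared label order"
                )

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self) -> Iterator[LandmarkConfiguration]:
        return iter(self.configurations)

    @property
    def n_landmarks(self) -> int:
        return len(self.landmark_labels)

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen.specimen_id for c in self.configurations]

    @property
    def groups(self) -> list[str]:
        return [c.specimen.group for c in self.configurations]

    def as_array(self) -> np.ndarray:
        """Stack configurations into an (n, k, 3) array."""
        return np.stack([c.coordinates for c in self.configurations])


def default_landmark_labels(k: int) -> tuple[str, ...]:
    """Generic landmark labels ``lm01``..``lmKK``."""
    return tuple(f"lm{i + 1:02d}" for i in range(k))
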