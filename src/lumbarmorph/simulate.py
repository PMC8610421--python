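"""Synthetic measurement tables and landmark datasets.

Two generators make every stage of the pipeline testable without any
external download:

* :func:`gen_measurements` draws per-level wedging angles from
  group-specific normal distributions (defaults transcribed from the
  published extant summaries) and inverts the wedging formula to emit
  well-formed vertebral geometry: with ventral height V and
  dorsoventral length L fixed at baseline values, the dorsal height is
  D = V + L*tan(theta).

* :func:`gen_landmarks` builds 48-landmark configurations as a shared
  stylized template plus group mean-shape offsets, an optional
  allometric component proportional to centroid size, and isotropic
  Gaussian landmark noise — then applies random rigid motions and
  scales so superimposition has genuine work to do.

Both are pure functions of (spec, seed) and return the latent truths
(drawn angles, offset vectors, allometry vector, sizes) alongside the
data so recovery tests read stored truth rather than regenerating it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    FacetWidths,
    LandmarkConfiguration,
    LandmarkSet,
    LumbarSeries,
    Measurement,
    SpecimenInfo,
    VertebralBodyGeometry,
)

__all__ = [
    "MeasurementSimSpec",
    "SimulatedMeasurements",
    "gen_measurements",
    "template_vertebra",
    "PROCESS_LANDMARKS",
    "CORE_LANDMARKS",
    "LandmarkSimSpec",
    "SimulatedLandmarks",
    "gen_landmarks",
]

_SIM_LEVELS = ("L2", "L3", "L4", "L5")


def _default_group_params() -> dict[str, dict[str, tuple[float, float]]]:
    """Per-group, per-level wedging (mean, sd) from the bundled summaries."""
    from .comparative import load_reference_summaries

    table = load_reference_summaries()
    params: dict[str, dict[str, tuple[float, float]]] = {}
    for row in table.itertuples(index=False):
        if row.variable not in _SIM_LEVELS:
            continue
        params.setdefault(row.group, {})[row.variable] = (
            float(row.mean),
            float(row.sd),
        )
    return params


@dataclass
class MeasurementSimSpec:
    """Specification of a synthetic wedging-measurement dataset.

    ``group_params`` maps group -> level -> (mean, sd) in degrees;
    defaults are the published extant summaries. ``baseline_ventral``
    and ``baseline_length`` (mm) fix V and L of every generated body;
    25 mm and 30 mm are typical adult human middle-lumbar dimensions.
    """

    group_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_default_group_params
    )
    n_per_group: int = 30
    baseline_ventral: float = 25.0
    baseline_length: float = 30.0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        if self.baseline_ventral <= 0 or self.baseline_length <= 0:
            raise ValueError("baseline dimensions must be positive")
        for g, levels in self.group_params.items():
            for lv, (_, sd) in levels.items():
                if sd < 0:
                    raise ValueError(f"{g}/{lv}: negative sd")


@dataclass
class SimulatedMeasurements:
    """Generated series plus the latent per-record truth."""

    series: list[LumbarSeries]
    latent: pd.DataFrame  # specimen_id, group, level, theta_deg
    n_redraws: int


def gen_measurements(
    spec: MeasurementSimSpec, seed: Optional[int] = None
) -> SimulatedMeasurements:
    """Draw wedging angles and invert them into vertebral geometry.

    Draws with |theta| >= 90 degrees (impossible for the arctangent
    construction) are redrawn; the redraw count is reported.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    series: list[LumbarSeries] = []
    latent_rows = []
    n_redraws = 0
    v = spec.baseline_ventral
    length = spec.baseline_length
    for group in spec.group_params:
        levels = spec.group_params[group]
        for i in range(spec.n_per_group):
            sid = f"{group}_{i + 1:03d}"
            info = SpecimenInfo(
                specimen_id=sid, taxon=group, group=group, lumbar_count=5
            )
            level_map = {}
            for lv in _SIM_LEVELS:
                if lv not in levels:
                    continue
                mean, sd = levels[lv]
                theta = rng.normal(mean, sd)
                while abs(theta) >= 90.0:
                    n_redraws += 1
                    theta = rng.normal(mean, sd)
                d = v + length * np.tan(np.radians(theta))
                level_map[lv] = (
                    VertebralBodyGeometry(
                        ventral_height=Measurement(v),
                        dorsal_height=Measurement(d),
                        sup_dv_diameter=Measurement(length),
                        inf_dv_diameter=Measurement(length),
                    ),
                    FacetWidths(),
                )
                latent_rows.append(
                    {
                        "specimen_id": sid,
                        "group": group,
                        "level": lv,
                        "theta_deg": float(theta),
                    }
                )
            series.append(LumbarSeries(specimen=info, levels=level_map))
    latent = pd.DataFrame.from_records(latent_rows)
    return SimulatedMeasurements(series=series, latent=latent, n_redraws=n_redraws)


# ---------------------------------------------------------------------------
# Landmark template and generator


def template_vertebra() -> LandmarkConfiguration:
    """A deterministic, stylized 48-landmark lumbar vertebra.

    Axes: x mediolateral, y dorsoventral (+y ventral), z craniocaudal
    (+z cranial); units nominally mm. The template comprises a superior
    and inferior body-rim octagon, body midline points, pedicles,
    superior and inferior articular facets, lamina, and the bases of
    the spinous and costal processes (the 37 "core" landmarks), plus 11
    spinous/costal process shaft-and-tip landmarks (the "process"
    subset dropped in the reduced analysis).
    """
    pts: list[tuple[float, float, float]] = []
    labels: list[str] = []

    def add(label: str, x: float, y: float, z: float) -> None:
        labels.append(label)
        pts.append((x, y, z))

    # vertebral body: superior and inferior rim octagons (ellipse a=16, b=11)
    for ring, z in (("sup", 12.0), ("inf", -12.0)):
        for j in range(8):
            ang = 2 * np.pi * j / 8
            add(f"body_{ring}_{j + 1}", 16.0 * np.cos(ang), 11.0 * np.sin(ang), z)
    add("body_ventral_mid", 0.0, 12.5, 0.0)
    add("body_dorsal_mid", 0.0, -11.5, 0.0)
    # pedicles (left x<0, right x>0), superior and inferior borders
    add("pedicle_sup_L", -12.0, -13.0, 6.0)
    add("pedicle_inf_L", -12.0, -13.0, -4.0)
    add("pedicle_sup_R", 12.0, -13.0, 6.0)
    add("pedicle_inf_R", 12.0, -13.0, -4.0)
    # superior articular facets: cranial tip and caudal base
    add("saf_tip_L", -10.0, -18.0, 14.0)
    add("saf_base_L", -10.0, -17.0, 7.0)
    add("saf_tip_R", 10.0, -18.0, 14.0)
    add("saf_base_R", 10.0, -17.0, 7.0)
    # inferior articular facets
    add("iaf_tip_L", -8.0, -20.0, -14.0)
    add("iaf_base_L", -8.0, -19.0, -7.0)
    add("iaf_tip_R", 8.0, -20.0, -14.0)
    add("iaf_base_R", 8.0, -19.0, -7.0)
    # lamina: left, midline, right
    add("lamina_L", -6.0, -22.0, 0.0)
    add("lamina_mid", 0.0, -23.0, 1.0)
    add("lamina_R", 6.0, -22.0, 0.0)
    # process bases (part of the core subset)
    add("sp_base_sup", 0.0, -24.0, 4.0)
    add("sp_base_inf", 0.0, -24.0, -3.0)
    add("cp_base_L", -14.0, -10.0, 2.0)
    add("cp_base_R", 14.0, -10.0, 2.0)
    assert len(pts) == 37
    # spinous process shaft and tip (3)
    add("sp_shaft", 0.0, -31.0, 0.0)
    add("sp_tip_sup", 0.0, -38.0, 2.0)
    add("sp_tip_inf", 0.0, -38.0, -2.0)
    # costal processes, 4 landmarks each
    for side, sx in (("L", -1.0), ("R", 1.0)):
        add(f"cp_shaft_{side}", sx * 22.0, -9.0, 3.0)
        add(f"cp_tip_sup_{side}", sx * 30.0, -8.0, 5.0)
        add(f"cp_tip_{side}", sx * 31.0, -8.0, 3.5)
        add(f"cp_tip_inf_{side}", sx * 30.0, -8.0, 2.0)
    assert len(pts) == 48

    info = SpecimenInfo(specimen_id="template", taxon="template", group="template")
    return LandmarkConfiguration(
        specimen=info,
        coordinates=np.asarray(pts, dtype=float),
        landmark_labels=tuple(labels),
    )


_TEMPLATE_LABELS = tuple(template_vertebra().landmark_labels)

#: The 11 spinous/costal process landmarks removed in the reduced analysis.
PROCESS_LANDMARKS: tuple[str, ...] = _TEMPLATE_LABELS[37:]

#: The 37 landmarks retained in the reduced analysis.
CORE_LANDMARKS: tuple[str, ...] = _TEMPLATE_LABELS[:37]


@dataclass
class LandmarkSimSpec:
    """Specification of a synthetic landmark dataset.

    ``group_offset_magnitudes`` maps group -> Procrustes-scale magnitude
    of that group's mean-shape displacement (0.05 is a clearly separable
    between-group difference against the default noise). Offset
    directions are drawn from the seeded generator unless supplied in
    ``group_offsets``. ``noise_sd`` is the isotropic per-coordinate
    landmark noise in shape space (unit-centroid-size scale).
    ``allometry_slope`` scales the shared allometric direction per mm of
    centroid size deviation from the mean. Centroid sizes are
    log-normal: log-mean ``size_log_mean`` (default log 180 mm, a
    middle-lumbar vertebra scale), log-sd ``size_log_sd``.
    """

    template: Optional[LandmarkConfiguration] = None
    group_offset_magnitudes: dict[str, float] = field(default_factory=dict)
    group_offsets: dict[str, np.ndarray] = field(default_factory=dict)
    n_per_group: int = 20
    noise_sd: float = 0.01
    allometry_slope: float = 0.0
    allometry_vector: Optional[np.ndarray] = None
    size_log_mean: float = float(np.log(180.0))
    size_log_sd: float = 0.08

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be positive")
        tpl = self.template or template_vertebra()
        if tpl.n_landmarks != 48:
            raise ValueError("template must have 48 landmarks")


@dataclass
class SimulatedLandmarks:
    """Generated landmark set plus latent truth for recovery tests."""

    landmarks: LandmarkSet
    true_shapes: np.ndarray  # (n, k, 3) noise-free shapes, unit-CS scale
    group_offsets: dict[str, np.ndarray]  # group -> (k, 3)
    allometry_vector: Optional[np.ndarray]  # (k, 3) unit Frobenius norm
    sizes: np.ndarray  # (n,) drawn centroid sizes (mm)
    groups: list[str]
    specimen_ids: list[str]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, -1] = -q[:, -1]
    return q


def _unit_shape(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    return c / np.sqrt(np.sum(c**2))


def _random_tangent_direction(
    rng: np.random.Generator, base: np.ndarray
) -> np.ndarray:
    """Random unit direction orthogonal to the base shape (keeps CS ~ 1)."""
    d = rng.normal(size=base.shape)
    d -= d.mean(axis=0)  # stay centered
    d -= base * np.sum(d * base)  # orthogonal to pure rescaling of base
    return d / np.sqrt(np.sum(d**2))


def gen_landmarks(
    spec: LandmarkSimSpec, seed: Optional[int] = None
) -> SimulatedLandmarks:
    """Generate landmark configurations with known latent structure.

    Per specimen: shape = template + group offset + slope*(size - mean
    size)*allometry direction + iid Normal(0, noise_sd^2) per
    coordinate, all in unit-centroid-size shape space; the result is
    then rotated by a random proper rotation, scaled to the drawn
    centroid size, and translated.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    template = spec.template or template_vertebra()
    base = _unit_shape(template.coordinates)
    k = base.shape[0]

    groups = sorted(
        set(spec.group_offset_magnitudes) | set(spec.group_offsets)
    ) or ["A"]
    offsets: dict[str, np.ndarray] = {}
    for g in groups:
        if g in spec.group_offsets:
            offsets[g] = np.asarray(spec.group_offsets[g], dtype=float)
        else:
            mag = spec.group_offset_magnitudes.get(g, 0.0)
            offsets[g] = mag * _random_tangent_direction(rng, base)

    allo = None
    if spec.allometry_slope != 0.0:
        if spec.allometry_vector is not None:
            allo = np.asarray(spec.allometry_vector, dtype=float)
            allo = allo / np.sqrt(np.sum(allo**2))
        else:
            allo = _random_tangent_direction(rng, base)

    n = spec.n_per_group * len(groups)
    sizes = rng.lognormal(spec.size_log_mean, spec.size_log_sd, size=n)
    mean_size = sizes.mean()

    configs = []
    true_shapes = np.empty((n, k, 3))
    group_labels = []
    ids = []
    i = 0
    for g in groups:
        for j in range(spec.n_per_group):
            sid = f"{g}_{j + 1:03d}"
            shape = base + offsets[g]
            if allo is not None:
                shape = shape + spec.allometry_slope * (sizes[i] - mean_size) * allo
            true_shapes[i] = shape
            noisy = shape + rng.normal(0.0, spec.noise_sd, size=(k, 3))
            rot = _random_rotation(rng)
            placed = (noisy @ rot.T) * sizes[i] + rng.uniform(-50, 50, size=3)
            info = SpecimenInfo(specimen_id=sid, taxon=g, group=g)
            configs.append(
                LandmarkConfiguration(
                    specimen=info,
                    coordinates=placed,
                    landmark_labels=template.landmark_labels,
                )
            )
            group_labels.append(g)
            ids.append(sid)
            i += 1
    lms = LandmarkSet(
        configurations=configs, landmark_labels=template.landmark_labels
    )
    return SimulatedLandmarks(
        landmarks=lms,
        true_shapes=true_shapes,
        group_offsets=offsets,
        allometry_vector=allo,
        sizes=sizes,
        groups=group_labels,
        specimen_ids=ids,
    )
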