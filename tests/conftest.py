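import numpy as np
import pytest
from hypothesis import settings

import lumbarmorph as lm

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mh2_series() -> lm.LumbarSeries:
    """The bundled MH2 lumbar measurement table."""
    series = lm.load_mh2_measurements()
    assert len(series) == 1
    return series[0]


@pytest.fixture(scope="session")
def template():
    return lm.template_vertebra()


@pytest.fixture(scope="session")
def two_group_sim():
    """Two groups with a clear mean-shape offset, moderate noise."""
    spec = lm.LandmarkSimSpec(
        group_offset_magnitudes={"A": 0.0, "B": 0.08},
        n_per_group=15,
        noise_sd=0.01,
    )
    return lm.gen_landmarks(spec, seed=20260901)


@pytest.fixture(scope="session")
def two_group_fit(two_group_sim):
    return lm.GeneralizedProcrustes(two_group_sim.landmarks).fit()


def make_geometry(v, d, sup, inf=None):
    """Helper: vertebral body geometry from plain numbers."""
    M = lm.Measurement
    return lm.VertebralBodyGeometry(
        ventral_height=M(v),
        dorsal_height=M(d),
        sup_dv_diameter=M(sup),
        inf_dv_diameter=M(inf if inf is not None else sup),
    )


def series_from_angles(angles_deg, v=25.0, length=30.0, specimen_id="synthetic"):
    """Build a five-lumbar series whose L2..L5 wedging angles are given."""
    info = lm.SpecimenInfo(specimen_id=specimen_id, taxon="x", group="x")
    levels = {}
    for lv, theta in zip(("L2", "L3", "L4", "L5"), angles_deg):
        d = v + length * np.tan(np.radians(theta))
        levels[lv] = (make_geometry(v, d, length), lm.FacetWidths())
    return lm.LumbarSeries(specimen=info, levels=levels)
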