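import pytest
from hypothesis import settings

from perisim.field_geometry import build_grid_30_2

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")
from perisim.field_stats import build_default_sector_map
from perisim.observer_sim import FIXATION, TrueField


@pytest.fixture(scope="session")
def grid_od():
    return build_grid_30_2("OD")


@pytest.fixture(scope="session")
def sector_map_od():
    return build_default_sector_map("OD")


def flat_field(level: float, eye: str = "OD") -> TrueField:
    """A uniform ground-truth field (including fixation) at `level` dB."""
    values = {FIXATION: level}
    for p in build_grid_30_2(eye):
        values[(p.x, p.y)] = level
    return TrueField(eye=eye, values=values)


@pytest.fixture
def flat30():
    return flat_field(30.0)
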