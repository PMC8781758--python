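import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bonebeam.core import (
    SpecimenGeometry,
    StrainRecord,
    bending_moment_from_stress,
    calibrate_E0,
)

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geom() -> SpecimenGeometry:
    """Nominal study geometry: 6 x 6 mm section, 34 mm inner span, a = 4 mm."""
    return SpecimenGeometry()


@pytest.fixture(scope="session")
def baseline_record() -> StrainRecord:
    """Pre-fatigue average strain pair (microstrain)."""
    return StrainRecord(life_fraction_t=0.0, eps_C=2819.0, eps_T=2807.0)


@pytest.fixture(scope="session")
def E0(geom, baseline_record) -> float:
    return calibrate_E0(baseline_record, 66.0, geom)


@pytest.fixture(scope="session")
def moment_meas(geom) -> float:
    """Inner-span bending moment at the 66 MPa measurement stress."""
    return bending_moment_from_stress(66.0, geom)
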