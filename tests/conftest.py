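import math

import pytest
from hypothesis import HealthCheck, settings

from ctpress.leg_geometry import LegModel, circle_section
from ctpress.materials import TissueModel, reference_fabric

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def s1_fabric():
    """Class I ankle tube from the bundled reference batch."""
    return reference_fabric("S1", "I", "B")


@pytest.fixture
def soft_tissue():
    """Stiffest of the three soft-tissue presets (0.003 MPa, incompressible)."""
    return TissueModel.from_modulus(3000.0)


def make_circle_leg(girths, rigidity="rigid", tissue=None, n=720):
    """A leg of circular sections with prescribed girths per position."""
    heights = {"B": 0.04, "B1": 0.12, "C": 0.24, "D": 0.35}
    sections = tuple(
        circle_section(girths[pos] / (2 * math.pi), z=heights[pos], n=n, label=pos)
        for pos in ("B", "B1", "C", "D")
        if pos in girths
    )
    if tissue is None:
        tissue = (
            TissueModel.from_modulus(3.0e9, nu=0.3)
            if rigidity == "rigid"
            else TissueModel.from_modulus(3000.0)
        )
    return LegModel(sections=sections, rigidity=rigidity, tissue=tissue)


@pytest.fixture
def rigid_circle_leg():
    """Rigid mannequin leg with the reference ankle girth 0.2513 m."""
    return make_circle_leg({"B": 0.2513, "B1": 0.28, "C": 0.35, "D": 0.34})
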