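import numpy as np
import pytest

from stentsim.deployment import DeploymentConfig, initial_state
from stentsim.devices import BalloonSpec, design_from_preset
from stentsim.synthetic import (
    AnatomyParams,
    CompositionZone,
    Stenosis,
    generate_bifurcation,
)

#: The reference synthetic case: 3.5->3.0 mm tapered MV, 2.5 mm SB at 60
#: degrees, 60% diameter stenosis of 8 mm length in the distal MV.
STENOSIS = Stenosis("MV", 32.0, 0.6, 8.0)


@pytest.fixture(scope="session")
def stenosed_anatomy():
    return generate_bifurcation(AnatomyParams(stenoses=(STENOSIS,)))


@pytest.fixture(scope="session")
def clean_anatomy():
    """Constant-diameter bifurcation (no taper, no stenosis)."""
    return generate_bifurcation(
        AnatomyParams(proximal_mv_diameter=3.0, distal_mv_diameter=3.0)
    )


@pytest.fixture()
def stenosed_state(stenosed_anatomy):
    return initial_state(stenosed_anatomy)


@pytest.fixture(scope="session")
def mv_stent_design():
    return design_from_preset("integrity_like", diameter_mm=3.0, length_mm=26.0)


@pytest.fixture(scope="session")
def mv_balloon():
    return BalloonSpec(nominal_diameter=3.0, length=26.0, compliance_class="semi_compliant")


def plaque_anatomy(score_sign: int):
    """Stenosed anatomy whose lesion scores -1 (lipid-rich) or +1 (calcific)."""
    fractions = (0.5, 0.5, 0.0) if score_sign < 0 else (0.0, 0.5, 0.5)
    return generate_bifurcation(
        AnatomyParams(
            stenoses=(STENOSIS,),
            composition_zones=(CompositionZone("MV", 28.0, 36.0, fractions),),
        )
    )
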