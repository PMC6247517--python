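import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


from pipfep.potentials import (
    AlchemicalSystem,
    AlchemicalTag,
    HarmonicWell,
    InteractionParams,
)


@pytest.fixture
def harmonic_particle():
    """Single particle in an isotropic lambda-independent harmonic well."""
    return AlchemicalSystem(
        coordinates=np.zeros((1, 3)),
        params=[InteractionParams(epsilon=0.0, sigma=1.0)],
        tags=[AlchemicalTag.UNPERTURBED],
        wells=[[HarmonicWell.isotropic(2.0)]],
    )


@pytest.fixture
def charged_pair():
    """Unperturbed charged LJ pair at 4 A separation, frozen partner."""
    return AlchemicalSystem(
        coordinates=np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]]),
        params=[
            InteractionParams(0.15, 3.2, 0.3),
            InteractionParams(0.2, 3.0, -0.35),
        ],
        tags=[AlchemicalTag.UNPERTURBED, AlchemicalTag.UNPERTURBED],
        wells=[[], [HarmonicWell.isotropic(5.0, center=(4.0, 0.0, 0.0))]],
        mobile=[False, True],
    )
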