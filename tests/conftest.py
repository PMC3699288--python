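import numpy as np
import pytest

from cyanoflux.synth import (
    SIX_POINT_DESIGN,
    CoreModelToggles,
    build_core_model,
)


@pytest.fixture(scope="session")
def core_model():
    """Default synthetic core network (phosphoserine present, TCA bypass)."""
    return build_core_model()


@pytest.fixture(scope="session")
def core_model_all():
    """Core network carrying every TCA-closure variant simultaneously."""
    return build_core_model(CoreModelToggles(tca_variant="all"))


@pytest.fixture(scope="session")
def design_times():
    """The six uneven circadian sampling times, two replicates."""
    return np.tile(np.asarray(SIX_POINT_DESIGN), 2)
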