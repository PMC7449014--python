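import numpy as np
import pytest

from morphoeet import AssayTimeSeries, PhysicalParams


@pytest.fixture(scope="session")
def table_params() -> PhysicalParams:
    """Default physical constants (ferricyanide in BG11 at ~30 C)."""
    return PhysicalParams()


@pytest.fixture
def collinear_assay() -> AssayTimeSeries:
    """Four sampling points constructed to lie exactly on c = 1 - 1e-3 t."""
    return AssayTimeSeries(
        times_min=(0.0, 10.0, 30.0, 120.0),
        concentration_mM=(1.000, 0.990, 0.970, 0.880),
        cell_conc_per_ml=6.78e8,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20200826)
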