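import numpy as np
import pytest

import hemisif as hs


@pytest.fixture(scope="session")
def o2a_constant_model() -> hs.TransmittanceModel:
    """Constant extinction anchored at T=0.924 over a 37.7 m path."""
    return hs.TransmittanceModel.from_calibration(0.924, 37.7)


@pytest.fixture(scope="session")
def o2a_spectral_model() -> hs.TransmittanceModel:
    return hs.TransmittanceModel.o2a_default()


@pytest.fixture(scope="session")
def iso_field() -> hs.DirectionalField:
    return hs.DirectionalField.isotropic(1.0)


@pytest.fixture(scope="session")
def tower_footprint() -> hs.FootprintGrid:
    """Table-case convective footprint on a 1 m grid."""
    return hs.ffp_2d(hs.TOWER_FFP_PARAMS, grid_extent=700.0, grid_step=1.0)


@pytest.fixture(scope="session")
def full_retrieval_comparison() -> hs.RetrievalComparison:
    """Retrieval of the four processing variants over the full 80-scene grid."""
    return hs.run_retrieval_comparison(seed=0)


@pytest.fixture(scope="session")
def full_ertpl_evaluation() -> hs.ErtplEvaluation:
    return hs.run_ertpl_evaluation(seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)
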