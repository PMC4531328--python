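import numpy as np
import pytest

from ionrbe import (
    LetResponse,
    LQParams,
    ZSaturationModel,
    ZSaturationParams,
    load_z_letu_calibration,
)


@pytest.fixture(scope="session")
def calibration():
    """Packaged four-point (z, let_u) calibration table."""
    return load_z_letu_calibration()


@pytest.fixture(scope="session")
def fitted_z_params(calibration) -> ZSaturationParams:
    """Charge-relation parameters fitted to the packaged calibration data."""
    res = ZSaturationModel(calibration["z"], calibration["let_u"]).fit()
    assert res.converged
    return ZSaturationModel.results_to_params(res)


@pytest.fixture
def worked_response() -> LetResponse:
    """The worked-example response: LET_C=1.2, LET_U=120, alpha 0.3->1.3,
    beta 0.046->0.15."""
    return LetResponse(
        let_u=120.0,
        lq_low=LQParams(alpha=0.3, beta=0.046),
        lq_turn=LQParams(alpha=1.3, beta=0.15),
        let_c=1.2,
    )


@pytest.fixture
def barendsen_lq():
    """Low/turnover LQ pairs assessed for the mono-energetic alpha-particle
    survival data (human kidney cells)."""
    return LQParams(alpha=0.16, beta=0.046), LQParams(alpha=1.31, beta=0.15)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150811)
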