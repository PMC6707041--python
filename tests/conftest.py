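import numpy as np
import pytest

from pkprop import (
    NoiseModel,
    PKParamsIM,
    PKParamsIV,
    PKProfile,
    SamplingSchedule,
    Subject,
    bsa_from_weight,
    conc_im,
    conc_iv,
)


@pytest.fixture
def im_params() -> PKParamsIM:
    return PKParamsIM(amplitude=50.0, gamma=6.0, beta=0.5)


@pytest.fixture
def iv_params() -> PKParamsIV:
    return PKParamsIV(A=8.0, B=4.0, alpha=3.0, beta=0.4)


def make_subject(params, route="IM", sid="s1", weight=300.0) -> Subject:
    return Subject(
        subject_id=sid,
        sex="M",
        weight_g=weight,
        bsa_cm2=bsa_from_weight(weight),
        dose_mg_per_kg=20.0,
        route=route,
        true_params=params,
    )


def noiseless_profile(params, times, route="IM", sid="s1") -> PKProfile:
    conc = conc_im(times, params) if route == "IM" else conc_iv(times, params)
    return PKProfile(times=times, concentrations=conc, subject_id=sid)


@pytest.fixture
def dense_im_profile(im_params) -> PKProfile:
    """Noiseless Bateman curve on the 7 s / 3 h sensor grid."""
    return noiseless_profile(im_params, SamplingSchedule.dense_eab().times)


@pytest.fixture
def dense_iv_profile(iv_params) -> PKProfile:
    return noiseless_profile(iv_params, SamplingSchedule.dense_eab().times, route="IV")
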