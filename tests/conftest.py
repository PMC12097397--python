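import pytest

from meows.scoring import EWS, MEOWS, VitalsObservation


@pytest.fixture(scope="session")
def meows():
    return MEOWS


@pytest.fixture(scope="session")
def ews():
    return EWS


@pytest.fixture
def normal_obs():
    """An observation with every parameter in its normal range (scores 0
    under both charts)."""
    return VitalsObservation(
        woman_id="w1",
        timestamp=0.0,
        resp_rate=14,
        spo2=98,
        o2_supplement=False,
        temperature=36.8,
        sbp=120,
        dbp=75,
        heart_rate=80,
        avpu="A",
        vas_pain=2,
    )


@pytest.fixture(scope="session")
def small_cohort_frame():
    """A deterministic 40-woman synthetic cohort table."""
    from meows.synthetic import SyntheticConfig, generate_cohort_frame

    config = SyntheticConfig(n_women=40, prevalence=6 / 40)
    return generate_cohort_frame(config, seed=7)
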