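import numpy as np
import pytest

import rfbreath as rb


@pytest.fixture
def config():
    return rb.PipelineConfig()


@pytest.fixture
def breathing_scenario():
    """One subject breathing at 0.25 Hz under default conditions."""
    return rb.BreathingScenario(subjects=(rb.SubjectSpec(subject_id=1),), seed=11)


def make_single_tag_scenario(rate_hz, seed, noise_sigma=0.02, ambiguity=0.05,
                             amplitude=0.0025, apnea=()):
    place = rb.TagPlacement(rate_hz=rate_hz, amplitude_m=amplitude)
    subject = rb.SubjectSpec(subject_id=1, chest=place, abdomen=place,
                             apnea_intervals=tuple(apnea))
    return rb.BreathingScenario(subjects=(subject,), seed=seed,
                                noise_sigma_rad=noise_sigma,
                                ambiguity_prob=ambiguity)


@pytest.fixture
def chest_epc():
    return rb.encode_epc(1, "chest")
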