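import pytest
from hypothesis import HealthCheck, settings

from braycall import (
    BraySequence,
    ClassifiedElement,
    ElementObservation,
    default_patterns,
    default_ruleset,
)
from braycall.synthetic_data import CLASS_SIGNATURES

settings.register_profile(
    "ci",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rules():
    return default_ruleset()


@pytest.fixture(scope="session")
def patterns():
    return default_patterns()


def make_obs(begin=0.0, dur=0.04, min_freq=295.0, max_freq=773.0,
             peak_freq=None, contour="downsweep", harmonic=False,
             sound_class="pulsed_continuous", site="tyrrhenian"):
    return ElementObservation(
        begin_time=begin, end_time=begin + dur, min_freq=min_freq,
        max_freq=max_freq, peak_freq=peak_freq, contour=contour,
        harmonic=harmonic, sound_class=sound_class, site=site,
    )


#: class -> kwargs producing an in-band observation of that class
CLASS_KWARGS = {
    "GU1": dict(min_freq=295, max_freq=773, dur=0.04),
    "GU2": dict(min_freq=361, max_freq=584, dur=0.04),
    "GU3": dict(min_freq=216, max_freq=541, dur=0.04),
    "GU4": dict(min_freq=592, max_freq=868, dur=0.07),
    "GR1": dict(min_freq=200, max_freq=2000, dur=0.14),
    "GR2": dict(min_freq=200, max_freq=2200, dur=0.14),
    "SQ": dict(min_freq=535, max_freq=892, dur=0.17),
    "POP": dict(min_freq=400, max_freq=2600, dur=0.03, peak_freq=813),
    "CR": dict(min_freq=150, max_freq=7000, dur=0.01, peak_freq=1237),
    "LFN": dict(min_freq=256, max_freq=650, dur=0.084),
}


def typical_obs(cls, begin=0.0, **overrides):
    """An observation with the canonical signature and in-band parameters."""
    sound_class, contour, harmonic = CLASS_SIGNATURES[cls]
    kwargs = dict(CLASS_KWARGS[cls])
    kwargs.update(sound_class=sound_class, contour=contour, harmonic=harmonic,
                  begin=begin, **overrides)
    return make_obs(**kwargs)


def make_seq(labels, begin=0.0, gap=0.4, site="tyrrhenian"):
    """Build a BraySequence from class labels with regular timing."""
    elements = []
    t = begin
    for cls in labels:
        obs = typical_obs(cls, begin=t)
        elements.append(ClassifiedElement(obs, cls))
        t = obs.end_time + gap
    return BraySequence(elements=elements, site=site)


def make_elements(labels, begin=0.0, gap=0.4, site="tyrrhenian"):
    return make_seq(labels, begin=begin, gap=gap, site=site).elements
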