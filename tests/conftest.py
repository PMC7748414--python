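import numpy as np
import pytest
from hypothesis import settings

from lickroc.trials import BLANK, STIMULUS, Session, Trial

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_trial(kind=STIMULUS, licks=(), index=0, contrast=None, led_on=False,
               delay_s=0.25, window_s=4.0):
    if contrast is None:
        contrast = 1.0 if kind == STIMULUS else 0.0
    return Trial(
        index=index, kind=kind, contrast=contrast, led_on=led_on,
        delay_s=delay_s, response_window_s=window_s, lick_times_s=tuple(licks),
    )


def make_session(trials, animal_id="m01", day=1, group="intact"):
    return Session(animal_id=animal_id, day=day, group=group, trials=list(trials))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def profiles():
    from lickroc.synth import default_profiles

    return default_profiles()
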