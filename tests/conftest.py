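import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wmctransit import GutProfile, SciEffect, preset, simulate

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# Short fixture for brute-force comparisons.  The steep small-bowel pH rise
# of a compressed SITT makes the rolling baseline lag ~0.4 pH units, so the
# ileocecal step is deepened to keep the drop criterion decidable at low noise.
SMALL_PROFILE = dict(get_h=1.0, sitt_h=1.2, ctt_h=1.5, dt=5.0, icj_drop=1.6)


@pytest.fixture
def healthy_trace():
    """Default-condition synthetic trace with ground truth."""
    profile, effect = preset("pig_pre", seed=5)
    return simulate(profile, effect)


def small_trace(seed, **overrides):
    """Short (<5000 samples) trace for brute-force comparisons."""
    kw = {**SMALL_PROFILE, **overrides}
    return simulate(GutProfile(seed=seed, **kw))


@pytest.fixture
def flat_pressure_recording():
    from wmctransit import WmcRecording

    t = np.arange(0.0, 600.0, 1.0)
    return WmcRecording(t=t, pressure=np.full(t.size, 5.0), nominal_dt=1.0)
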