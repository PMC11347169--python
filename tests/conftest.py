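import numpy as np
import pytest

from flowstretch.calibration import GEOMETRIES
from flowstretch.segmentation import NoiseProfile
from flowstretch.simulate import PRESETS, TruthInterval, render_plan


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sv40_profile():
    return NoiseProfile(noise_sd_bp=150.0, resolution_bp=200.0)


@pytest.fixture(scope="session")
def leading_geom():
    return GEOMETRIES["leading_ssb"]


def make_plan(*intervals):
    """Build a truth plan from (kind, duration_s, rate_bp_s) triples."""
    plan = []
    t = 0.0
    for kind, dur, rate in intervals:
        plan.append(TruthInterval(kind, t, t + dur, rate, rate * dur))
        t += dur
    return plan


@pytest.fixture(scope="session")
def noise_free_trace(leading_geom):
    """Noise-free trace: 400 bp @5 bp/s, 100 s pause, 300 bp @5 bp/s."""
    plan = make_plan(
        ("baseline", 60.0, 0.0),
        ("event", 80.0, 5.0),
        ("pause", 100.0, 0.0),
        ("event", 60.0, 5.0),
        ("baseline", 60.0, 0.0),
    )
    return render_plan(plan, leading_geom, 0.0, 0, trace_id="clean")


@pytest.fixture(scope="session")
def sv40_ensemble():
    """Small seeded sv40 ensemble with truth, for recovery checks."""
    from flowstretch.simulate import simulate_ensemble

    return simulate_ensemble(PRESETS["sv40_ssb"], 60, seed=2024)
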