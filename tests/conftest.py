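import numpy as np
import pandas as pd
import pytest

import cuewheel as cw


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def e1_session():
    return cw.build_session("E1", n_blocks=7, practice=True, seed=7)


@pytest.fixture(scope="session")
def e2_session():
    return cw.build_session("E2", n_blocks=8, practice=True, seed=7)


@pytest.fixture(scope="session")
def small_e1_dataset():
    """2 subjects x 1 block, default generating parameters."""
    return cw.simulate_experiment(2, "E1", seed=42, n_blocks=1)


def mixture_errors(rng, rho, kappa, n):
    """Directly sampled signed errors (radians) from the generative mixture."""
    encoded = rng.random(n) < rho
    return np.where(
        encoded, rng.vonmises(0.0, kappa, n), rng.uniform(-np.pi, np.pi, n)
    )


@pytest.fixture
def toy_trials():
    """Hand-built 10-trial table: 2 practice, 1 miss, 1 FA, 1 pre-target, 5 hits."""
    base = dict(
        subject_id="S00", experiment="E1", cue_type="valid", cue_symbol="2",
        soa_ms=800, target_present=True, target_side="left",
        target_colour_deg=10.0, wheel_rotation_deg=0.0,
        response_colour_deg=15.0, rt_ms=350.0, outcome="hit",
    )
    rows = []
    for i in range(10):
        r = dict(base, block=1, trial_index=i)
        rows.append(r)
    rows[0].update(block=0)                       # practice
    rows[1].update(block=0)                       # practice
    rows[2].update(outcome="miss", rt_ms=np.nan, response_colour_deg=np.nan)
    rows[3].update(outcome="false_alarm", target_present=False, target_side="none",
                   target_colour_deg=np.nan)
    rows[4].update(outcome="pre_target", rt_ms=-100.0)
    return pd.DataFrame(rows)
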