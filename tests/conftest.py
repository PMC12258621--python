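import numpy as np
import pytest

import rloopkinetics as rk


@pytest.fixture(scope="session")
def ou_baseline():
    """Event-free 2-min baseline trace and its calibrated noise model."""
    cfg = rk.simulate.dspry_config(
        rate_kCI_law=rk.FixedLaw(0.0), duration=120.0, seed=901
    )
    _, baseline = rk.simulate.simulate_experiment(cfg)
    return baseline, rk.calibrate_ou(baseline)


@pytest.fixture(scope="session")
def three_state_run():
    """A 10-min three-state trace with its latent path (500 Hz, sigma 1.5)."""
    cfg = rk.simulate.dspry_config(
        rate_kCI_law=rk.FixedLaw(0.1),
        rate_kIC=0.25,
        rate_kIO=0.25,
        rate_kOI=0.15,
        duration=600.0,
        seed=902,
    )
    path, trace = rk.simulate.simulate_experiment(cfg)
    return cfg, path, trace


def states_from_path(path, levels=None):
    """Exact StateSequence of a latent path (oracle without observation)."""
    from rloopkinetics.states import State, StateSequence

    levels = levels or {"C": 0.0, "I": 10.0, "O": 20.0}
    d = path.dwells()
    seq = StateSequence()
    for row in d.itertuples():
        seq.append(
            State(row.state, levels[row.state], row.dwell_s, row.start_s,
                  row.start_s + row.dwell_s)
        )
    return seq
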