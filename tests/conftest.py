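"""Shared fixtures.

Two tiers: a miniature structural fixture (fast, but the per-connection
coupling is too coarse for functional behaviour), and session-scoped
full-size runs at desk-scale trial counts that several functional and
acceptance tests share.  The heavy fixtures use dt = 0.125 ms (the Poisson
thinning stays valid: ceiling rate x dt = 0.1) and trials of 400 ms with
the published last-250-ms analysis window.
"""

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pytest

from attnet import ModelParams, build_topology, run_attention_task, run_sensory_task, select_control_neurons
from attnet.io import derive_seed, make_fixture
from attnet.protocols import RateData

SUITE_SEED = 90
ACCEPT_DT = 0.125
ATT_KW = dict(duration_ms=400.0, baseline_ms=0.0, window_ms=250.0)
SENS_KW = dict(duration_ms=300.0, baseline_ms=0.0, window_ms=250.0)


@pytest.fixture(scope="session")
def mini_params() -> ModelParams:
    """Miniature network sizes; every physiological constant unchanged."""
    return ModelParams(n_first_per_sub=64, n_second=128, seed=3)


@pytest.fixture(scope="session")
def mini_conn(mini_params):
    return build_topology(mini_params, seed=3)


@pytest.fixture(scope="session")
def mini_trials():
    """Fixture network plus a handful of short stimulated trials."""
    conn, trials = make_fixture(scale=8, seed=3, n_trials=3)
    return conn, trials


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def _concat(a: RateData, b: RateData) -> RateData:
    return RateData(
        np.concatenate([a.rates, b.rates]),
        pd.concat([a.meta, b.meta], ignore_index=True),
    )


@dataclass
class InitRun:
    """One network initialization with its task data."""

    conn: object
    sensory: RateData  # 16-stimulus sensory task (decoder training) or targeting run
    targets: dict
    attention: RateData


@dataclass
class Experiment:
    params: ModelParams
    inits: list = field(default_factory=list)


def _run_init(params, k, sensory_stimuli, sensory_trials, att_trials,
              extras=True):
    conn = build_topology(params, seed=derive_seed(SUITE_SEED, 0, k))
    sensory = run_sensory_task(
        conn, params, seed=derive_seed(SUITE_SEED, 1, k),
        stimuli_deg=sensory_stimuli, n_trials=sensory_trials, **SENS_KW,
    )
    targets = {
        deg: select_control_neurons(sensory, deg, 0.2, params=params)
        for deg in (90.0, 270.0)
    }
    # the gain analysis needs the full strength grid for attend-90 only;
    # attend-270 trials are added at the headline strength 10 so the SVM
    # and circular-decoder analyses have both classes there
    attention = run_attention_task(
        conn, targets, params, seed=derive_seed(SUITE_SEED, 2, k),
        stim_strengths=[float(s) for s in range(1, 12)],
        att_strengths=[0.0, 2.0, 4.0], attended_degs=(90.0,),
        n_trials=att_trials, **ATT_KW,
    )
    if not extras:
        return InitRun(conn, sensory, targets, attention)
    extra = run_attention_task(
        conn, targets, params, seed=derive_seed(SUITE_SEED, 3, k),
        stim_strengths=[10.0], att_strengths=[0.0, 2.0, 4.0, 6.0],
        attended_degs=(270.0,), n_trials=att_trials, **ATT_KW,
    )
    extra6 = run_attention_task(
        conn, targets, params, seed=derive_seed(SUITE_SEED, 4, k),
        stim_strengths=[10.0], att_strengths=[6.0],
        attended_degs=(90.0,), n_trials=att_trials, **ATT_KW,
    )
    return InitRun(conn, sensory, targets, _concat(_concat(attention, extra), extra6))


@pytest.fixture(scope="session")
def experiment() -> Experiment:
    """Two full-size initializations of the random (kappa = 0) network.

    Init 0 runs the full 16-stimulus sensory task (shared by the decoding
    analyses); init 1 runs the two stimuli needed for targeting.  Both run
    the attention grid: stimulus strengths 1-11 x modulation {0, 2, 4}
    (plus {6} at strength 10), both attended stimuli, 10 trials/condition.
    """
    params = ModelParams(dt_ms=ACCEPT_DT)
    exp = Experiment(params=params)
    exp.inits.append(_run_init(params, 0, None, 8, 10))  # 16 stimuli x 8
    exp.inits.append(_run_init(params, 1, [90.0, 270.0], 10, 10, extras=False))
    return exp


@dataclass
class KappaRun:
    kappa: float
    params: ModelParams
    sensory: RateData
    attention: RateData


@pytest.fixture(scope="session")
def kappa_runs() -> list:
    """Structured-connectivity runs (kappa 0.1 and 0.3), one seed each."""
    out = []
    for i, kappa in enumerate((0.1, 0.3)):
        params = ModelParams(dt_ms=ACCEPT_DT, kappa_structure=kappa)
        conn = build_topology(params, seed=derive_seed(SUITE_SEED, 10, i))
        sensory = run_sensory_task(
            conn, params, seed=derive_seed(SUITE_SEED, 11, i),
            n_trials=5, **SENS_KW,
        )
        targets = {
            deg: select_control_neurons(sensory, deg, 0.2, params=params)
            for deg in (90.0, 270.0)
        }
        attention = run_attention_task(
            conn, targets, params, seed=derive_seed(SUITE_SEED, 12, i),
            stim_strengths=[10.0], att_strengths=[0.0, 6.0],
            attended_degs=(90.0, 270.0), n_trials=8, **ATT_KW,
        )
        out.append(KappaRun(kappa, params, sensory, attention))
    return out
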