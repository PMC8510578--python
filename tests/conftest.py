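import numpy as np
import pytest

from larvalearn import GenerativeConfig, simulate_experiment
from larvalearn.data import Decision, ExperimentGroup, LarvaRecord, Outcome, Phase


def make_record(larva_id, group, n_cycles, pre="", post="", next_day=""):
    """Build a LarvaRecord from outcome strings like 'aavva' (a=approach)."""
    rec = LarvaRecord(larva_id=larva_id, group=group, n_cycles=n_cycles)
    for phase, s in ((Phase.PRE, pre), (Phase.POST, post), (Phase.NEXT_DAY, next_day)):
        rec.decisions[phase] = [
            Decision(outcome=Outcome.APPROACH if c == "a" else Outcome.AVOID, index=i)
            for i, c in enumerate(s)
        ]
    return rec


@pytest.fixture(scope="session")
def small_experiment():
    """Three dose groups of 30 simulated larvae each, all-or-none truth."""
    cfg = GenerativeConfig(cycle_doses={0: 30, 2: 30, 20: 30}, seed=11)
    groups, truths = simulate_experiment(cfg)
    return cfg, groups, truths


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
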