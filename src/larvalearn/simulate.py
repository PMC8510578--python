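"""Generative model for nested individual-larva choice data.

The simulator emulates the statistical structure of a dose-response learning
experiment: larvae are grouped by training-cycle count, each larva makes a
serially correlated sequence of binary approach/avoid decisions in an
hour-long PRE phase, receives its dose of training cycles, and makes another
sequence in a POST phase.

Two learning modes are supported:

* ``all_or_none`` — each training cycle independently switches an untrained
  larva to the trained state with probability ``rho``; the expected untrained
  fraction after ``i`` cycles is ``(1 - rho)**i``.  A trained larva's mean
  preference jumps from ``mu_u`` to ``mu_t``.
* ``graded`` — every cycle shifts the larva's latent mean preference by
  ``graded_step`` (clipped to [0, 1]); there are no discrete states.

Serial correlation: larvae that just chose the CO2 channel are less likely to
choose it again at the next junction.  This is modeled as a two-state Markov
chain on the previous choice with approach probabilities ``m - delta_a``
after an APPROACH and ``m + delta_b`` after an AVOID, with
``delta_b = m * delta_a / (1 - m)`` so that the stationary mean is exactly the
target ``m``.  The first decision of a phase is drawn at the marginal mean.

Per-larva random streams are split from the master seed with
``numpy.random.SeedSequence(seed, spawn_key=...)`` so that changing one
group's composition never perturbs the draws of another larva.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml

from .data import Decision, ExperimentGroup, LarvaRecord, Outcome, Phase

__all__ = [
    "GenerativeConfig",
    "SimTruth",
    "analytic_untrained_fraction",
    "markov_choice_sequence",
    "simulate_larva",
    "simulate_experiment",
    "simulate_extinction_block",
    "write_truth_table",
]

#: group sizes of the dose-response design (dose -> number of larvae)
STUDY_DOSE_DESIGN: dict[int, int] = {0: 50, 1: 35, 2: 87, 3: 31, 4: 32, 5: 63, 10: 14, 20: 64}

UNTRAINED = "untrained"
TRAINED = "trained"


@dataclass(frozen=True)
class GenerativeConfig:
    """Parameters of the generative model.

    Defaults are the study conditions: untrained larvae choose the CO2
    channel with mean probability 0.27 and trained larvae with 0.52; a
    training cycle converts an untrained larva with probability ``rho``
    (equivalently the untrained fraction decays as ``lambda = 1 - rho`` per
    cycle); each larva makes a few dozen decisions per hour-long phase.
    """

    mu_u: float = 0.27
    mu_t: float = 0.52
    rho: float = 0.4
    serial_delta: float = 0.08
    decisions_mean: float = 30.0
    decisions_dispersion: float = 8.0
    decisions_min: int = 1
    cycle_doses: dict[int, int] = field(default_factory=lambda: dict(STUDY_DOSE_DESIGN))
    extinction_revert_prob: float = 0.15
    mode: Literal["all_or_none", "graded"] = "all_or_none"
    graded_step: float = 0.0125
    seed: int = 0

    def validate(self) -> None:
        for name in ("mu_u", "mu_t", "rho", "extinction_revert_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.serial_delta < 0:
            raise ValueError("serial_delta must be non-negative")
        for m in (self.mu_u, self.mu_t):
            if 0.0 < m < 1.0:
                delta_b = m * self.serial_delta / (1.0 - m)
                if m - self.serial_delta < 0 or m + delta_b > 1:
                    raise ValueError(
                        f"serial_delta={self.serial_delta} incompatible with mean {m}"
                    )
        if self.decisions_min < 0:
            raise ValueError("decisions_min must be >= 0")
        if self.mode not in ("all_or_none", "graded"):
            raise ValueError(f"unknown mode: {self.mode}")
        if not self.cycle_doses:
            raise ValueError("cycle_doses must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GenerativeConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "cycle_doses" in raw:
            raw["cycle_doses"] = {int(k): int(v) for k, v in raw["cycle_doses"].items()}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        d = self.__dict__.copy()
        path = Path(path)
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    def with_(self, **kw) -> "GenerativeConfig":
        return replace(self, **kw)


@dataclass
class SimTruth:
    """Latent ground truth for one simulated larva.

    ``states`` holds the per-cycle latent trajectory: state labels in
    all-or-none mode, latent means in graded mode.  Entry 0 is the state
    before any training.
    """

    larva_id: str
    mode: str
    states: list

    @property
    def final_state(self):
        return self.states[-1]

    @property
    def is_trained(self) -> bool:
        if self.mode != "all_or_none":
            raise ValueError("is_trained defined only for all_or_none mode")
        return self.final_state == TRAINED


def analytic_untrained_fraction(rho: float, i: int) -> float:
    """Expected untrained fraction after ``i`` cycles of a memoryless
    per-cycle conversion with probability ``rho``: ``(1 - rho)**i``."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho={rho} outside [0, 1]")
    if i < 0:
        raise ValueError("cycle count must be non-negative")
    return (1.0 - rho) ** i


def _markov_probs(mean: float, delta: float) -> tuple[float, float]:
    """(P(approach | prev approach), P(approach | prev avoid)) with stationary
    mean equal to ``mean``."""
    if delta == 0.0 or mean <= 0.0 or mean >= 1.0:
        return mean, mean
    delta_b = mean * delta / (1.0 - mean)
    return mean - delta, mean + delta_b


def markov_choice_sequence(
    mean: float, delta: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` binary choices (1 = approach) from the negatively
    autocorrelated chain with stationary mean ``mean``."""
    if n == 0:
        return np.zeros(0, dtype=np.int8)
    p_after_app, p_after_avoid = _markov_probs(mean, delta)
    u = rng.random(n)
    out = np.empty(n, dtype=np.int8)
    out[0] = u[0] < mean
    for i in range(1, n):
        p = p_after_app if out[i - 1] else p_after_avoid
        out[i] = u[i] < p
    return out


def _n_decisions(config: GenerativeConfig, rng: np.random.Generator) -> int:
    """Per-phase decision count: negative binomial with configured mean and
    dispersion (shape) parameter, floored at the configured minimum."""
    r = config.decisions_dispersion
    mean = config.decisions_mean
    if mean <= 0:
        return config.decisions_min
    p = r / (r + mean)
    return max(int(rng.negative_binomial(r, p)), config.decisions_min)


def _decisions_from_bits(bits: np.ndarray) -> list[Decision]:
    return [
        Decision(outcome=Outcome.APPROACH if b else Outcome.AVOID, index=i)
        for i, b in enumerate(bits)
    ]


def simulate_larva(
    config: GenerativeConfig, dose: int, rng: np.random.Generator, larva_id: str = "sim"
) -> tuple[LarvaRecord, SimTruth]:
    """Simulate one larva: PRE choices, latent state evolution over ``dose``
    training cycles, then POST choices at the post-training mean."""
    config.validate()
    rec = LarvaRecord(larva_id=larva_id, group=f"dose_{dose}", n_cycles=dose)

    n_pre = _n_decisions(config, rng)
    rec.decisions[Phase.PRE] = _decisions_from_bits(
        markov_choice_sequence(config.mu_u, config.serial_delta, n_pre, rng)
    )

    if config.mode == "all_or_none":
        states: list = [UNTRAINED]
        for _ in range(dose):
            if states[-1] == UNTRAINED and rng.random() < config.rho:
                states.append(TRAINED)
            else:
                states.append(states[-1])
        post_mean = config.mu_t if states[-1] == TRAINED else config.mu_u
    else:
        states = [config.mu_u + min(k, dose) * config.graded_step for k in range(dose + 1)]
        states = [float(np.clip(s, 0.0, 1.0)) for s in states]
        post_mean = states[-1]

    n_post = _n_decisions(config, rng)
    # cap the serial offset so transition probabilities stay in [0, 1]
    delta = min(config.serial_delta, post_mean, 1.0 - post_mean) if 0 < post_mean < 1 else 0.0
    rec.decisions[Phase.POST] = _decisions_from_bits(
        markov_choice_sequence(post_mean, delta, n_post, rng)
    )
    truth = SimTruth(larva_id=larva_id, mode=config.mode, states=states)
    return rec, truth


def simulate_extinction_block(
    record: LarvaRecord,
    truth: SimTruth,
    n_unrewarded: int,
    config: GenerativeConfig,
    rng: np.random.Generator,
) -> SimTruth:
    """Apply ``n_unrewarded`` CS-only cycles: a trained larva reverts to the
    untrained state with per-cycle probability ``extinction_revert_prob``;
    untrained larvae are unaffected.  No choices are scored during the block.
    """
    if truth.mode != "all_or_none":
        raise ValueError("extinction reversion is defined for all_or_none truth")
    states = list(truth.states)
    for _ in range(n_unrewarded):
        if states[-1] == TRAINED and rng.random() < config.extinction_revert_prob:
            states.append(UNTRAINED)
        else:
            states.append(states[-1])
    return SimTruth(larva_id=truth.larva_id, mode=truth.mode, states=states)


def _larva_rng(seed: int, dose_index: int, larva_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(seed, spawn_key=(dose_index, larva_index))
    return np.random.Generator(np.random.PCG64(ss))


def simulate_experiment(
    config: GenerativeConfig,
) -> tuple[list[ExperimentGroup], list[SimTruth]]:
    """Simulate the full dose-response design: one group per entry of
    ``config.cycle_doses``.  Deterministic given ``config.seed``."""
    config.validate()
    groups: list[ExperimentGroup] = []
    truths: list[SimTruth] = []
    for d_idx, (dose, n_larvae) in enumerate(sorted(config.cycle_doses.items())):
        group = ExperimentGroup(
            name=f"dose_{dose}", protocol={"n_cycles": dose, "mode": config.mode}
        )
        for j in range(n_larvae):
            rng = _larva_rng(config.seed, d_idx, j)
            rec, truth = simulate_larva(config, dose, rng, larva_id=f"d{dose}_l{j:04d}")
            group.larvae.append(rec)
            truths.append(truth)
        groups.append(group)
    return groups, truths


def write_truth_table(truths: Sequence[SimTruth], path: str | Path) -> Path:
    """Sidecar export ``larva_id,final_state`` for recovery tests."""
    path = Path(path)
    lines = ["larva_id,final_state"]
    for t in truths:
        lines.append(f"{t.larva_id},{t.final_state}")
    path.write_text("\n".join(lines) + "\n")
    return path
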