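"""Trial sequencing: single trials, replicates, and replicate batches.

A trial presents two randomly drawn compound stimuli, lets the learner
choose by soft-max over its estimated values, delivers a noisy reward for
the chosen stimulus, updates the learner on the chosen stimulus's features
only, and records everything.  Phase transitions are silent to the learner:
weights, rates and traces carry over unannounced, which is exactly the kind
of volatility the simulations probe.

Each replicate is an independent individual: fresh learner, independent
child RNG stream spawned from the root seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import learners, stimuli_env
from .learners import LearnerState, make_learner
from .stimuli_env import Phase, Scenario, build_scenario, expected_reward

__all__ = ["TrialRecord", "ExperimentConfig", "run_trial", "run_replicate", "run_experiment"]


@dataclass(frozen=True)
class TrialRecord:
    """Everything observed in one trial; w/alpha are post-update snapshots."""

    replicate: int
    trial: int  # 1-based, global across phases
    phase: int  # 1-based
    type1: str
    type2: str
    chosen_index: int  # 1 or 2
    correct: bool  # chose the stimulus with the higher expected reward (ties correct)
    V_chosen: float  # expected reward of the chosen stimulus
    V_max: float  # max expected reward available in the trial
    Q_chosen: float  # learner's pre-update estimate for the chosen stimulus
    R: float  # delivered reward
    w: np.ndarray
    alpha: np.ndarray


@dataclass(frozen=True)
class ExperimentConfig:
    """A full experiment: scenario, learner, replicate count and seeding."""

    scenario: str = "case1"
    scenario_overrides: dict[str, Any] = field(default_factory=dict)
    learner: str = "constant"
    alpha0: float = learners.DEFAULT_ALPHA0
    w0: float = 0.0
    mu: float = learners.DEFAULT_MU
    tau: float = learners.DEFAULT_TAU
    omega: float = learners.DEFAULT_OMEGA
    n_replicates: int = 100
    seed: int = 1
    block_size: int = 10

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be positive")
        if self.learner not in ("constant", "flexible"):
            raise ValueError(f"unknown learner kind {self.learner!r}")

    def build_scenario(self) -> Scenario:
        return build_scenario(self.scenario, **self.scenario_overrides)

    def build_learner(self, M: int) -> LearnerState:
        return make_learner(
            self.learner, M, alpha0=self.alpha0, w0=self.w0, mu=self.mu, tau=self.tau
        )


def _stimulus_value(stype_id: str, V_raw: float, phase: Phase) -> float:
    """True expected reward of a realized stimulus in the current phase."""
    if phase.reward_map is not None:
        return expected_reward(float(phase.reward_map[stype_id]))
    return expected_reward(V_raw)


def run_trial(
    scenario: Scenario,
    phase: Phase,
    state: LearnerState,
    rng: np.random.Generator,
    omega: float = learners.DEFAULT_OMEGA,
    replicate: int = 0,
    trial: int = 1,
    phase_index: int = 1,
) -> tuple[TrialRecord, LearnerState]:
    """Run one trial and update the learner in place."""
    active = [scenario.types[t] for t in phase.active]
    t1, t2 = stimuli_env.sample_pair(active, rng, scenario.allow_same_type)
    s1 = stimuli_env.realize(t1, scenario, rng)
    s2 = stimuli_env.realize(t2, scenario, rng)
    V1 = _stimulus_value(t1.id, s1.V, phase)
    V2 = _stimulus_value(t2.id, s2.V, phase)

    Q1 = learners.predict(state, s1.x)
    Q2 = learners.predict(state, s2.x)
    outcome = learners.choose(Q1, Q2, omega, rng)
    if outcome.chosen_index == 1:
        x_c, V_c, Q_c = s1.x, V1, Q1
    else:
        x_c, V_c, Q_c = s2.x, V2, Q2
    V_max = max(V1, V2)

    R = stimuli_env.reward(V_c, scenario.sigma_R, rng, scenario.median_preserving)
    learners.update(state, x_c, R)

    record = TrialRecord(
        replicate=replicate,
        trial=trial,
        phase=phase_index,
        type1=t1.id,
        type2=t2.id,
        chosen_index=outcome.chosen_index,
        correct=V_c == V_max,
        V_chosen=V_c,
        V_max=V_max,
        Q_chosen=Q_c,
        R=R,
        w=state.w.copy(),
        alpha=state.alpha.copy(),
    )
    return record, state


def run_replicate(
    scenario: Scenario,
    state: LearnerState,
    rng: np.random.Generator,
    omega: float = learners.DEFAULT_OMEGA,
    replicate: int = 0,
) -> list[TrialRecord]:
    """One individual's full pass through every phase of a scenario."""
    records: list[TrialRecord] = []
    trial = 0
    for phase_index, phase in enumerate(scenario.phases, start=1):
        for _ in range(phase.n_trials):
            trial += 1
            rec, state = run_trial(
                scenario, phase, state, rng, omega,
                replicate=replicate, trial=trial, phase_index=phase_index,
            )
            records.append(rec)
    return records


def records_to_frame(records: list[TrialRecord], M: int) -> pd.DataFrame:
    """Flatten trial records into a DataFrame (one row per trial)."""
    n = len(records)
    w = np.empty((n, M))
    alpha = np.empty((n, M))
    cols: dict[str, Any] = {
        "replicate": np.empty(n, dtype=int),
        "trial": np.empty(n, dtype=int),
        "phase": np.empty(n, dtype=int),
        "type1": np.empty(n, dtype=object),
        "type2": np.empty(n, dtype=object),
        "chosen_index": np.empty(n, dtype=int),
        "correct": np.empty(n, dtype=bool),
        "V_chosen": np.empty(n),
        "V_max": np.empty(n),
        "Q_chosen": np.empty(n),
        "R": np.empty(n),
    }
    for i, r in enumerate(records):
        for key in cols:
            cols[key][i] = getattr(r, key)
        w[i] = r.w
        alpha[i] = r.alpha
    df = pd.DataFrame(cols)
    for m in range(M):
        df[f"w_{m + 1}"] = w[:, m]
    for m in range(M):
        df[f"alpha_{m + 1}"] = alpha[:, m]
    return df


def replicate_seeds(root_seed: int, n_replicates: int) -> list[np.random.SeedSequence]:
    """Independent child seed sequences, one per replicate."""
    return np.random.SeedSequence(root_seed).spawn(n_replicates)


def run_experiment(config: ExperimentConfig, progress=None) -> pd.DataFrame:
    """Run all replicates of an experiment and return the pooled records.

    Replicates use independent child RNG streams spawned from the root
    seed, so any subset of replicates can be reproduced in isolation.
    ``progress``, if given, is called with the number of completed
    replicates after each one.
    """
    scenario = config.build_scenario()
    seeds = replicate_seeds(config.seed, config.n_replicates)
    records: list[TrialRecord] = []
    for r, seed in enumerate(seeds):
        state = config.build_learner(scenario.M)
        rng = np.random.default_rng(seed)
        records.extend(
            run_replicate(scenario, state, rng, omega=config.omega, replicate=r)
        )
        if progress is not None:
            progress(r + 1)
    return records_to_frame(records, scenario.M)
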