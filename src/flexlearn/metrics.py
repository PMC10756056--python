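"""Performance summaries: block averages, RMSE, reward-loss percentages.

The central performance measure is the *proportion of reward gained*: per
trial, the expected reward of the chosen stimulus divided by the maximum
expected reward available in that trial, ``V_chosen / V_max``.  Losses are
``100 * (1 - proportion of reward)``.  Two aggregation conventions are
supported: the mean of the per-trial ratios (``per_trial``) and the ratio
of summed rewards (``ratio_of_sums``); they differ only in how trials with
small denominators are weighted.

``frozen_policy_eval`` scores a non-learning policy with fixed weights —
e.g. an individual that keeps choosing on stimulus size alone after the
world has become more complex — against the same loss measure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import learners, stimuli_env
from .stimuli_env import Scenario

__all__ = [
    "block_summaries",
    "rmse",
    "loss_over_window",
    "frozen_policy_eval",
    "trials_to_criterion",
]


def _prop_reward(V_chosen: np.ndarray, V_max: np.ndarray) -> np.ndarray:
    """Per-trial reward proportion; a trial with nothing to gain counts as 1."""
    out = np.ones_like(np.asarray(V_chosen, dtype=float))
    nz = np.asarray(V_max) > 0
    out[nz] = np.asarray(V_chosen)[nz] / np.asarray(V_max)[nz]
    return out


def block_summaries(records: pd.DataFrame, block_size: int = 10) -> pd.DataFrame:
    """Per-block averages pooled across replicates.

    Blocks are consecutive groups of ``block_size`` trials on the global
    trial index.  Returns one row per block with mean learning rates and
    weights per dimension, proportion correct, proportion of reward, and
    the RMSE of the learner's estimate for the chosen stimulus.  A final
    partial block (trial count not divisible by the block size) is kept and
    flagged in the ``partial`` column.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    df = records.copy()
    df["block"] = (df["trial"] - 1) // block_size + 1
    df["prop_reward"] = _prop_reward(df["V_chosen"].to_numpy(), df["V_max"].to_numpy())
    df["sq_err"] = (df["Q_chosen"] - df["V_chosen"]) ** 2

    dim_cols = [c for c in df.columns if c.startswith(("alpha_", "w_"))]
    agg = {c: (c, "mean") for c in dim_cols}
    agg.update(
        phase=("phase", "min"),
        prop_correct=("correct", "mean"),
        prop_reward=("prop_reward", "mean"),
        mse=("sq_err", "mean"),
        n_trials=("trial", "nunique"),
    )
    out = df.groupby("block").agg(**agg).reset_index()
    out["rmse"] = np.sqrt(out.pop("mse"))
    out["partial"] = out["n_trials"] < block_size
    ordered = ["block", "phase", "n_trials", "partial", "prop_correct", "prop_reward", "rmse"]
    return out[ordered + dim_cols]


def rmse(records: pd.DataFrame) -> float:
    """Root mean square deviation of the estimate Q from the true value V
    of the chosen stimulus, over the given window of trial records."""
    if len(records) == 0:
        raise ValueError("empty window")
    err = records["Q_chosen"].to_numpy() - records["V_chosen"].to_numpy()
    return float(np.sqrt(np.mean(err**2)))


def _phase_window(records: pd.DataFrame, phase: int, n_trials: int) -> pd.DataFrame:
    in_phase = records[records["phase"] == phase]
    if len(in_phase) == 0:
        raise ValueError(f"no trials in phase {phase}")
    start = int(in_phase["trial"].min())
    phase_len = int(in_phase["trial"].max()) - start + 1
    if n_trials > phase_len:
        raise ValueError(f"window of {n_trials} exceeds phase length {phase_len}")
    return in_phase[in_phase["trial"] < start + n_trials]


def loss_over_window(
    records: pd.DataFrame,
    first_n_post_change_trials: int,
    phase: int = 2,
    method: str = "per_trial",
) -> float:
    """Reward-loss percentage over the first trials after a phase change.

    ``100 * (1 - proportion of reward)`` over the window pooled across
    replicates; ``method`` selects the mean of per-trial ratios
    (``per_trial``) or the ratio of sums (``ratio_of_sums``).
    """
    win = _phase_window(records, phase, first_n_post_change_trials)
    Vc = win["V_chosen"].to_numpy()
    Vm = win["V_max"].to_numpy()
    if method == "per_trial":
        prop = float(np.mean(_prop_reward(Vc, Vm)))
    elif method == "ratio_of_sums":
        prop = float(Vc.sum() / Vm.sum())
    else:
        raise ValueError(f"unknown loss method {method!r}")
    return 100.0 * (1.0 - prop)


def frozen_policy_eval(
    w_frozen: np.ndarray,
    scenario: Scenario,
    phase: int,
    n_trials: int,
    rng: np.random.Generator,
    omega: float = learners.DEFAULT_OMEGA,
    choice_rule: str = "greedy",
    method: str = "ratio_of_sums",
    allow_same_type: bool | None = None,
) -> float:
    """Loss percentage of a non-learning policy with fixed weights.

    Simulates ``n_trials`` independent trials of the given phase: both
    stimuli are realized, the policy scores them as ``Q = w_frozen . x``
    and chooses either the larger score (``greedy``) or by soft-max
    (``softmax``); no learning takes place.  ``w_frozen`` shorter than the
    scenario's dimensionality is zero-padded.

    The defaults (greedy choice, ratio-of-sums loss, the scenario's own
    pair sampling) are the convention under which the size-only baseline
    reproduces the reference reward-loss levels; all three switches are
    exposed for sensitivity analysis.
    """
    w = np.zeros(scenario.M)
    w_frozen = np.asarray(w_frozen, dtype=float)
    w[: w_frozen.size] = w_frozen
    if choice_rule not in ("greedy", "softmax"):
        raise ValueError(f"unknown choice rule {choice_rule!r}")
    same = scenario.allow_same_type if allow_same_type is None else allow_same_type

    ph = scenario.phases[phase - 1]
    active = [scenario.types[t] for t in ph.active]
    Vc = np.empty(n_trials)
    Vm = np.empty(n_trials)
    for t in range(n_trials):
        t1, t2 = stimuli_env.sample_pair(active, rng, same)
        s1 = stimuli_env.realize(t1, scenario, rng)
        s2 = stimuli_env.realize(t2, scenario, rng)
        if ph.reward_map is not None:
            V1 = stimuli_env.expected_reward(float(ph.reward_map[t1.id]))
            V2 = stimuli_env.expected_reward(float(ph.reward_map[t2.id]))
        else:
            V1 = stimuli_env.expected_reward(s1.V)
            V2 = stimuli_env.expected_reward(s2.V)
        Q1 = float(s1.x @ w)
        Q2 = float(s2.x @ w)
        if choice_rule == "greedy":
            pick1 = Q1 >= Q2
        else:
            pick1 = rng.random() < learners.choice_probability(Q1, Q2, omega)
        Vc[t] = V1 if pick1 else V2
        Vm[t] = max(V1, V2)
    if method == "per_trial":
        prop = float(np.mean(_prop_reward(Vc, Vm)))
    elif method == "ratio_of_sums":
        prop = float(Vc.sum() / Vm.sum())
    else:
        raise ValueError(f"unknown loss method {method!r}")
    return 100.0 * (1.0 - prop)


def trials_to_criterion(
    records: pd.DataFrame,
    threshold: float = 0.8,
    block_size: int = 10,
) -> dict[int, int | None]:
    """First block (1-based, within phase) whose pooled proportion correct
    reaches the threshold, per phase; ``None`` if never reached."""
    out: dict[int, int | None] = {}
    for phase, grp in records.groupby("phase"):
        start = int(grp["trial"].min())
        blocks = (grp["trial"] - start) // block_size + 1
        prop = grp.groupby(blocks)["correct"].mean()
        hit = prop[prop >= threshold]
        out[int(phase)] = int(hit.index[0]) if len(hit) else None
    return out
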