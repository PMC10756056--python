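"""Headline reward-loss computations for the complex-world transition.

Six quantities summarize how costly the transition to the 10-stimulus
world (case 2) is, and what ignoring the new stimulus dimensions would
cost: post-change losses of the flexible and constant learners over the
first 250 and 500 phase-2 trials, and the per-trial loss of a frozen
size-only policy in phase 2 of cases 1 and 2.

``REFERENCE`` holds the published values these computations are compared
against; everything in ``headline_losses`` is recomputed from scratch.
"""

from __future__ import annotations

import numpy as np

from .engine import ExperimentConfig, run_experiment
from .metrics import frozen_policy_eval, loss_over_window
from .stimuli_env import build_scenario

__all__ = ["REFERENCE", "headline_losses"]

#: published reward-loss percentages for the six headline quantities
REFERENCE = {
    "case2_flexible_loss_250": 7.5,
    "case2_constant_loss_250": 11.0,
    "case2_flexible_loss_500": 4.1,
    "case2_constant_loss_500": 6.6,
    "case1_size_only_loss": 7.4,
    "case2_size_only_loss": 22.0,
}


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent integer sub-seeds (< 2^31) derived from a root seed."""
    return [int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(seed).generate_state(n)]


def headline_losses(
    seed: int = 1,
    n_replicates: int = 100,
    baseline_trials: int = 100_000,
) -> dict[str, dict[str, float | int]]:
    """Recompute the six headline losses; returns ``{name: {value, n}}``.

    The learner losses run the full case-2 experiment (two phases of 1000
    trials) for ``n_replicates`` individuals per learner and average the
    per-trial reward proportion over the post-change window.  The frozen
    size-only baselines simulate ``baseline_trials`` independent phase-2
    trials with weights fixed at the phase-1 truth (size weight 1, all
    else 0), greedy size comparison and ratio-of-sums loss.
    """
    s_flex, s_const, s_b1, s_b2 = _child_seeds(seed, 4)
    out: dict[str, dict[str, float | int]] = {}

    for learner, exp_seed in (("flexible", s_flex), ("constant", s_const)):
        df = run_experiment(
            ExperimentConfig(
                scenario="case2", learner=learner, n_replicates=n_replicates, seed=exp_seed
            )
        )
        for n in (250, 500):
            out[f"case2_{learner}_loss_{n}"] = {
                "value": loss_over_window(df, n, phase=2, method="per_trial"),
                "n": n_replicates * n,
            }

    w_size_only = np.array([1.0])  # zero-padded to the scenario's 10 dimensions
    for case, bseed in (("case1", s_b1), ("case2", s_b2)):
        loss = frozen_policy_eval(
            w_size_only,
            build_scenario(case),
            phase=2,
            n_trials=baseline_trials,
            rng=np.random.default_rng(bseed),
        )
        out[f"{case}_size_only_loss"] = {"value": loss, "n": baseline_trials}
    return out
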