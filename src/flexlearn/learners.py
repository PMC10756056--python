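"""Learning mechanisms: constant-rate delta rule and Autostep meta-learning.

Both learners maintain one estimated value ``w_m`` per stimulus dimension
and predict the value of a compound as the additive sum over the features
present, ``Q = sum_m x_m w_m``.  After receiving reward ``R`` the estimate
of every present feature moves by the prediction error ``delta = R - Q``
scaled by a per-dimension learning rate ``alpha_m``:

    w_m' = w_m + alpha_m * delta * x_m

The *constant* learner (Rescorla-Wagner) keeps ``alpha_m`` fixed.  The
*flexible* learner (Autostep, a robust refinement of the IDBD
delta-bar-delta family) adapts ``alpha_m`` multiplicatively on the log
scale, driven by the correlation between the current weight change and a
decaying trace ``h_m`` of recent weight changes: consistent same-sign
changes (the estimate is tracking a moved target) grow the rate, while
alternating signs (the estimate is dithering around a stable target) shrink
it.  A per-dimension normalizer ``v_m`` makes the meta-update scale-free,
and an effective-rate normalization keeps ``sum_m alpha_m x_m^2 <= 1`` so a
single update can never overshoot the target.

Choices between two compounds use the soft-max rule
``p1 = 1 / (1 + exp(-omega (Q1 - Q2)))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LearnerState",
    "ChoiceOutcome",
    "make_learner",
    "predict",
    "choice_probability",
    "choose",
    "rw_update",
    "autostep_update",
    "update",
    "DEFAULT_ALPHA0",
    "DEFAULT_MU",
    "DEFAULT_TAU",
    "DEFAULT_OMEGA",
]

DEFAULT_ALPHA0 = 0.04  # initial learning rate: unit value differences learned over 50-100 trials
DEFAULT_MU = 0.2  # Autostep meta learning rate (log-scale step for alpha)
DEFAULT_TAU = 1e4  # Autostep normalizer time scale
DEFAULT_OMEGA = 5.0  # soft-max sharpness


@dataclass
class LearnerState:
    """Mutable learner state.

    ``h`` (recent-update trace) and ``v`` (meta-update normalizer) are only
    carried by the flexible learner; ``alpha`` of a constant learner never
    changes after construction.
    """

    kind: str  # "constant" | "flexible"
    w: np.ndarray
    alpha: np.ndarray
    h: np.ndarray | None = None
    v: np.ndarray | None = None
    mu: float = DEFAULT_MU
    tau: float = DEFAULT_TAU

    @property
    def M(self) -> int:
        return self.w.size

    def copy(self) -> "LearnerState":
        return LearnerState(
            kind=self.kind,
            w=self.w.copy(),
            alpha=self.alpha.copy(),
            h=None if self.h is None else self.h.copy(),
            v=None if self.v is None else self.v.copy(),
            mu=self.mu,
            tau=self.tau,
        )


@dataclass(frozen=True)
class ChoiceOutcome:
    p1: float
    chosen_index: int  # 1 or 2


def make_learner(
    kind: str,
    M: int,
    alpha0: float = DEFAULT_ALPHA0,
    w0: float = 0.0,
    mu: float = DEFAULT_MU,
    tau: float = DEFAULT_TAU,
) -> LearnerState:
    """Fresh learner with uniform initial rates and estimates."""
    if kind not in ("constant", "flexible"):
        raise ValueError(f"unknown learner kind {kind!r}")
    if M < 1:
        raise ValueError("need at least one dimension")
    if alpha0 <= 0:
        raise ValueError("alpha0 must be positive")
    if mu < 0 or tau <= 0:
        raise ValueError("mu must be >= 0 and tau > 0")
    flexible = kind == "flexible"
    return LearnerState(
        kind=kind,
        w=np.full(M, float(w0)),
        alpha=np.full(M, float(alpha0)),
        h=np.zeros(M) if flexible else None,
        v=np.zeros(M) if flexible else None,
        mu=mu,
        tau=tau,
    )


def predict(state: LearnerState, x: np.ndarray) -> float:
    """Estimated compound value Q = sum_m x_m w_m."""
    x = np.asarray(x, dtype=float)
    if x.shape != state.w.shape:
        raise ValueError(f"feature vector length {x.size} != {state.M} dimensions")
    return float(x @ state.w)


def choice_probability(Q1: float, Q2: float, omega: float = DEFAULT_OMEGA) -> float:
    """Soft-max probability of choosing option 1."""
    return float(1.0 / (1.0 + np.exp(-omega * (Q1 - Q2))))


def choose(
    Q1: float, Q2: float, omega: float = DEFAULT_OMEGA, rng: np.random.Generator | None = None
) -> ChoiceOutcome:
    """Sample a choice between two estimated values under the soft-max rule."""
    if rng is None:
        rng = np.random.default_rng()
    p1 = choice_probability(Q1, Q2, omega)
    chosen = 1 if rng.random() < p1 else 2
    return ChoiceOutcome(p1=p1, chosen_index=chosen)


def rw_update(state: LearnerState, x: np.ndarray, R: float) -> LearnerState:
    """Constant-rate delta-rule update (in place).

    Absent features (x_m = 0) are untouched; the quantitative dimension's
    change scales with the feature magnitude, since w_m is the estimated
    reward per unit of the dimension.
    """
    if state.kind != "constant":
        raise ValueError("rw_update applies to constant-rate learners")
    x = np.asarray(x, dtype=float)
    delta = R - predict(state, x)
    state.w += state.alpha * delta * x
    return state


def autostep_update(state: LearnerState, x: np.ndarray, R: float) -> LearnerState:
    """Autostep update (in place): adapt rates, then weights, then the trace.

    For each present feature, in order:

    1. normalizer:  v <- max(|delta x h|, v + (alpha x^2 / tau)(|delta x h| - v))
    2. rate (log scale, if v > 0):  alpha <- alpha * exp(mu delta x h / v)
    3. effective-rate normalization:  alpha <- alpha / max(sum alpha x^2, 1)
    4. weight:  w <- w + alpha delta x
    5. trace:  h <- h max(0, 1 - alpha x^2) + alpha delta x

    Dimensions with x_m = 0 are left bit-identical.
    """
    if state.kind != "flexible":
        raise ValueError("autostep_update applies to flexible-rate learners")
    x = np.asarray(x, dtype=float)
    delta = R - predict(state, x)
    act = x != 0.0
    if not act.any():
        return state

    xa = x[act]
    xa2 = xa * xa
    corr = delta * xa * state.h[act]  # current-change x recent-change correlate
    abs_corr = np.abs(corr)
    v = state.v[act]
    v = np.maximum(abs_corr, v + (state.alpha[act] * xa2 / state.tau) * (abs_corr - v))
    state.v[act] = v

    alpha = state.alpha[act]
    pos = v > 0
    alpha[pos] = alpha[pos] * np.exp(state.mu * corr[pos] / v[pos])
    alpha /= max(float(alpha @ xa2), 1.0)
    state.alpha[act] = alpha

    step = alpha * delta * xa
    state.w[act] += step
    state.h[act] = state.h[act] * np.maximum(0.0, 1.0 - alpha * xa2) + step
    return state


def update(state: LearnerState, x: np.ndarray, R: float) -> LearnerState:
    """Dispatch to the learner's update rule."""
    if state.kind == "constant":
        return rw_update(state, x, R)
    return autostep_update(state, x, R)
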