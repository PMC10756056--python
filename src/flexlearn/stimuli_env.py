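"""Stimulus dimensions, compound stimuli, scenario schedules and reward noise.

The learning environments simulated here are built from *compound stimuli*:
multi-dimensional stimuli (think of a client fish at a cleaning station)
described by one quantitative dimension (body size, log-normally distributed
within a stimulus type) and a number of absence/presence (0/1) feature
dimensions (colorful or not, pectoral-fin swimming or not, ...).  Each
dimension ``m`` carries a true expected reward per unit, ``W_m``, and the
true expected reward of a compound is additive, ``V = sum_m W_m * x_m``.

Ten canonical compound-stimulus types (CS1..CS10) over ten dimensions are
shipped as a CSV table (``data/stimulus_table.csv``); the two-phase "transition to a
more complex world" scenarios draw their stimuli from it.  Two further
scenario families — serial reversal learning and learning-set formation —
use purely binary stimuli whose reward (1 or 0) is assigned per phase by an
explicit reward map rather than by dimension values.

Rewards are log-normal around the true expected value with log-scale
standard deviation ``sigma_R``; the noise is mean-preserving by default so
that the average delivered reward equals ``V``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DimensionSpec",
    "StimulusType",
    "RealizedStimulus",
    "Phase",
    "Scenario",
    "stimulus_table",
    "stimulus_dimensions",
    "stimulus_types",
    "size_draw",
    "realize",
    "sample_pair",
    "expected_reward",
    "reward",
    "build_scenario",
    "SCENARIO_NAMES",
]

#: floor applied to a non-positive realized expected value before reward
#: noise (log-normal noise is undefined for V <= 0; the event is rare,
#: ~0.4% of size draws for the negative-feature types).
V_FLOOR = 0.01


@dataclass(frozen=True)
class DimensionSpec:
    """One stimulus dimension: its kind and true expected reward per unit."""

    index: int  # 1-based, as in the stimulus table
    kind: str  # "quantitative" | "binary"
    true_value: float  # W_m

    def __post_init__(self) -> None:
        if self.kind not in ("quantitative", "binary"):
            raise ValueError(f"unknown dimension kind {self.kind!r}")
        if self.index < 1:
            raise ValueError("dimension index is 1-based")


@dataclass(frozen=True)
class StimulusType:
    """A compound-stimulus template.

    ``size_mean`` is the arithmetic mean of the quantitative (size)
    dimension for this type (0.0 if the scenario has no size dimension) and
    ``features`` the fixed 0/1 pattern over the remaining dimensions.
    """

    id: str
    size_mean: float
    features: tuple[float, ...]

    def template(self, has_size_dim: bool) -> np.ndarray:
        """Full feature vector with the size dimension at its mean."""
        if has_size_dim:
            return np.concatenate(([self.size_mean], self.features))
        return np.asarray(self.features, dtype=float)


@dataclass(frozen=True)
class RealizedStimulus:
    """A sampled stimulus instance: feature vector and true expected value.

    ``V`` is the raw additive value ``sum_m W_m x_m``; the expected
    *delivered* reward is ``expected_reward(V)`` (clamped at a small
    positive floor, or exactly 0 for unrewarded map entries).
    """

    type_id: str
    x: np.ndarray
    V: float


@dataclass(frozen=True)
class Phase:
    """A block of trials with a fixed active stimulus set.

    ``reward_map`` assigns the true expected reward per type id; ``None``
    means the reward derives from the dimension values (complex-world
    scenarios).
    """

    n_trials: int
    active: tuple[str, ...]
    reward_map: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("phase needs n_trials > 0")
        if len(self.active) < 2:
            raise ValueError("phase needs at least two active stimulus types")


@dataclass(frozen=True)
class Scenario:
    name: str
    dimensions: tuple[DimensionSpec, ...]
    types: Mapping[str, StimulusType]
    phases: tuple[Phase, ...]
    sigma_x: float = 0.0
    sigma_R: float = 0.0
    allow_same_type: bool = False
    median_preserving: bool = False

    def __post_init__(self) -> None:
        if self.sigma_x < 0 or self.sigma_R < 0:
            raise ValueError("noise SDs must be non-negative")

    @property
    def M(self) -> int:
        return len(self.dimensions)

    @property
    def has_size_dim(self) -> bool:
        return self.dimensions[0].kind == "quantitative"

    @property
    def W(self) -> np.ndarray:
        return np.array([d.true_value for d in self.dimensions])

    @property
    def n_trials(self) -> int:
        return sum(p.n_trials for p in self.phases)

    def phase_of_trial(self, trial: int) -> int:
        """1-based phase index of a 1-based global trial index."""
        upto = 0
        for i, p in enumerate(self.phases, start=1):
            upto += p.n_trials
            if trial <= upto:
                return i
        raise ValueError(f"trial {trial} beyond scenario length {upto}")

    def phase_start(self, phase: int) -> int:
        """1-based global index of the first trial of a 1-based phase."""
        return 1 + sum(p.n_trials for p in self.phases[: phase - 1])


def stimulus_table() -> pd.DataFrame:
    """The canonical stimulus table (rows = dimensions, CS1..CS10 columns)."""
    with resources.files("flexlearn.data").joinpath("stimulus_table.csv").open() as fh:
        return pd.read_csv(fh)


def stimulus_dimensions() -> tuple[DimensionSpec, ...]:
    """The ten stimulus dimensions with their true per-unit values W_m."""
    tab = stimulus_table()
    return tuple(
        DimensionSpec(
            index=int(row.dim),
            kind="quantitative" if int(row.dim) == 1 else "binary",
            true_value=float(row.value),
        )
        for row in tab.itertuples()
    )


def stimulus_types() -> list[StimulusType]:
    """The ten compound-stimulus templates CS1..CS10."""
    tab = stimulus_table()
    out = []
    for cs in [c for c in tab.columns if c.startswith("CS")]:
        col = tab[cs].to_numpy(dtype=float)
        out.append(StimulusType(id=cs, size_mean=float(col[0]), features=tuple(col[1:])))
    return out


def size_draw(
    mean_target: float, sigma_x: float, rng: np.random.Generator
) -> float:
    """Log-normal size draw whose arithmetic mean equals ``mean_target``.

    Returns ``exp(y + z)`` with ``z ~ Normal(0, sigma_x^2)`` and
    ``y = ln(mean_target) - sigma_x^2 / 2``, so ``E[draw] = mean_target``.
    """
    if mean_target <= 0:
        raise ValueError("mean_target must be positive")
    if sigma_x == 0:
        return float(mean_target)
    z = rng.normal(0.0, sigma_x)
    return float(mean_target * np.exp(z - sigma_x**2 / 2))


def realize(
    stype: StimulusType,
    scenario: Scenario,
    rng: np.random.Generator,
) -> RealizedStimulus:
    """Sample a stimulus instance of the given type within a scenario.

    The size dimension (if the scenario has one) is drawn log-normally
    around the type's mean; binary features are copied from the template.
    ``V`` is the additive value under the scenario's dimension values; if
    the current phase assigns rewards by map, the caller overrides it.
    """
    x = stype.template(scenario.has_size_dim)
    if scenario.has_size_dim and stype.size_mean > 0:
        x = x.copy()
        x[0] = size_draw(stype.size_mean, scenario.sigma_x, rng)
    V = float(x @ scenario.W)
    return RealizedStimulus(type_id=stype.id, x=x, V=V)


def sample_pair(
    active: Sequence[StimulusType],
    rng: np.random.Generator,
    allow_same_type: bool = False,
) -> tuple[StimulusType, StimulusType]:
    """Draw the two stimulus types presented in a trial.

    By default the two types are distinct, uniform over ordered distinct
    pairs (equivalently: uniform over unordered pairs with randomized
    presentation order).  With ``allow_same_type`` the two types are
    independent uniform draws, so the same type can appear twice.
    """
    n = len(active)
    if n < 2:
        raise ValueError("need at least two active stimulus types")
    i = int(rng.integers(n))
    if allow_same_type:
        j = int(rng.integers(n))
    else:
        j = (i + 1 + int(rng.integers(n - 1))) % n
    return active[i], active[j]


def expected_reward(V: float, floor: float = V_FLOOR) -> float:
    """Expected delivered reward for a realized value.

    Exactly-zero values (unrewarded stimuli in the reversal and
    learning-set schedules) yield zero; positive values pass through;
    negative values are clamped to a small positive floor so that
    log-normal noise is defined.
    """
    if V == 0.0:
        return 0.0
    return max(V, floor)


def reward(
    V: float,
    sigma_R: float,
    rng: np.random.Generator,
    median_preserving: bool = False,
    floor: float = V_FLOOR,
) -> float:
    """Stochastic reward: log-normal around the expected value.

    Mean-preserving by default, ``R = V * exp(z - sigma_R^2/2)`` with
    ``z ~ Normal(0, sigma_R^2)``; with ``median_preserving`` the half-variance
    correction is dropped.  ``V = 0`` delivers exactly 0.
    """
    if sigma_R < 0:
        raise ValueError("sigma_R must be non-negative")
    base = expected_reward(V, floor)
    if base == 0.0:
        return 0.0
    if sigma_R == 0:
        return float(base)
    z = rng.normal(0.0, sigma_R)
    shift = 0.0 if median_preserving else sigma_R**2 / 2
    return float(base * np.exp(z - shift))


def _binary_pair_types(n_dims: int, pairs: Sequence[tuple[int, int]]) -> dict[str, StimulusType]:
    """One-hot stimulus types for reversal / learning-set schedules.

    ``pairs`` lists (rewarded_dim, unrewarded_dim) 1-based dimension pairs;
    the types are named ``D<dim>`` after the dimension carrying the feature.
    """
    types: dict[str, StimulusType] = {}
    for a, b in pairs:
        for d in (a, b):
            feats = [0.0] * n_dims
            feats[d - 1] = 1.0
            types[f"D{d}"] = StimulusType(id=f"D{d}", size_mean=0.0, features=tuple(feats))
    return types


SCENARIO_NAMES = (
    "case1",
    "case2",
    "case3",
    "case4",
    "case5",
    "case6",
    "case1_long",
    "case2_long",
    "reversal",
    "learning_set",
)

# complex-world family: (active set size in phase 2, sigma_R, trials/phase)
_COMPLEX = {
    "case1": (4, 0.10, 1000),
    "case2": (10, 0.10, 1000),
    "case3": (4, 0.50, 1000),
    "case4": (10, 0.50, 1000),
    "case5": (4, 0.50, 10_000),
    "case6": (10, 0.50, 10_000),
    "case1_long": (4, 0.10, 10_000),
    "case2_long": (10, 0.10, 10_000),
}


def build_scenario(name: str, **overrides) -> Scenario:
    """Construct a named scenario schedule.

    Complex-world cases have a simple phase (CS1-CS2) followed by a complex
    phase (CS1-CS4 or CS1-CS10).  ``reversal`` swaps a 1/0 reward pair every
    100 trials (4 phases); ``learning_set`` presents a fresh pair of
    dimensions every 100 trials (4 phases of a 4-pair series).  Keyword
    overrides replace Scenario fields (e.g. ``sigma_R=0.5``,
    ``allow_same_type=True``).
    """
    if name in _COMPLEX:
        n_phase2, sigma_R, T = _COMPLEX[name]
        types = {t.id: t for t in stimulus_types()}
        order = [f"CS{i}" for i in range(1, 11)]
        # the two stimuli of a trial are drawn independently from the
        # phase's types (the same type can appear twice); the reversal and
        # learning-set schedules instead present a fixed distinct pair
        scenario = Scenario(
            name=name,
            dimensions=stimulus_dimensions(),
            types=types,
            phases=(
                Phase(T, ("CS1", "CS2")),
                Phase(T, tuple(order[:n_phase2])),
            ),
            sigma_x=0.25,
            sigma_R=sigma_R,
            allow_same_type=True,
        )
    elif name == "reversal":
        types = _binary_pair_types(2, [(1, 2)])
        dims = tuple(DimensionSpec(i, "binary", 0.0) for i in (1, 2))
        phases = tuple(
            Phase(
                100,
                ("D1", "D2"),
                reward_map={"D1": 1.0, "D2": 0.0} if k % 2 == 0 else {"D1": 0.0, "D2": 1.0},
            )
            for k in range(4)
        )
        scenario = Scenario(
            name=name, dimensions=dims, types=types, phases=phases, sigma_x=0.0, sigma_R=0.02
        )
    elif name == "learning_set":
        pairs = [(1, 2), (3, 4), (5, 6), (7, 8)]
        types = _binary_pair_types(8, pairs)
        dims = tuple(DimensionSpec(i, "binary", 0.0) for i in range(1, 9))
        phases = tuple(
            Phase(100, (f"D{a}", f"D{b}"), reward_map={f"D{a}": 1.0, f"D{b}": 0.0})
            for a, b in pairs
        )
        scenario = Scenario(
            name=name, dimensions=dims, types=types, phases=phases, sigma_x=0.0, sigma_R=0.02
        )
    else:
        raise ValueError(f"unknown scenario {name!r}; known: {SCENARIO_NAMES}")

    if overrides:
        valid = set(Scenario.__dataclass_fields__)
        bad = set(overrides) - valid
        if bad:
            raise ValueError(f"unknown scenario overrides: {sorted(bad)}")
        scenario = replace(scenario, **overrides)
    return scenario
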