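"""Online target selection by continuous cost-to-go comparison.

Each candidate goal (option) carries its own quadratic cost structure and a
scalar reward bias.  At every step the expected cost-to-go of every option
is evaluated on the *same* current state estimate — with that option's goal
values substituted into the target block — and the command of the cheapest
option is applied.  When another option's value crosses below the current
one, the controller switches goal mid-movement: a change of mind.

Reward enters as an inverse-reward cost bias s0 added to the terminal
scalar: options at highly rewarded locations get a *small* s0.  For
redundant rectangular targets the reward varies along the redundant axis as
a piecewise quadratic; the rectangle is discretized into a fan of point
options, one per location, each biased by the local s0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .control import ControlSolution, TargetSpec, target_vector, with_target

__all__ = [
    "RewardModel",
    "OptionSet",
    "DecisionTrace",
    "reward_bias",
    "evaluate_options",
    "select_option",
    "discretize_rectangle",
    "switch_time",
]


@dataclass
class RewardModel:
    """Reward (as inverse-cost bias s0) over targets or along a rectangle.

    Kinds
    -----
    ``uniform``          all options equally rewarded (s0 = 0 everywhere)
    ``center_advantage`` the central option is more rewarding: off-center
                         options are biased by ``bias_scale`` (default 5e-2)
    ``rect_symmetric``   s0(x) = −10 x² + 0.025  (both extremities cheapest)
    ``rect_left_bias``   s0(x) = −15 x² + 0.0375 (x<0) / −5 x² + 0.0375 (x≥0)
    ``rect_right_bias``  mirror image of the left bias

    ``x`` is the transverse position in meters, centered on the rectangle;
    all distributions are clamped at zero below.
    """

    kind: str = "uniform"
    bias_scale: float = 5e-2

    _KINDS = ("uniform", "center_advantage", "rect_symmetric",
              "rect_left_bias", "rect_right_bias")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown reward model {self.kind!r}")


def reward_bias(model: RewardModel, x: float) -> float:
    """Inverse-reward cost bias s0 at transverse position ``x`` (m)."""
    if model.kind == "uniform":
        return 0.0
    if model.kind == "center_advantage":
        return model.bias_scale if abs(x) > 1e-12 else 0.0
    if model.kind == "rect_symmetric":
        val = -10.0 * x * x + 0.025
    elif model.kind == "rect_left_bias":
        val = (-15.0 if x < 0 else -5.0) * x * x + 0.0375
    else:  # rect_right_bias
        val = (-5.0 if x < 0 else -15.0) * x * x + 0.0375
    return max(0.0, val)


@dataclass
class OptionSet:
    """Candidate targets with their control solutions over a shared horizon."""

    options: list[TargetSpec]
    solutions: list[ControlSolution] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.options:
            raise ValueError("OptionSet needs at least one option")
        if self.solutions and len(self.solutions) != len(self.options):
            raise ValueError("one ControlSolution per option required")
        self._targets8 = [target_vector(t) for t in self.options]

    def __len__(self) -> int:
        return len(self.options)

    def target8(self, i: int) -> np.ndarray:
        return self._targets8[i]


def evaluate_options(option_set: OptionSet, x_hat: np.ndarray, t: int) -> np.ndarray:
    """Cost-to-go of every option on the same current estimate.

    ``v^i = x̂_iᵀ S_t^i x̂_i + s_t^i`` where x̂_i is the estimate with option
    i's goal values written into the target block.
    """
    values = np.empty(len(option_set))
    for i, sol in enumerate(option_set.solutions):
        xi = with_target(x_hat, option_set.target8(i))[: sol.dim]
        values[i] = float(xi @ sol.S[t] @ xi + sol.s[t])
    return values


def select_option(values: np.ndarray, current: int, hysteresis: float = 0.0) -> int:
    """Index of the smallest cost-to-go; exact ties keep the current option.

    ``hysteresis`` (default 0) requires a challenger to undercut the current
    option's value by that margin before a switch is granted.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("cost-to-go values must be finite")
    best = int(np.argmin(values))
    if values[current] <= values[best] + hysteresis:
        return current
    return best


@dataclass
class DecisionTrace:
    """Per-step record of the decision layer over one trial."""

    values: np.ndarray          # (T, n_options) cost-to-go per option
    chosen: np.ndarray          # (T,) selected option index
    switch_events: list[tuple[int, int, int]] = field(default_factory=list)  # (step, from, to)

    @property
    def final_option(self) -> int:
        return int(self.chosen[-1])

    @classmethod
    def from_series(cls, values: np.ndarray, chosen: np.ndarray) -> "DecisionTrace":
        chosen = np.asarray(chosen, dtype=int)
        events = [(int(t), int(chosen[t - 1]), int(chosen[t]))
                  for t in range(1, len(chosen)) if chosen[t] != chosen[t - 1]]
        return cls(values=np.asarray(values, dtype=float), chosen=chosen,
                   switch_events=events)


def switch_time(trace: DecisionTrace) -> int | None:
    """First step of a sustained change of mind, or ``None``.

    The step at which the chosen option first moves away from the initial
    option and never reverts to it before the horizon.
    """
    chosen = trace.chosen
    initial = int(chosen[0])
    away = np.nonzero(chosen != initial)[0]
    if away.size == 0:
        return None
    # last step still on the initial option bounds the sustained departure
    last_on_initial = np.nonzero(chosen == initial)[0][-1]
    if last_on_initial > away[-1]:
        return None
    return int(last_on_initial + 1)


def discretize_rectangle(target: TargetSpec, model: RewardModel, K: int = 21) -> OptionSet:
    """Fan a redundant rectangle into ``K`` reward-biased point options.

    Options span the rectangle's transverse extent evenly; each gets the
    local inverse-reward bias ``s0(x)`` (x measured from the rectangle
    center) as its terminal cost offset, and the rectangle's forward
    coordinate and accuracy weights.
    """
    if target.shape != "rectangle":
        raise ValueError("discretize_rectangle expects a rectangle target")
    if K < 2:
        raise ValueError("need at least two candidate locations")
    cx, cy = target.position
    xs = np.linspace(-target.half_width, target.half_width, K)
    options = [
        TargetSpec(
            position=(cx + x, cy), shape="point", w1=target.w1,
            velocity_weight=target.velocity_weight,
            reward_bias=reward_bias(model, x),
            label=f"x={cx + x:+.3f}",
        )
        for x in xs
    ]
    return OptionSet(options=options)
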