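"""Finite-horizon LQG backward recursion, cost-to-go, and per-step replanning.

The optimal policy for cost

    J = Σ_t ( x_tᵀ Q_t x_t + u_tᵀ R u_t )

is linear state feedback ``u_t = −L_t x̂_t`` with gains from the backward
Riccati recursion

    L_t     = (R + Bᵀ S_{t+1} B)⁻¹ Bᵀ S_{t+1} A
    S_t     = Q_t + Aᵀ S_{t+1} (A − B L_t)
    s_t     = s_{t+1} + tr(S_{t+1} Σ_m),      S_N = Q_N, s_N = r_N

and the expected cost-to-go under that policy is the decision variable

    v̂(x̂, t) = x̂ᵀ S_t x̂ + s_t.

A terminal reward enters only through the scalar boundary value
``s_N = r_N`` (r_N is an inverse-reward *cost* bias): it offsets every s_t by
the same constant and leaves all gains and cost matrices untouched, which is
what lets reward reshape decisions without reshaping control.

Time-varying task parameters (e.g. a target whose width changes mid-reach)
are handled by :func:`replan`: at every step the recursion is re-run over the
remaining horizon with the currently known parameters and only the first
gain is applied, as in model-predictive control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .plant import CORE_DIM, IDX, LinearPlant

__all__ = [
    "CostSchedule",
    "ControlSolution",
    "TargetSpec",
    "WidthSchedule",
    "build_terminal_Q",
    "width_weight",
    "lqr_backward",
    "backward_recursion",
    "cost_to_go",
    "control_command",
    "replan",
    "target_vector",
    "with_target",
]


@dataclass
class CostSchedule:
    """Quadratic cost specification over a horizon of ``N`` steps.

    ``Q`` is either the terminal penalty matrix alone (running penalties
    zero, the default task structure: only the end point is constrained) or
    a sequence of ``N + 1`` per-step matrices ``Q_0 … Q_N``; the cost-to-go
    at step t includes Q_t applied to the current state.
    """

    Q: np.ndarray | Sequence[np.ndarray]
    R: np.ndarray
    N: int
    terminal_bias: float = 0.0

    def q_at(self, t: int) -> np.ndarray:
        if isinstance(self.Q, np.ndarray) and self.Q.ndim == 2:
            dim = self.Q.shape[0]
            return self.Q if t == self.N else np.zeros((dim, dim))
        return np.asarray(self.Q[t], dtype=float)

    @property
    def dim(self) -> int:
        q = self.q_at(self.N)
        return q.shape[0]

    def validate(self) -> None:
        if self.N < 1:
            raise ValueError("horizon N must be >= 1")
        R = np.asarray(self.R, dtype=float)
        if not np.allclose(R, R.T) or np.min(np.linalg.eigvalsh(R)) <= 0:
            raise ValueError("R must be symmetric positive definite")
        for t in range(1, self.N + 1):
            Qt = self.q_at(t)
            if not np.allclose(Qt, Qt.T) or np.min(np.linalg.eigvalsh(Qt)) < -1e-10:
                raise ValueError(f"Q at step {t} must be symmetric PSD")


@dataclass
class ControlSolution:
    """Gains and cost-to-go terms over a horizon.

    Attributes
    ----------
    L : (N, m, n) array — feedback gains, ``u_t = −L[t] x̂``
    S : (N + 1, n, n) array — cost matrices
    s : (N + 1,) array — scalar offsets (noise cost + terminal reward bias)
    """

    L: np.ndarray
    S: np.ndarray
    s: np.ndarray

    @property
    def N(self) -> int:
        return self.L.shape[0]

    @property
    def dim(self) -> int:
        return self.S.shape[1]


def lqr_backward(
    A: np.ndarray,
    B: np.ndarray,
    schedule: CostSchedule,
    Sigma_m: np.ndarray | None = None,
) -> ControlSolution:
    """Backward Riccati recursion on an arbitrary linear system."""
    schedule.validate()
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    n, m = B.shape
    N = schedule.N
    R = np.asarray(schedule.R, dtype=float)
    if Sigma_m is None:
        Sigma_m = np.zeros((n, n))

    L = np.empty((N, m, n))
    S = np.empty((N + 1, n, n))
    noise_acc = np.zeros(N + 1)  # expected future-noise cost, bias-free
    S[N] = schedule.q_at(N)
    for t in range(N - 1, -1, -1):
        St1 = S[t + 1]
        L[t] = np.linalg.solve(R + B.T @ St1 @ B, B.T @ St1 @ A)
        S[t] = schedule.q_at(t) + A.T @ St1 @ (A - B @ L[t])
        S[t] = (S[t] + S[t].T) / 2
        noise_acc[t] = noise_acc[t + 1] + (
            float(np.trace(St1 @ Sigma_m)) if np.any(Sigma_m) else 0.0)
    # the terminal reward bias enters as a single final addition so that it
    # shifts every offset by exactly the same float
    s = noise_acc + schedule.terminal_bias
    return ControlSolution(L=L, S=S, s=s)


def backward_recursion(plant: LinearPlant, schedule: CostSchedule) -> ControlSolution:
    """Riccati recursion on a built plant.

    A schedule whose matrices are 16-dim runs on the plant's core block
    (the delayed copies never feed back into it and carry no cost, so the
    full-dimension solution is the core solution padded with zeros); a
    full-dimension schedule runs on the augmented matrices.
    """
    if schedule.dim == CORE_DIM:
        return lqr_backward(plant.A_core, plant.B_core, schedule, plant.Sigma_m_core)
    if schedule.dim == plant.dim:
        return lqr_backward(plant.A, plant.B, schedule, plant.Sigma_m)
    raise ValueError(
        f"schedule dimension {schedule.dim} matches neither the core ({CORE_DIM}) "
        f"nor the augmented ({plant.dim}) state"
    )


def cost_to_go(solution: ControlSolution, x_hat: np.ndarray, t: int) -> float:
    """Evaluate ``v̂(x̂, t) = x̂ᵀ S_t x̂ + s_t``.

    ``x_hat`` longer than the solution dimension is truncated to its leading
    block (the cost matrices are supported there).
    """
    if not 0 <= t <= solution.N:
        raise ValueError(f"step {t} outside [0, {solution.N}]")
    x = np.asarray(x_hat, dtype=float)[: solution.dim]
    return float(x @ solution.S[t] @ x + solution.s[t])


def control_command(solution: ControlSolution, x_hat: np.ndarray, t: int) -> np.ndarray:
    """Optimal command ``u_t = −L_t x̂_t``."""
    if not 0 <= t < solution.N:
        raise ValueError(f"step {t} outside [0, {solution.N})")
    x = np.asarray(x_hat, dtype=float)[: solution.dim]
    return -solution.L[t] @ x


# ---------------------------------------------------------------------------
# Task structure: targets, width schedules, terminal costs
# ---------------------------------------------------------------------------

@dataclass
class WidthSchedule:
    """Time course of the transverse accuracy weight w2(t).

    ``condition``:

    * ``static`` — constant ``pre_value`` (0 for a wide target);
    * ``switch`` — step from ``pre_value`` to ``post_value`` at schedule
      time 0;
    * ``slow`` / ``fast`` — sigmoidal growth
      ``c · w2_base / (1 + exp((midpoint − t)/slope))`` with prefactor
      c = 0.001 (slow) or 0.01 (fast); the fast weight is exactly ten times
      the slow one at every instant.

    Schedule time ``t`` counts integration steps from the (delayed) onset of
    the structural change; callers apply the 15-step update delay before
    evaluating.
    """

    condition: str = "static"
    w2_base: float = 100.0
    midpoint: float = 10.0
    slope: float = 3.0
    update_delay: int = 15
    pre_value: float = 0.0
    post_value: float | None = None

    _PREFACTORS = {"slow": 0.001, "fast": 0.01}

    def __post_init__(self) -> None:
        if self.condition not in ("static", "switch", "slow", "fast"):
            raise ValueError(f"unknown width condition {self.condition!r}")
        if self.condition == "switch" and self.post_value is None:
            self.post_value = self.w2_base


def width_weight(schedule: WidthSchedule, t: float) -> float:
    """Evaluate the transverse weight at schedule time ``t`` (steps)."""
    if schedule.condition == "static":
        return schedule.pre_value
    if schedule.condition == "switch":
        return schedule.post_value if t >= 0 else schedule.pre_value
    c = WidthSchedule._PREFACTORS[schedule.condition]
    return c * schedule.w2_base / (1.0 + np.exp((schedule.midpoint - t) / schedule.slope))


@dataclass
class TargetSpec:
    """A candidate goal: position, accuracy structure, and reward bias.

    ``w1`` weights the forward (y) end-point accuracy and, for point/narrow
    targets, the transverse (x) accuracy too.  ``w2`` is the transverse
    weight of wide/rectangle targets (0 leaves the x end point
    unconstrained); it may be a :class:`WidthSchedule` for targets whose
    structure changes during the movement.  ``reward_bias`` is the inverse
    reward r_N added to the terminal scalar s_N: less rewarding options get
    a larger (more costly) bias.
    """

    position: tuple[float, float] = (0.0, 0.25)
    shape: str = "point"
    w1: float = 1.0
    w2: float | WidthSchedule = 0.0
    velocity_weight: float = 1.0
    reward_bias: float = 0.0
    half_width: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.shape not in ("point", "narrow", "wide", "rectangle"):
            raise ValueError(f"unknown target shape {self.shape!r}")
        if min(self.w1, self.velocity_weight) < 0:
            raise ValueError("weights must be non-negative")
        if isinstance(self.w2, (int, float)) and self.w2 < 0:
            raise ValueError("weights must be non-negative")
        if self.shape == "rectangle" and not self.half_width:
            raise ValueError("rectangle targets need a transverse half_width")

    def transverse_weight(self, t: float = 0.0) -> float:
        if self.shape in ("point", "narrow"):
            return self.w1
        if isinstance(self.w2, WidthSchedule):
            return width_weight(self.w2, t)
        return float(self.w2)


def target_vector(target: TargetSpec) -> np.ndarray:
    """8-vector of goal values: at the target position, at rest, no forces."""
    vec = np.zeros(8)
    vec[IDX["px"]] = target.position[0]
    vec[IDX["py"]] = target.position[1]
    return vec


def with_target(x: np.ndarray, target8: np.ndarray) -> np.ndarray:
    """Copy of an augmented (or core) state with every target half replaced.

    The estimator treats the goal block as known input; evaluating an
    option's cost-to-go or control law substitutes that option's goal values
    into the state estimate.
    """
    x = np.asarray(x, dtype=float).copy()
    for start in range(0, x.shape[0], CORE_DIM):
        x[start + 8:start + 16] = target8
    return x


def build_terminal_Q(target: TargetSpec, t: float = 0.0, dim: int = CORE_DIM) -> np.ndarray:
    """Terminal state penalty as a quadratic form on the augmented state.

    Penalizes end-point position error component-wise — weight ``w1`` on the
    forward axis, the (possibly time-varying) transverse weight on x — and
    terminal velocity, all expressed through differences between the
    physical and target blocks so the form is homogeneous.
    """
    wx = target.transverse_weight(t)
    terms = [
        (IDX["py"], target.w1),
        (IDX["px"], wx),
        (IDX["vx"], target.velocity_weight),
        (IDX["vy"], target.velocity_weight),
    ]
    Q = np.zeros((dim, dim))
    for idx, w in terms:
        if w == 0:
            continue
        a = np.zeros(dim)
        a[idx] = 1.0
        a[idx + 8] = -1.0
        Q += w * np.outer(a, a)
    return Q


def replan(
    plant: LinearPlant,
    q_terminal: np.ndarray,
    R: np.ndarray,
    remaining_N: int,
    terminal_bias: float = 0.0,
    q_running: Callable[[int], np.ndarray] | None = None,
) -> ControlSolution:
    """Re-solve the control problem over the remaining horizon.

    Model-predictive use: called once per step with the currently known task
    parameters and the decremented horizon; the caller applies only the
    first gain ``L[0]`` and reads ``S[0]``, ``s[0]`` for the cost-to-go.
    With time-invariant parameters the per-step first gains reproduce the
    single offline solution exactly.
    """
    if remaining_N < 1:
        raise ValueError("remaining horizon must be >= 1")
    if q_running is None:
        Q = q_terminal
    else:
        Q = [q_running(k) for k in range(remaining_N)] + [q_terminal]
    schedule = CostSchedule(Q=Q, R=R, N=remaining_N, terminal_bias=terminal_bias)
    return backward_recursion(plant, schedule)
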