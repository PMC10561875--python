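"""Preset builders and the trial/batch runner for the simulated experiments.

Five presets reproduce the classes of reaching experiments the model
addresses:

* ``narrow_wide_switch`` — a goal whose width steps from narrow to wide (or
  back) mid-movement, with an optional lateral force pulse;
* ``continuous_width``   — the transverse accuracy weight follows a slow or
  fast sigmoid, an instantaneous switch, or stays static;
* ``triple_target``      — three potential goals (center nearer than the two
  laterals), lateral force in {−10, −5, 0, 5, 10} N, equal or
  center-advantaged rewards;
* ``rectangle_reward``   — a redundant rectangle whose reward varies along
  the redundant axis (symmetric / left- / right-biased);
* ``reward_switch``      — the rectangle's reward distribution changes
  mid-movement.

Every structural or reward change of the tracked goal reaches the
controller only after a hard 150 ms (15-step) update delay, distinct from
the 50 ms sensory delay.  Per-step feedback gains, cost matrices and
offsets depend on time only (never on the state), so they are computed once
per condition and shared across the trials of a batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np

from .control import (
    TargetSpec, WidthSchedule, build_terminal_Q, replan, width_weight,
    target_vector, with_target,
)
from .decisions import (
    DecisionTrace, OptionSet, RewardModel, discretize_rectangle, reward_bias,
    select_option,
)
from .estimation import estimate_step, kalman_recursion
from .plant import (
    CORE_DIM, AugmentedState, PointMassParams, apply_perturbation, build_plant,
    observe, step,
)

__all__ = [
    "PRESETS", "ScenarioConfig", "TrajectoryRecord", "BatchSummary",
    "SimulationDiverged", "build_preset", "run_trial", "run_batch",
]

PRESETS = ("narrow_wide_switch", "continuous_width", "triple_target",
           "rectangle_reward", "reward_switch")

#: default per-channel sensory noise standard deviations on the observed
#: 16-block (position m, velocity m/s, forces N; target channels near-exact)
DEFAULT_SENSORY_SD = (
    0.01, 0.01, 0.05, 0.05, 0.5, 0.5, 0.5, 0.5,
    1e-6, 1e-6, 1e-6, 1e-6, 1e-6, 1e-6, 1e-6, 1e-6,
)


class SimulationDiverged(RuntimeError):
    """Closed loop left the physical envelope; carries the partial record."""

    def __init__(self, message: str, record: "TrajectoryRecord | None" = None):
        super().__init__(message)
        self.record = record


@dataclass
class ScenarioConfig:
    """Complete, serializable description of one simulated condition."""

    preset: str = "narrow_wide_switch"
    # plant
    mass: float = 1.0
    viscosity: float = 1.0
    tau: float = 0.060
    dt: float = 0.010
    delay_steps: int = 5
    motor_noise: float = 0.1            # sd (N) on the controlled-force rows
    sensory_noise: tuple = DEFAULT_SENSORY_SD
    prior_cov: float = 1e-6
    estimator_fext_noise: float = 1.0   # filter-model Fext random-walk sd (N/step)
    # cost structure
    horizon: int = 60
    control_cost: float = 1e-4          # R = control_cost * I2
    w1: float = 1000.0
    w2_base: float = 1000.0
    velocity_weight: float = 10.0
    sigmoid_midpoint: float = 10.0
    sigmoid_slope: float = 3.0
    # geometry (m)
    reach_distance: float = 0.25
    lateral_offset: float = 0.12
    rect_half_width: float = 0.05
    # events (steps)
    perturbation: float = 0.0           # signed lateral force (N)
    perturbation_onset: int = 15
    change_onset: int = 10
    update_delay: int = 15
    # condition switches
    initial_shape: str = "narrow"       # narrow_wide_switch
    switch_to: str | None = None        # narrow_wide_switch: 'wide'|'narrow'|None
    width_condition: str = "static"     # continuous_width: static|slow|fast|switch
    reward_condition: str = "equal"     # equal|different|symmetric|left|right
    reward_switch_to: str | None = None  # reward_switch second distribution
    reward_bias_scale: float = 5e-2
    hysteresis: float = 0.0
    n_options: int = 21                 # rectangle discretization
    # batch
    n_trials: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        for name in ("perturbation_onset", "change_onset"):
            if not 0 <= getattr(self, name) <= self.horizon:
                raise ValueError(f"{name} must lie within the horizon")

    @property
    def params(self) -> PointMassParams:
        return PointMassParams(m=self.mass, G=self.viscosity, tau=self.tau, dt=self.dt)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sensory_noise"] = list(self.sensory_noise) if np.ndim(self.sensory_noise) else self.sensory_noise
        return d


def build_preset(name: str, **overrides) -> ScenarioConfig:
    """Named scenario with its experiment-specific defaults applied."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose one of {PRESETS}")
    defaults: dict = {"preset": name}
    if name == "narrow_wide_switch":
        defaults.update(initial_shape="narrow", switch_to="wide")
    elif name == "continuous_width":
        defaults.update(width_condition="slow")
    elif name == "triple_target":
        defaults.update(reward_condition="equal")
    elif name == "rectangle_reward":
        defaults.update(reward_condition="symmetric")
    elif name == "reward_switch":
        # reward change at movement onset; the controller update then lands
        # 150 ms in, before the reach commits to the initially favored end
        defaults.update(reward_condition="left", reward_switch_to="right",
                        change_onset=0)
    defaults.update(overrides)
    cfg = ScenarioConfig(**defaults)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# condition -> options, schedules, reward biases
# ---------------------------------------------------------------------------

def _width_schedule(cfg: ScenarioConfig) -> WidthSchedule:
    """Transverse-weight time course of the single-goal width presets."""
    kw = dict(w2_base=cfg.w2_base, midpoint=cfg.sigmoid_midpoint,
              slope=cfg.sigmoid_slope, update_delay=cfg.update_delay)
    if cfg.preset == "narrow_wide_switch":
        pre = cfg.w2_base if cfg.initial_shape == "narrow" else 0.0
        if cfg.switch_to is None:
            return WidthSchedule(condition="static", pre_value=pre, **kw)
        post = cfg.w2_base if cfg.switch_to == "narrow" else 0.0
        return WidthSchedule(condition="switch", pre_value=pre, post_value=post, **kw)
    # continuous_width: all conditions start wide
    if cfg.width_condition == "static":
        return WidthSchedule(condition="static", pre_value=0.0, **kw)
    if cfg.width_condition == "switch":
        return WidthSchedule(condition="switch", pre_value=0.0, post_value=cfg.w2_base, **kw)
    return WidthSchedule(condition=cfg.width_condition, pre_value=0.0, **kw)


def _reward_model(cfg: ScenarioConfig, which: str) -> RewardModel:
    kinds = {"symmetric": "rect_symmetric", "left": "rect_left_bias",
             "right": "rect_right_bias", "equal": "uniform",
             "different": "center_advantage"}
    if which not in kinds:
        raise ValueError(f"unknown reward condition {which!r}")
    return RewardModel(kind=kinds[which], bias_scale=cfg.reward_bias_scale)


def _make_options(cfg: ScenarioConfig) -> tuple[OptionSet, np.ndarray, np.ndarray | None]:
    """Options plus per-option terminal biases (and post-switch biases)."""
    y = cfg.reach_distance
    if cfg.preset in ("narrow_wide_switch", "continuous_width"):
        goal = TargetSpec(position=(0.0, y), shape="wide", w1=cfg.w1,
                          w2=_width_schedule(cfg),
                          velocity_weight=cfg.velocity_weight, label="goal")
        return OptionSet(options=[goal]), np.zeros(1), None
    if cfg.preset == "triple_target":
        lat = cfg.lateral_offset
        opts = [
            TargetSpec(position=(-lat, y), shape="point", w1=cfg.w1,
                       velocity_weight=cfg.velocity_weight, label="left"),
            TargetSpec(position=(0.0, y), shape="point", w1=cfg.w1,
                       velocity_weight=cfg.velocity_weight, label="center"),
            TargetSpec(position=(lat, y), shape="point", w1=cfg.w1,
                       velocity_weight=cfg.velocity_weight, label="right"),
        ]
        model = _reward_model(cfg, cfg.reward_condition)
        biases = np.array([reward_bias(model, o.position[0]) for o in opts])
        return OptionSet(options=opts), biases, None
    # rectangle presets
    rect = TargetSpec(position=(0.0, y), shape="rectangle", w1=cfg.w1,
                      velocity_weight=cfg.velocity_weight,
                      half_width=cfg.rect_half_width, label="rectangle")
    model = _reward_model(cfg, cfg.reward_condition)
    option_set = discretize_rectangle(rect, model, K=cfg.n_options)
    biases = np.array([o.reward_bias for o in option_set.options])
    post = None
    if cfg.preset == "reward_switch":
        if cfg.reward_switch_to is None:
            raise ValueError("reward_switch preset needs reward_switch_to")
        post_model = _reward_model(cfg, cfg.reward_switch_to)
        xs = np.linspace(-cfg.rect_half_width, cfg.rect_half_width, cfg.n_options)
        post = np.array([reward_bias(post_model, x) for x in xs])
    return option_set, biases, post


# ---------------------------------------------------------------------------
# per-condition controller tape (deterministic in time)
# ---------------------------------------------------------------------------

@dataclass
class _ControlTape:
    """Per-step first gains/cost terms of the replanned controller.

    ``L[t]``, ``S[t]`` are shared by options with identical accuracy
    weights (all presets); ``s_base[t]`` is the bias-free offset and
    ``biases[t, i]`` the per-option terminal bias active at step t — a
    terminal bias shifts every offset of the remaining-horizon solution by
    exactly itself, so it can be added at evaluation time.
    """

    L: np.ndarray        # (N, 2, 16)
    S: np.ndarray        # (N + 1, 16, 16)
    s_base: np.ndarray   # (N + 1,)
    biases: np.ndarray   # (N + 1, n_options)
    w2: np.ndarray       # (N + 1,) active transverse weight (record keeping)


def _build_tape(cfg: ScenarioConfig, plant, option_set: OptionSet,
                biases_pre: np.ndarray, biases_post: np.ndarray | None) -> _ControlTape:
    N = cfg.horizon
    n_opt = len(option_set)
    R = cfg.control_cost * np.eye(2)
    rep = option_set.options[0]  # all options share accuracy weights
    update_step = cfg.change_onset + cfg.update_delay

    L = np.empty((N, 2, CORE_DIM))
    S = np.empty((N + 1, CORE_DIM, CORE_DIM))
    s_base = np.empty(N + 1)
    w2 = np.empty(N + 1)
    biases = np.empty((N + 1, n_opt))
    for t in range(N):
        sched_t = t - update_step
        if isinstance(rep.w2, WidthSchedule) and sched_t < 0:
            w2[t] = rep.w2.pre_value
        else:
            w2[t] = rep.transverse_weight(sched_t)
        q_term = _terminal_q_at(rep, w2[t])
        sol = replan(plant, q_term, R, remaining_N=N - t)
        L[t] = sol.L[0]
        S[t] = sol.S[0]
        s_base[t] = sol.s[0]
        biases[t] = biases_post if (biases_post is not None and sched_t >= 0) else biases_pre
    # step N: terminal quantities of the last replan (remaining horizon 1)
    w2[N] = w2[N - 1]
    S[N] = _terminal_q_at(rep, w2[N])
    s_base[N] = 0.0
    biases[N] = biases[N - 1]
    return _ControlTape(L=L, S=S, s_base=s_base, biases=biases, w2=w2)


def _terminal_q_at(target: TargetSpec, w2_value: float) -> np.ndarray:
    if target.shape in ("point", "narrow"):
        return build_terminal_Q(target)
    resolved = replace(target, w2=float(w2_value))
    return build_terminal_Q(resolved)


# ---------------------------------------------------------------------------
# trial runner
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryRecord:
    """Full per-trial time series, serializable to the versioned CSV."""

    trial: int
    t_ms: np.ndarray           # (N + 1,)
    physical: np.ndarray       # (N + 1, 8) true physical block
    estimate: np.ndarray       # (N + 1, 8) estimated physical block
    command: np.ndarray        # (N + 1, 2), zero on the terminal row
    chosen: np.ndarray         # (N + 1,) selected option index
    w2: np.ndarray             # (N + 1,) active transverse weight
    values: np.ndarray         # (N + 1, n_options) cost-to-go per option
    events: dict               # step of change onset, controller update, force onset
    decision: DecisionTrace
    seed: int
    labels: dict = field(default_factory=dict)

    @property
    def final_option(self) -> int:
        return self.decision.final_option

    @property
    def endpoint(self) -> np.ndarray:
        return self.physical[-1, :2]

    def to_dataframe(self):
        import pandas as pd

        n = len(self.t_ms)
        event = np.array([""] * n, dtype=object)
        for name, step_ in self.events.items():
            if step_ is not None and 0 <= step_ < n:
                event[step_] = (event[step_] + "+" + name).lstrip("+")
        for (t, i, j) in self.decision.switch_events:
            event[t] = (event[t] + f"+switch:{i}->{j}").lstrip("+")
        cols = {
            "trial": np.full(n, self.trial),
            "t_ms": self.t_ms,
            "px": self.physical[:, 0], "py": self.physical[:, 1],
            "vx": self.physical[:, 2], "vy": self.physical[:, 3],
            "Fx": self.physical[:, 4], "Fy": self.physical[:, 5],
            "Fext_x": self.physical[:, 6], "Fext_y": self.physical[:, 7],
            "ux": self.command[:, 0], "uy": self.command[:, 1],
            "xhat_px": self.estimate[:, 0], "xhat_py": self.estimate[:, 1],
            "xhat_vx": self.estimate[:, 2], "xhat_vy": self.estimate[:, 3],
            "xhat_Fx": self.estimate[:, 4], "xhat_Fy": self.estimate[:, 5],
            "xhat_Fext_x": self.estimate[:, 6], "xhat_Fext_y": self.estimate[:, 7],
            "option": self.chosen,
            "w2_t": self.w2,
            "event": event,
        }
        return pd.DataFrame(cols)


@dataclass
class _ConditionCache:
    plant: object
    kalman_gains: np.ndarray
    tape: _ControlTape
    option_set: OptionSet
    targets8: np.ndarray     # (n_options, 8)


def _prepare(cfg: ScenarioConfig) -> _ConditionCache:
    cfg.validate()
    plant = build_plant(cfg.params, h=cfg.delay_steps,
                        motor_noise=cfg.motor_noise,
                        sensory_noise=np.asarray(cfg.sensory_noise, dtype=float))
    option_set, biases_pre, biases_post = _make_options(cfg)
    tape = _build_tape(cfg, plant, option_set, biases_pre, biases_post)
    proc = plant.Sigma_m.copy()
    for idx in (6, 7):  # Fext rows of the newest block: filter-model random walk
        proc[idx, idx] += cfg.estimator_fext_noise ** 2
    ksol = kalman_recursion(plant, cfg.prior_cov, cfg.horizon, process_noise=proc)
    targets8 = np.stack([option_set.target8(i) for i in range(len(option_set))])
    return _ConditionCache(plant=plant, kalman_gains=ksol.gains, tape=tape,
                           option_set=option_set, targets8=targets8)


def run_trial(cfg: ScenarioConfig, trial_seed: int,
              _cache: _ConditionCache | None = None) -> TrajectoryRecord:
    """Simulate one trial.

    Per step: observe the delayed block, update the state estimate, look up
    the replanned per-option gains for the current step, evaluate and
    compare the options' cost-to-go on the current estimate, apply the
    selected option's first command, and step the plant.
    """
    cache = _cache if _cache is not None else _prepare(cfg)
    plant, tape, option_set = cache.plant, cache.tape, cache.option_set
    N = cfg.horizon
    n_opt = len(option_set)
    rng = np.random.default_rng(trial_seed)
    noisy = cfg.motor_noise != 0 or np.any(np.asarray(cfg.sensory_noise))

    # start at rest at the origin; the state's goal block tracks the initial
    # choice (bookkeeping only: options substitute their own goal values)
    init_vals = _option_values(tape, cache.targets8, np.zeros(plant.dim), 0, n_opt)
    current = int(np.argmin(init_vals))
    target0 = cache.targets8[current]
    state = AugmentedState.initial(np.zeros(8), target0, cfg.delay_steps)
    x_hat = state.vector.copy()

    phys = np.empty((N + 1, 8))
    est = np.empty((N + 1, 8))
    u_rec = np.zeros((N + 1, 2))
    chosen = np.empty(N + 1, dtype=int)
    values = np.empty((N + 1, n_opt))

    for t in range(N):
        if cfg.perturbation and t == cfg.perturbation_onset:
            state = apply_perturbation(state, (cfg.perturbation, 0.0))
        vals = _option_values(tape, cache.targets8, x_hat, t, n_opt)
        current = select_option(vals, current, cfg.hysteresis)
        u = -tape.L[t] @ with_target(x_hat[:CORE_DIM], cache.targets8[current])

        phys[t] = state.physical
        est[t] = x_hat[:8]
        u_rec[t] = u
        chosen[t] = current
        values[t] = vals

        y = observe(plant, state, rng if noisy else None)
        state = step(plant, state, u, rng if noisy else None)
        x_hat = estimate_step(plant, x_hat, u, y, cache.kalman_gains[t])
        if np.max(np.abs(state.physical)) > 1e3:
            raise SimulationDiverged(
                f"trial {trial_seed}: state left the physical envelope at step {t}",
                record=None,
            )

    phys[N] = state.physical
    est[N] = x_hat[:8]
    values[N] = _option_values(tape, cache.targets8, x_hat, N, n_opt)
    chosen[N] = current

    trace = DecisionTrace.from_series(values, chosen)
    events = {
        "change_onset": cfg.change_onset if _has_change(cfg) else None,
        "controller_update": cfg.change_onset + cfg.update_delay if _has_change(cfg) else None,
        "perturbation_onset": cfg.perturbation_onset if cfg.perturbation else None,
    }
    return TrajectoryRecord(
        trial=0, t_ms=np.arange(N + 1) * cfg.dt * 1000.0,
        physical=phys, estimate=est, command=u_rec, chosen=chosen,
        w2=tape.w2.copy(), values=values, events=events, decision=trace,
        seed=trial_seed,
        labels={"preset": cfg.preset, "reward_condition": cfg.reward_condition,
                "width_condition": cfg.width_condition,
                "force": cfg.perturbation},
    )


def _option_values(tape: _ControlTape, targets8: np.ndarray, x_hat: np.ndarray,
                   t: int, n_opt: int) -> np.ndarray:
    xc = x_hat[:CORE_DIM]
    vals = np.empty(n_opt)
    S, s0 = tape.S[t], tape.s_base[t]
    for i in range(n_opt):
        xi = xc.copy()
        xi[8:] = targets8[i]
        vals[i] = xi @ S @ xi + s0 + tape.biases[t, i]
    return vals


def _has_change(cfg: ScenarioConfig) -> bool:
    if cfg.preset == "narrow_wide_switch":
        return cfg.switch_to is not None
    if cfg.preset == "continuous_width":
        return cfg.width_condition != "static"
    if cfg.preset == "reward_switch":
        return True
    return False


# ---------------------------------------------------------------------------
# batches
# ---------------------------------------------------------------------------

@dataclass
class BatchSummary:
    """Endpoint statistics, switch behavior and seeds of a batch."""

    n_trials: int
    master_seed: int
    trial_seeds: list[int]
    final_options: list[int]
    option_labels: list[str]
    proportions: dict
    endpoint_mean: list[float]
    endpoint_var: list[float | None]
    switch_times_ms: list[float]
    mean_switch_time_ms: float | None

    def to_dict(self) -> dict:
        from dataclasses import asdict as _asdict
        return _asdict(self)


def derive_trial_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-trial seed stream from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32)]


def run_batch(cfg: ScenarioConfig) -> tuple[list[TrajectoryRecord], BatchSummary]:
    """Simulate ``cfg.n_trials`` independent trials and summarize them."""
    if cfg.n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    cache = _prepare(cfg)
    seeds = derive_trial_seeds(cfg.seed, cfg.n_trials)
    records: list[TrajectoryRecord] = []
    for i, s in enumerate(seeds):
        try:
            rec = run_trial(cfg, s, _cache=cache)
        except SimulationDiverged as err:
            raise SimulationDiverged(f"trial {i}: {err}", record=err.record) from err
        rec.trial = i
        records.append(rec)

    labels = [o.label or str(i) for i, o in enumerate(cache.option_set.options)]
    finals = [r.final_option for r in records]
    counts = np.bincount(finals, minlength=len(labels)).astype(float)
    proportions = {labels[i]: counts[i] / len(records) for i in range(len(labels))}
    ends = np.stack([r.endpoint for r in records])
    var = ends.var(axis=0, ddof=1).tolist() if len(records) > 1 else [None, None]
    from .decisions import switch_time as _switch_time
    st = [_switch_time(r.decision) for r in records]
    st_ms = [float(s * cfg.dt * 1000.0) for s in st if s is not None]
    summary = BatchSummary(
        n_trials=len(records), master_seed=cfg.seed, trial_seeds=seeds,
        final_options=finals, option_labels=labels, proportions=proportions,
        endpoint_mean=ends.mean(axis=0).tolist(), endpoint_var=var,
        switch_times_ms=st_ms,
        mean_switch_time_ms=float(np.mean(st_ms)) if st_ms else None,
    )
    return records, summary
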