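"""Discretized, augmented point-mass plant with linear muscle dynamics and delayed observation.

The physical system is a unit point mass moving in the horizontal plane under
a viscous force, a controlled force produced by first-order (low-pass) muscle
dynamics, and a constant external force used to model mechanical
perturbations.  The x- and y-axes are independent; y is the forward reach
axis and x the transverse axis.  All quantities are SI (m, m/s, N, s).

The state is augmented twice:

* a *target block* of the same layout as the physical block carries the goal
  values, so that terminal costs become homogeneous quadratic forms on the
  augmented state;
* a *delay stack* of ``h + 1`` copies of the 16-vector (newest first) lets
  the controller observe only the most delayed copy, modeling the ~50 ms
  long-latency sensorimotor loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CORE_DIM",
    "PHYS_SLICE",
    "TARGET_SLICE",
    "IDX",
    "PointMassParams",
    "AugmentedState",
    "LinearPlant",
    "build_plant",
    "step",
    "observe",
    "apply_perturbation",
]

#: dimension of one (physical + target) block
CORE_DIM = 16

#: named indices into the 8-dim physical layout, reused for the target block
IDX = {
    "px": 0, "py": 1, "vx": 2, "vy": 3,
    "Fx": 4, "Fy": 5, "Fext_x": 6, "Fext_y": 7,
}

PHYS_SLICE = slice(0, 8)
TARGET_SLICE = slice(8, 16)


@dataclass(frozen=True)
class PointMassParams:
    """Physical parameters of the translating point mass.

    Parameters
    ----------
    m : float
        Mass (kg).
    G : float
        Viscous constant (N·s/m).
    tau : float
        Muscle (controlled-force) low-pass time constant (s).
    dt : float
        Euler integration step (s).  Must satisfy ``dt < tau`` so the
        discretized force row stays stable.
    """

    m: float = 1.0
    G: float = 1.0
    tau: float = 0.060
    dt: float = 0.010

    def __post_init__(self) -> None:
        for name in ("m", "G", "tau", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PointMassParams.{name} must be strictly positive")
        if self.tau <= self.dt:
            raise ValueError("PointMassParams requires tau > dt for a stable force row")


@dataclass
class AugmentedState:
    """Full augmented state: delay stack of (physical, target) 16-blocks.

    ``vector`` has length ``16 * (h + 1)``; block ``k`` (k = 0 newest) holds
    the 16-vector as it was ``k`` steps ago.
    """

    vector: np.ndarray
    h: int

    @classmethod
    def initial(cls, physical: np.ndarray, target: np.ndarray, h: int) -> "AugmentedState":
        """Build a start-of-trial state with a delay stack of identical copies."""
        physical = np.asarray(physical, dtype=float)
        target = np.asarray(target, dtype=float)
        if physical.shape != (8,) or target.shape != (8,):
            raise ValueError("physical and target must be 8-vectors")
        block = np.concatenate([physical, target])
        return cls(vector=np.tile(block, h + 1), h=h)

    @property
    def current(self) -> np.ndarray:
        """Newest 16-block (view)."""
        return self.vector[:CORE_DIM]

    @property
    def physical(self) -> np.ndarray:
        return self.vector[:8]

    @property
    def target(self) -> np.ndarray:
        return self.vector[8:16]

    def delayed_block(self, k: int) -> np.ndarray:
        """16-block as it was ``k`` steps ago (k <= h)."""
        if not 0 <= k <= self.h:
            raise ValueError(f"delay index {k} outside [0, {self.h}]")
        return self.vector[k * CORE_DIM:(k + 1) * CORE_DIM]


@dataclass
class LinearPlant:
    """Discretized augmented plant ``x_{t+1} = A x_t + B u_t + xi_t``.

    ``A``/``B``/``H`` act on the full ``16 (h+1)``-dim augmented state; the
    observation ``y_t = H x_t + omega_t`` selects the most delayed 16-block.
    ``A_core``/``B_core`` are the 16-dim restriction used by the controller
    (the delayed copies never feed back into the newest block and carry no
    cost, so control matrices are supported on the core alone).
    """

    A: np.ndarray
    B: np.ndarray
    H: np.ndarray
    Sigma_m: np.ndarray
    Sigma_s: np.ndarray
    h: int
    params: PointMassParams
    A_core: np.ndarray = field(repr=False, default=None)
    B_core: np.ndarray = field(repr=False, default=None)
    Sigma_m_core: np.ndarray = field(repr=False, default=None)

    @property
    def dim(self) -> int:
        return self.A.shape[0]


def _core_matrices(params: PointMassParams) -> tuple[np.ndarray, np.ndarray]:
    """Euler discretization of the continuous plant on one 16-block."""
    dt, m, G, tau = params.dt, params.m, params.G, params.tau
    A = np.eye(CORE_DIM)
    for ax in (0, 1):  # x then y; axes are independent
        p, v, F, Fe = IDX["px"] + ax, IDX["vx"] + ax, IDX["Fx"] + ax, IDX["Fext_x"] + ax
        A[p, v] = dt
        A[v, v] = 1.0 - dt * G / m
        A[v, F] = dt / m
        A[v, Fe] = dt / m
        A[F, F] = 1.0 - dt / tau
        # Fext and target rows stay identity: external force persists,
        # the goal block is constant under the dynamics.
    B = np.zeros((CORE_DIM, 2))
    B[IDX["Fx"], 0] = dt / tau
    B[IDX["Fy"], 1] = dt / tau
    return A, B


def build_plant(
    params: PointMassParams,
    h: int = 5,
    motor_noise: float | np.ndarray = 0.0,
    sensory_noise: float | np.ndarray = 0.0,
) -> LinearPlant:
    """Assemble the delayed, augmented, noisy linear plant.

    Parameters
    ----------
    params : PointMassParams
    h : int
        Feedback delay in steps (default 5, i.e. 50 ms at dt = 10 ms).
    motor_noise : float or (16, 16) array
        Scalar -> standard deviation of additive motor noise applied to the
        controlled-force rows (Fx, Fy) of the newest block; array -> full
        core covariance.
    sensory_noise : float or array
        Scalar -> common standard deviation on every observed channel;
        length-16 array -> per-channel standard deviations; (16, 16) array ->
        full observation covariance.
    """
    if h < 0:
        raise ValueError("delay h must be >= 0")
    A_core, B_core = _core_matrices(params)
    nblk = h + 1
    dim = CORE_DIM * nblk

    A = np.zeros((dim, dim))
    A[:CORE_DIM, :CORE_DIM] = A_core
    for k in range(1, nblk):  # block k copies block k-1 of the previous step
        A[k * CORE_DIM:(k + 1) * CORE_DIM, (k - 1) * CORE_DIM:k * CORE_DIM] = np.eye(CORE_DIM)

    B = np.zeros((dim, 2))
    B[:CORE_DIM] = B_core

    H = np.zeros((CORE_DIM, dim))
    H[:, h * CORE_DIM:] = np.eye(CORE_DIM)

    Sigma_m_core = np.asarray(motor_noise, dtype=float)
    if Sigma_m_core.ndim == 0:
        sd = float(Sigma_m_core)
        Sigma_m_core = np.zeros((CORE_DIM, CORE_DIM))
        Sigma_m_core[IDX["Fx"], IDX["Fx"]] = sd ** 2
        Sigma_m_core[IDX["Fy"], IDX["Fy"]] = sd ** 2
    _check_psd(Sigma_m_core, "motor noise covariance")
    Sigma_m = np.zeros((dim, dim))
    Sigma_m[:CORE_DIM, :CORE_DIM] = Sigma_m_core

    Sigma_s = np.asarray(sensory_noise, dtype=float)
    if Sigma_s.ndim == 0:
        Sigma_s = np.eye(CORE_DIM) * float(Sigma_s) ** 2
    elif Sigma_s.ndim == 1:
        Sigma_s = np.diag(Sigma_s.astype(float) ** 2)
    _check_psd(Sigma_s, "sensory noise covariance")

    return LinearPlant(
        A=A, B=B, H=H, Sigma_m=Sigma_m, Sigma_s=Sigma_s, h=h, params=params,
        A_core=A_core, B_core=B_core, Sigma_m_core=Sigma_m_core,
    )


def _check_psd(M: np.ndarray, what: str) -> None:
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T):
        raise ValueError(f"{what} must be square symmetric")
    if np.min(np.linalg.eigvalsh(M)) < -1e-12:
        raise ValueError(f"{what} must be positive semidefinite")


def step(
    plant: LinearPlant,
    state: AugmentedState,
    u: np.ndarray,
    rng: np.random.Generator | None = None,
) -> AugmentedState:
    """One forward step ``x_{t+1} = A x_t + B u_t + xi_t``, xi ~ N(0, Sigma_m).

    With zero motor noise (or ``rng=None``) the map is deterministic and
    linear in ``(x, u)``.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (2,):
        raise ValueError("command u must be a 2-vector")
    new = plant.A @ state.vector + plant.B @ u
    if rng is not None and np.any(plant.Sigma_m_core):
        new[:CORE_DIM] += _sample_noise(plant.Sigma_m_core, rng)
    return AugmentedState(vector=new, h=state.h)


def _sample_noise(cov: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw N(0, cov); diagonal (possibly singular) covariances sampled directly."""
    d = np.diag(cov)
    if not np.any(cov - np.diag(d)):
        return rng.standard_normal(cov.shape[0]) * np.sqrt(d)
    return rng.multivariate_normal(np.zeros(cov.shape[0]), cov, method="svd")


def observe(
    plant: LinearPlant,
    state: AugmentedState,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Delayed observation ``y_t = H x_t + omega_t``: the most delayed 16-block."""
    y = plant.H @ state.vector
    if rng is not None and np.any(plant.Sigma_s):
        y = y + _sample_noise(plant.Sigma_s, rng)
    return y


def apply_perturbation(state: AugmentedState, force: np.ndarray) -> AugmentedState:
    """Set the external-force entries of the newest physical block.

    The perturbation persists through subsequent steps because the external
    force rows of the dynamics are identity; it reaches the controller's
    observation only ``h`` steps later, through the delay stack.
    """
    force = np.asarray(force, dtype=float)
    new = state.vector.copy()
    new[IDX["Fext_x"]] = force[0]
    new[IDX["Fext_y"]] = force[1]
    return AugmentedState(vector=new, h=state.h)
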