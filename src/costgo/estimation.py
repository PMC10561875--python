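"""Kalman estimation of the augmented state from delayed, noisy feedback.

The estimator is the one-step-ahead (predictor) form

    x̂_{t+1} = A x̂_t + B u_t + K_t (y_t − H x̂_t)

with time-varying gains K_t from the standard covariance recursion for the
augmented system (A, H, Σ_m, Σ_s).  The plant and observation model do not
depend on the goal target, so the same gain sequence serves every option the
decision layer tracks; gains are computed once per trial horizon and cached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plant import LinearPlant

__all__ = ["KalmanSolution", "kalman_recursion", "estimate_step"]


@dataclass
class KalmanSolution:
    """Time-varying Kalman gains over a horizon.

    Attributes
    ----------
    gains : (N, dim, obs_dim) array
        ``gains[t]`` is K_t in the predictor update.
    prior_cov : (dim, dim) array
        Estimation-error covariance at t = 0.
    covariances : (N + 1, dim, dim) array
        Predicted error covariances P_t (P_0 = prior_cov).
    """

    gains: np.ndarray
    prior_cov: np.ndarray
    covariances: np.ndarray


def kalman_recursion(
    plant: LinearPlant,
    prior_cov: np.ndarray | float,
    N: int,
    process_noise: np.ndarray | None = None,
) -> KalmanSolution:
    """Compute time-varying predictor gains for ``N`` steps.

    ``prior_cov`` may be a scalar (isotropic covariance) or a full matrix.
    Singular innovation covariances (e.g. exactly noise-free channels) are
    handled with a pseudo-inverse, so the noiseless-observation limit is
    well defined.

    ``process_noise`` optionally replaces the plant's motor-noise covariance
    in the filter's internal model.  External-force steps are deterministic
    jumps the additive-noise model does not cover; giving the filter a small
    random-walk term on the external-force rows keeps its gain open so
    perturbations are tracked after the sensory delay instead of being
    explained away.
    """
    if N < 1:
        raise ValueError("horizon N must be >= 1")
    dim = plant.dim
    P = np.asarray(prior_cov, dtype=float)
    if P.ndim == 0:
        P = np.eye(dim) * float(P)
    if P.shape != (dim, dim):
        raise ValueError("prior_cov has wrong shape")
    if np.min(np.linalg.eigvalsh((P + P.T) / 2)) < -1e-12:
        raise ValueError("prior_cov must be positive semidefinite")

    Sigma_m = plant.Sigma_m if process_noise is None else np.asarray(process_noise, dtype=float)
    if Sigma_m.shape != (dim, dim):
        raise ValueError("process_noise has wrong shape")
    A, H = plant.A, plant.H
    gains = np.empty((N, dim, H.shape[0]))
    covs = np.empty((N + 1, dim, dim))
    covs[0] = P
    for t in range(N):
        S = H @ P @ H.T + plant.Sigma_s
        K = A @ P @ H.T @ np.linalg.pinv(S, hermitian=True)
        P = (A - K @ H) @ P @ A.T + Sigma_m
        P = (P + P.T) / 2  # keep the recursion symmetric against round-off
        gains[t] = K
        covs[t + 1] = P
    return KalmanSolution(gains=gains, prior_cov=covs[0], covariances=covs)


def estimate_step(
    plant: LinearPlant,
    x_hat: np.ndarray,
    u: np.ndarray,
    y: np.ndarray,
    K: np.ndarray,
) -> np.ndarray:
    """One predictor update ``x̂_{t+1} = A x̂_t + B u_t + K (y − H x̂_t)``."""
    innovation = y - plant.H @ x_hat
    return plant.A @ x_hat + plant.B @ np.asarray(u, dtype=float) + K @ innovation
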