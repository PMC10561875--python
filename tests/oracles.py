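"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the package's backward recursion: the batch
solution stacks the dynamics and solves the quadratic program in the
command sequence in closed form, and the rollout accumulates the realized
cost by direct simulation.
"""

import numpy as np


def batch_lqr_solution(A, B, Qs, R, N, x0):
    """Closed-form minimizer of sum x_t'Q_t x_t + u_t'R u_t over commands."""
    n, m = B.shape
    G = np.zeros((N * n, n))
    M = np.zeros((N * n, N * m))
    Ap = np.eye(n)
    for t in range(N):
        Ap = A @ Ap
        G[t * n:(t + 1) * n] = Ap
        for k in range(t + 1):
            M[t * n:(t + 1) * n, k * m:(k + 1) * m] = np.linalg.matrix_power(A, t - k) @ B
    Qblk = np.zeros((N * n, N * n))
    for t in range(1, N + 1):
        Qblk[(t - 1) * n:t * n, (t - 1) * n:t * n] = Qs[t]
    Rblk = np.kron(np.eye(N), R)
    U = np.linalg.solve(M.T @ Qblk @ M + Rblk, -M.T @ Qblk @ G @ x0)
    x = G @ x0 + M @ U
    cost = float(x @ Qblk @ x + U @ Rblk @ U)
    return U.reshape(N, m), cost


def rollout_cost(A, B, Qs, R, solution, x0, N, rng=None, noise_cov=None):
    """Realized cost of simulating the gain policy from x0 (optionally noisy)."""
    x, cost = np.asarray(x0, dtype=float).copy(), 0.0
    sd = None if noise_cov is None else np.sqrt(np.diag(noise_cov))
    for t in range(N):
        u = -solution.L[t] @ x
        cost += float(u @ R @ u)
        x = A @ x + B @ u
        if sd is not None:
            x = x + rng.standard_normal(x.shape) * sd
        cost += float(x @ Qs[t + 1] @ x)
    return cost


def random_system(rng, n, m):
    A = rng.normal(scale=0.6, size=(n, n))
    B = rng.normal(size=(n, m))
    W = rng.normal(size=(n, n))
    QN = W @ W.T
    V = rng.normal(size=(m, m))
    R = V @ V.T + np.eye(m)
    return A, B, QN, R
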