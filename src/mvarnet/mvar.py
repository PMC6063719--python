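"""MVAR(1)/MVAR(2) simulation and Yule-Walker coefficient estimation.

The dynamics are ``x_t = A x_{t-1} + zeta_t`` (order 1) or
``x_t = A1 x_{t-1} + A2 x_{t-2} + zeta_t`` (order 2) with i.i.d. Gaussian
innovations ``zeta_t ~ N(0, Sigma)``.

Coefficients are estimated from the empirical lagged covariances

    Qhat^tau_ij = 1/(T - tau_max - 1) * sum_{t=1..T-tau_max}
                  (x_i^{t+tau} - xbar_i)(x_j^t - xbar_j)

via the Yule-Walker relation ``Q^1 = A Q^0``, giving the OLS estimate
``a = Qhat^1 (Qhat^0)^{-1}`` at order 1 and its block extension
``(a1 a2) = Qtilde^1 (Qtilde^0)^{-1}`` at order 2.

All lags share the common summation window ``t = 1..T - tau_max`` (a switch
``per_lag_window=True`` uses the maximal window per lag instead).  The
``1/(T - tau_max - 1)`` normalization (``"bessel"``) can be changed to the
plain ``1/(T - tau_max)`` via ``normalization="plain"``; ratios built from
the covariances are insensitive to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from ._seeds import rng_from
from .exceptions import ConditioningError, ParameterError, ShapeError, StabilityError
from .netgen import ConnectivityMatrix, InputCovariance, companion_matrix, companion_spectral_radius

#: refuse to invert covariance matrices whose condition number exceeds this
CONDITION_CAP = 1e12


@dataclass
class TimeSeriesPanel:
    """Node x time observations, optionally with a leading trial axis."""

    data: np.ndarray  # (N, T) or (R, N, T)
    sampling_tag: str = "model-step"

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim not in (2, 3):
            raise ShapeError(f"panel must be (N, T) or (R, N, T), got {d.shape}")
        if not np.all(np.isfinite(d)):
            raise ParameterError("panel contains non-finite values")
        self.data = d

    @property
    def n_trials(self) -> int:
        return 1 if self.data.ndim == 2 else self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[-2]

    @property
    def n_samples(self) -> int:
        return self.data.shape[-1]

    def trials(self):
        """Iterate over (N, T) trial matrices."""
        if self.data.ndim == 2:
            yield self.data
        else:
            yield from self.data


@dataclass
class CovarianceSet:
    """Empirical (or theoretical) lagged covariances Q^tau, tau = 0..tau_max."""

    q: list
    tau_max: int
    t_used: int
    means: np.ndarray

    def __getitem__(self, tau: int) -> np.ndarray:
        return self.q[tau]

    @property
    def n_nodes(self) -> int:
        return self.q[0].shape[0]


@dataclass
class CoefficientEstimate:
    """MVAR coefficients: a (order 1) or the pair (a1, a2) (order 2)."""

    a: np.ndarray
    order: int = 1
    a2: np.ndarray | None = None
    source: Literal["empirical", "theoretical"] = "empirical"

    def matrices(self):
        return (self.a,) if self.order == 1 else (self.a, self.a2)


def simulate(
    conn: ConnectivityMatrix,
    sigma: InputCovariance,
    t_samples: int,
    seed: int = 0,
    burn_in: int = 100,
) -> TimeSeriesPanel:
    """Simulate the noise-diffusion network for ``t_samples`` steps.

    The initial state is drawn from N(0, Sigma) and the first ``burn_in``
    steps are discarded so the retained window is (approximately) stationary.
    Deterministic given ``seed``.
    """
    if t_samples < 1:
        raise ParameterError("t_samples must be >= 1")
    rho = companion_spectral_radius(conn)
    if rho >= 1.0:
        raise StabilityError(f"companion spectral radius {rho:.3f} >= 1")
    n = conn.n_nodes
    if sigma.n_nodes != n:
        raise ShapeError("sigma size does not match connectivity")
    rng = rng_from(seed, 2)
    total = t_samples + burn_in
    # zeta_t = M u_t gives exactly Cov = M M^T = Sigma
    noise = rng.standard_normal((total, n)) @ sigma.mixing.T
    out = np.empty((total, n))
    a1 = conn.weights
    if conn.order == 1:
        x = sigma.mixing @ rng.standard_normal(n)
        for t in range(total):
            x = a1 @ x + noise[t]
            out[t] = x
    else:
        a2 = conn.weights2
        x_prev = sigma.mixing @ rng.standard_normal(n)
        x = sigma.mixing @ rng.standard_normal(n)
        for t in range(total):
            x_new = a1 @ x + a2 @ x_prev + noise[t]
            x_prev, x = x, x_new
            out[t] = x
    return TimeSeriesPanel(data=out[burn_in:].T)


def _trial_covariances(x, tau_max, normalization, per_lag_window):
    n, t = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    qs = []
    for tau in range(tau_max + 1):
        if per_lag_window:
            win = t - tau
        else:
            win = t - tau_max
        denom = win - 1 if normalization == "bessel" else win
        qs.append(xc[:, tau : tau + win] @ xc[:, :win].T / denom)
    return qs, xc.mean(axis=1)


def lagged_covariance(
    panel: TimeSeriesPanel,
    tau_max: int = 1,
    *,
    normalization: Literal["bessel", "plain"] = "bessel",
    per_lag_window: bool = False,
) -> CovarianceSet:
    """Empirical lagged covariances of a panel.

    Multi-trial panels are centered per trial and the per-trial covariance
    matrices averaged (each trial contributes its own mean, matching the
    trial-wise centering used for electrode envelopes).

    Nodes with zero variance are flagged immediately: downstream inversion
    of Q^0 would be singular.
    """
    if panel.n_samples <= tau_max + 1:
        raise ParameterError(f"need T > tau_max + 1 (T={panel.n_samples}, tau_max={tau_max})")
    acc = None
    means = np.zeros(panel.n_nodes)
    for x in panel.trials():
        qs, _ = _trial_covariances(x, tau_max, normalization, per_lag_window)
        if acc is None:
            acc = qs
        else:
            acc = [a + q for a, q in zip(acc, qs)]
        means += x.mean(axis=1)
    r = panel.n_trials
    acc = [a / r for a in acc]
    means /= r
    dead = np.flatnonzero(np.diag(acc[0]) <= 0)
    if dead.size:
        warnings.warn(
            f"nodes {dead.tolist()} have zero variance; Q^0 is singular and "
            "coefficient estimation will fail",
            stacklevel=2,
        )
    return CovarianceSet(q=acc, tau_max=tau_max, t_used=panel.n_samples - tau_max, means=means)


def _safe_solve(q0, rhs_t):
    """Solve q0 @ X = rhs_t with a conditioning guard; returns X."""
    cond = np.linalg.cond(q0)
    if not np.isfinite(cond) or cond > CONDITION_CAP:
        variances = np.diag(q0)
        nodes = np.argsort(variances)[:5].tolist()
        raise ConditioningError(
            f"Q^0 condition number {cond:.2e} exceeds cap {CONDITION_CAP:.0e}; "
            f"smallest-variance nodes: {nodes}",
            nodes=nodes,
        )
    return np.linalg.solve(q0, rhs_t)


def estimate_order1(covs: CovarianceSet) -> CoefficientEstimate:
    """OLS/Yule-Walker estimate ``a = Q^1 (Q^0)^{-1}``."""
    if covs.tau_max < 1:
        raise ParameterError("need tau_max >= 1 for order-1 estimation")
    a = _safe_solve(covs[0], covs[1].T).T
    return CoefficientEstimate(a=a, order=1)


def estimate_order2(covs: CovarianceSet) -> CoefficientEstimate:
    """Block Yule-Walker estimate ``(a1 a2) = Qtilde^1 (Qtilde^0)^{-1}``."""
    if covs.tau_max < 2:
        raise ParameterError("need tau_max >= 2 for order-2 estimation")
    q0, q1, q2 = covs[0], covs[1], covs[2]
    q0t = np.block([[q0, q1], [q1.T, q0]])
    q1t = np.hstack([q1, q2])
    at = _safe_solve(q0t, q1t.T).T
    n = covs.n_nodes
    return CoefficientEstimate(a=at[:, :n], a2=at[:, n:], order=2)


def theoretical_covariance(
    conn: ConnectivityMatrix, sigma: InputCovariance, tau_max: int = 1
) -> CovarianceSet:
    """Exact stationary lagged covariances of the model.

    Order 1: ``Q^0`` solves the discrete Lyapunov equation
    ``Q^0 = A Q^0 A^T + Sigma`` and ``Q^tau = A^tau Q^0``.  Order 2 goes
    through the companion form.
    """
    rho = companion_spectral_radius(conn)
    if rho >= 1.0:
        raise StabilityError(f"companion spectral radius {rho:.3f} >= 1")
    n = conn.n_nodes
    if conn.order == 1:
        a = conn.weights
        q0 = solve_discrete_lyapunov(a, sigma.sigma)
        q0 = (q0 + q0.T) / 2
        qs = [q0]
        for _ in range(tau_max):
            qs.append(a @ qs[-1])
    else:
        c = companion_matrix(conn)
        big_sigma = np.zeros((2 * n, 2 * n))
        big_sigma[:n, :n] = sigma.sigma
        big_q = solve_discrete_lyapunov(c, big_sigma)
        big_q = (big_q + big_q.T) / 2
        q0 = big_q[:n, :n]
        q1 = big_q[:n, n : 2 * n]  # Cov(x_t, x_{t-1})
        qs = [q0, q1]
        # recursion Q^tau = A1 Q^{tau-1} + A2 Q^{tau-2}
        for _ in range(2, tau_max + 1):
            qs.append(conn.weights @ qs[-1] + conn.weights2 @ qs[-2])
        qs = qs[: tau_max + 1]
    return CovarianceSet(q=qs, tau_max=tau_max, t_used=0, means=np.zeros(n))


# ---------------------------------------------------------------------------
# panel I/O

def save_panel(path, panel: TimeSeriesPanel, node_labels=None) -> None:
    """Write a single-trial panel as TSV (nodes x time, header of node labels)."""
    path = Path(path)
    if panel.data.ndim != 2:
        raise ParameterError("TSV export supports single-trial panels; use npz for trials")
    labels = node_labels or [f"node{i}" for i in range(panel.n_nodes)]
    header = "\t".join(map(str, labels))
    np.savetxt(path, panel.data, delimiter="\t", header=header, comments="")


def load_panel(path) -> TimeSeriesPanel:
    data = np.loadtxt(Path(path), delimiter="\t", skiprows=1)
    return TimeSeriesPanel(data=np.atleast_2d(data))
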