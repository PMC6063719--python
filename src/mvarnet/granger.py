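"""Granger-causality baselines: residual log-ratios and parametric F-tests.

For a target node i and a conditioning set S, the lag-1 regression

    x_i^t = sum_{j in S} a_ij x_j^{t-1} + eps^t,   t = 2..T

yields the residual ``eps(x_i | x_S) = sqrt(sum_t (eps^t)^2)`` (series are
mean-centered, which plays the role of an intercept in the zero-mean model).

Two scores are used to probe the edge j -> i:

    GRu(j -> i): conditioning on {i} versus {i, j}
    GRc(j -> i): conditioning on all nodes but j versus all nodes

``GrangerScore.value`` is the log of the *squared*-residual (i.e. residual
variance) ratio of the nested fits, so ``exp(value) - 1`` is the relative
RSS increase and the parametric decision

    GRu: exp(value) - 1 > F_isf(alpha, 1, T-3) / (T-3)
    GRc: exp(value) - 1 > F_isf(alpha, 1, T-N-1) / (T-N-1)

is the standard one-degree F-test at level alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .exceptions import ConditioningError, ParameterError
from .mvar import TimeSeriesPanel

#: floor inside logs to absorb rounding when nested residuals tie
EPS_NUMERIC = 1e-12


@dataclass
class GrangerScore:
    value: float  # log variance-ratio of the nested fits, >= 0 up to rounding
    kind: Literal["GRu", "GRc"]
    target: int
    source: int
    residual_full: float  # sqrt(RSS), full model
    residual_reduced: float  # sqrt(RSS), source removed


def _design(panel: TimeSeriesPanel):
    """Centered targets Y (t=2..T) and lagged regressors X (t=1..T-1)."""
    if panel.data.ndim != 2:
        raise ParameterError("Granger scores operate on single-trial panels")
    x = panel.data
    y = x[:, 1:] - x[:, 1:].mean(axis=1, keepdims=True)
    z = x[:, :-1] - x[:, :-1].mean(axis=1, keepdims=True)
    return y, z


def _rss(y_i, z_sub):
    """Residual sum of squares of y_i regressed on rows of z_sub."""
    g = z_sub @ z_sub.T
    h = z_sub @ y_i
    try:
        beta = np.linalg.solve(g, h)
    except np.linalg.LinAlgError as err:
        raise ConditioningError(f"rank-deficient regressor matrix: {err}") from err
    return float(y_i @ y_i - h @ beta)


def residual_std(panel: TimeSeriesPanel, target: int, sources) -> float:
    """sqrt(sum of squared residuals) of the lag-1 regression of ``target``
    on the past of ``sources``."""
    sources = np.atleast_1d(np.asarray(sources, dtype=int))
    if sources.size == 0:
        raise ParameterError("sources must be nonempty")
    if panel.n_samples < sources.size + 2:
        raise ParameterError("too few samples for the requested regression")
    y, z = _design(panel)
    return float(np.sqrt(max(_rss(y[target], z[sources]), 0.0)))


def granger_logratio(
    panel: TimeSeriesPanel, i: int, j: int, kind: Literal["GRu", "GRc"] = "GRc"
) -> GrangerScore:
    """Score for the edge j -> i (see module docstring for the conditioning)."""
    if i == j:
        raise ParameterError("Granger score requires i != j")
    n = panel.n_nodes
    if kind == "GRu":
        reduced, full = [i], [i, j]
    elif kind == "GRc":
        reduced = [k for k in range(n) if k != j]
        full = list(range(n))
    else:
        raise ParameterError(f"unknown kind {kind!r}")
    y, z = _design(panel)
    rss_red = max(_rss(y[i], z[reduced]), EPS_NUMERIC)
    rss_full = max(_rss(y[i], z[full]), EPS_NUMERIC)
    value = float(np.log(max(rss_red, EPS_NUMERIC) / max(rss_full, EPS_NUMERIC)))
    return GrangerScore(
        value=max(value, 0.0),
        kind=kind,
        target=i,
        source=j,
        residual_full=float(np.sqrt(rss_full)),
        residual_reduced=float(np.sqrt(rss_red)),
    )


def f_threshold(alpha: float, t_samples: int, n_nodes: int, kind: Literal["GRu", "GRc"]) -> float:
    """Parametric decision threshold on ``exp(score) - 1``."""
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must lie in (0, 1)")
    dof = t_samples - 3 if kind == "GRu" else t_samples - n_nodes - 1
    if dof <= 0:
        raise ParameterError(f"nonpositive degrees of freedom ({dof})")
    return float(stats.f.isf(alpha, 1, dof) / dof)


def granger_f_test(
    score: GrangerScore, t_samples: int, n_nodes: int, alpha: float = 0.02
):
    """Parametric F-test decision for a score; returns (significant, threshold)."""
    thr = f_threshold(alpha, t_samples, n_nodes, score.kind)
    return bool(np.expm1(score.value) > thr), thr


# ---------------------------------------------------------------------------
# whole-matrix scores (used by the benchmarks and the nonparametric GRc test)

def grc_matrix(panel: TimeSeriesPanel) -> np.ndarray:
    """All conditional scores GRc(j -> i) as an N x N matrix (diagonal 0).

    Uses the exact OLS rank-one downdate: removing regressor j from the full
    model increases the RSS by ``beta_ij^2 / (G^{-1})_jj`` where
    ``G = Z Z^T``.  One matrix inversion serves all N^2 scores.
    """
    y, z = _design(panel)
    g = z @ z.T
    try:
        ginv = np.linalg.inv(g)
    except np.linalg.LinAlgError as err:
        raise ConditioningError(f"singular regressor Gram matrix: {err}") from err
    h = y @ z.T  # h[i, k] = y_i . z_k
    beta = h @ ginv.T  # beta[i, j]
    rss_full = np.einsum("it,it->i", y, y) - np.einsum("ij,ij->i", beta, h)
    rss_full = np.maximum(rss_full, EPS_NUMERIC)
    increase = beta**2 / np.maximum(np.diag(ginv), EPS_NUMERIC)[None, :]
    scores = np.log1p(increase / rss_full[:, None])
    np.fill_diagonal(scores, 0.0)
    return scores


def gru_matrix(panel: TimeSeriesPanel) -> np.ndarray:
    """All unconditional scores GRu(j -> i) as an N x N matrix (diagonal 0)."""
    y, z = _design(panel)
    g = z @ z.T
    h = y @ z.T
    syy = np.einsum("it,it->i", y, y)
    n = panel.n_nodes
    scores = np.zeros((n, n))
    gd = np.diag(g)
    for i in range(n):
        rss_red = syy[i] - h[i, i] ** 2 / max(gd[i], EPS_NUMERIC)
        rss_red = max(rss_red, EPS_NUMERIC)
        for j in range(n):
            if j == i:
                continue
            # 2x2 normal equations for regressors {z_i, z_j}
            a, b, c = gd[i], g[i, j], gd[j]
            det = a * c - b * b
            if abs(det) < EPS_NUMERIC:
                scores[i, j] = 0.0
                continue
            hi, hj = h[i, i], h[i, j]
            expl = (c * hi * hi - 2 * b * hi * hj + a * hj * hj) / det
            rss_full = max(syy[i] - expl, EPS_NUMERIC)
            scores[i, j] = max(np.log(rss_red / rss_full), 0.0)
    return scores


def parametric_decisions(
    scores: np.ndarray, t_samples: int, kind: Literal["GRu", "GRc"], alpha: float = 0.02
) -> np.ndarray:
    """Vectorized F-test over a score matrix; diagonal is always False."""
    n = scores.shape[0]
    thr = f_threshold(alpha, t_samples, n, kind)
    dec = np.expm1(scores) > thr
    np.fill_diagonal(dec, False)
    return dec
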