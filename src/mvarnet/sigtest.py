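"""Local and global nonparametric significance decisions.

Both tests compare an observed coefficient matrix against a surrogate
ensemble:

* the *local* test builds, for every connection (i, j), the null from the S
  surrogate values of that same matrix element and thresholds its tail(s);
* the *global* test pools all S*N^2 surrogate matrix elements into a single
  null and applies one common threshold.

Thresholds are type-1 empirical quantiles (inverted ECDF, no interpolation),
so a threshold is always a realized surrogate value; the decision requires
the observation to lie strictly beyond it.  One-tailed tests cut the upper
alpha tail; two-tailed tests cut alpha/2 in each tail (needed for inhibitory,
i.e. negative, weights).  Empirical p-values use the standard +1 permutation
correction and are never exactly zero.

No multiple-comparison correction is applied anywhere: the per-connection
p-values are the raw material for any such downstream procedure.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from ._seeds import child_seed
from .exceptions import ParameterError
from .mvar import CoefficientEstimate, TimeSeriesPanel
from .surrogate import NullEnsemble, make_surrogate

Tails = Literal["one", "two"]


@dataclass
class DetectionReport:
    """Per-connection decisions and empirical p-values."""

    decisions: np.ndarray  # boolean N x N
    pvals: np.ndarray  # in (0, 1]
    thresholds: np.ndarray | tuple  # per-edge (local) or scalar-like (global)
    alpha: float
    tails: Tails
    test_tag: str

    @property
    def n_nodes(self) -> int:
        return self.decisions.shape[0]


def _check_alpha(alpha, n_surrogates):
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must lie in (0, 1)")
    if n_surrogates < int(np.ceil(1.0 / alpha)):
        warnings.warn(
            f"S={n_surrogates} surrogates is small for alpha={alpha}; "
            "tail quantiles are coarse",
            stacklevel=3,
        )


def _quantile(values, q, axis=0):
    return np.quantile(values, q, axis=axis, method="inverted_cdf")


def _pvals(obs, null, tails):
    s = null.shape[0]
    if tails == "one":
        exceed = (null >= obs[None, ...]).sum(axis=0)
    else:
        exceed = (np.abs(null) >= np.abs(obs)[None, ...]).sum(axis=0)
    return (1.0 + exceed) / (s + 1.0)


def _decide(obs, lo, hi, tails):
    if tails == "one":
        return obs > hi
    return (obs > hi) | (obs < lo)


def _observed(estimate):
    if isinstance(estimate, CoefficientEstimate):
        return estimate.a
    return np.asarray(estimate, dtype=float)


def local_test(
    estimate: CoefficientEstimate | np.ndarray,
    null: NullEnsemble,
    alpha: float = 0.02,
    tails: Tails = "one",
) -> DetectionReport:
    """Per-connection null: the same matrix element across the S surrogates."""
    obs = _observed(estimate)
    vals = null.values
    _check_alpha(alpha, null.n_surrogates)
    if tails == "one":
        hi = _quantile(vals, 1.0 - alpha, axis=0)
        lo = np.full_like(hi, -np.inf)
    else:
        hi = _quantile(vals, 1.0 - alpha / 2.0, axis=0)
        lo = _quantile(vals, alpha / 2.0, axis=0)
    return DetectionReport(
        decisions=_decide(obs, lo, hi, tails),
        pvals=_pvals(obs, vals, tails),
        thresholds=hi if tails == "one" else (lo, hi),
        alpha=alpha,
        tails=tails,
        test_tag="local",
    )


def global_test(
    estimate: CoefficientEstimate | np.ndarray,
    null: NullEnsemble,
    alpha: float = 0.02,
    tails: Tails = "one",
    include_diagonal: bool = True,
) -> DetectionReport:
    """Single pooled null from all S*N^2 surrogate matrix elements.

    ``include_diagonal=False`` drops the surrogate diagonals from the pool
    (CS surrogates preserve autocovariances, so their diagonal entries would
    contaminate the pooled null).
    """
    obs = _observed(estimate)
    vals = null.values
    _check_alpha(alpha, null.n_surrogates)
    if include_diagonal or vals.ndim != 3:
        pool = vals.reshape(vals.shape[0], -1)
    else:
        off = ~np.eye(vals.shape[-1], dtype=bool)
        pool = vals[:, off]
    flat = pool.ravel()
    if tails == "one":
        hi = float(_quantile(flat, 1.0 - alpha))
        lo = -np.inf
    else:
        hi = float(_quantile(flat, 1.0 - alpha / 2.0))
        lo = float(_quantile(flat, alpha / 2.0))
    s_eff = flat.size
    if tails == "one":
        ranks = np.sort(flat)
        exceed = s_eff - np.searchsorted(ranks, obs.ravel(), side="left")
    else:
        ranks = np.sort(np.abs(flat))
        exceed = s_eff - np.searchsorted(ranks, np.abs(obs).ravel(), side="left")
    pvals = ((1.0 + exceed) / (s_eff + 1.0)).reshape(obs.shape)
    return DetectionReport(
        decisions=_decide(obs, lo, hi, tails),
        pvals=pvals,
        thresholds=(lo, hi),
        alpha=alpha,
        tails=tails,
        test_tag="global",
    )


def nonparam_grc_test(
    panel: TimeSeriesPanel,
    mode: Literal["target", "full"] = "full",
    n_surrogates: int = 100,
    alpha: float = 0.02,
    seed: int = 0,
    method: str = "RP",
) -> DetectionReport:
    """Nonparametric (surrogate) test for conditional Granger scores.

    ``full`` shuffles all node series simultaneously and recomputes the whole
    GRc matrix per surrogate; ``target`` shuffles only the target node's
    series, building each target row's null separately.  Decisions use
    local-style per-edge one-tailed thresholds (GRc scores are nonnegative).
    """
    from .granger import grc_matrix

    obs = grc_matrix(panel)
    n = panel.n_nodes
    _check_alpha(alpha, n_surrogates)
    null = np.empty((n_surrogates, n, n))
    if mode == "full":
        for s in range(n_surrogates):
            surr = make_surrogate(panel, method, seed=child_seed(seed, s))
            null[s] = grc_matrix(surr)
    elif mode == "target":
        data = panel.data
        if data.ndim != 2:
            raise ParameterError("target-mode GRc test needs a single-trial panel")
        for s in range(n_surrogates):
            for i in range(n):
                shuffled = data.copy()
                one = make_surrogate(
                    TimeSeriesPanel(data[i : i + 1]), method, seed=child_seed(seed, s, i)
                )
                shuffled[i] = one.data[0]
                null[s, i] = grc_matrix(TimeSeriesPanel(shuffled))[i]
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    hi = _quantile(null, 1.0 - alpha, axis=0)
    dec = obs > hi
    np.fill_diagonal(dec, False)
    return DetectionReport(
        decisions=dec,
        pvals=_pvals(obs, null, "one"),
        thresholds=hi,
        alpha=alpha,
        tails="one",
        test_tag=f"grc-{mode}",
    )


def save_report(path, report: DetectionReport) -> None:
    """JSON summary + delimited decision/p-value matrices."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savetxt(path / "decisions.csv", report.decisions.astype(int), fmt="%d", delimiter=",")
    np.savetxt(path / "pvals.csv", report.pvals, delimiter=",")
    summary = {
        "test_tag": report.test_tag,
        "alpha": report.alpha,
        "tails": report.tails,
        "n_nodes": int(report.n_nodes),
        "n_detected": int(report.decisions.sum()),
    }
    (path / "summary.json").write_text(json.dumps(summary, indent=2))
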