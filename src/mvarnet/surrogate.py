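"""Null time series by randomization, and surrogate coefficient ensembles.

Four randomization schemes, each applied to every node's series
independently of the others:

``RP``  random permutation of the time indices;
``CS``  random circular shift by t0 drawn uniformly in {1..T} (t0 = 1
        returns the original series);
``PR``  Fourier phase randomization: every DFT coefficient is rotated by an
        independent uniform phase, with conjugate-symmetric assignment so the
        inverse transform is exactly real (DC and Nyquist bins keep phase 0;
        amplitudes are untouched);
``STD`` replacement of all series by i.i.d. N(0, sbar^2) where sbar is the
        per-node standard deviation averaged over nodes.

RP and CS destroy all lagged covariance structure off the diagonal of Q^0;
CS preserves each node's autocovariance (up to wrap-around terms), which is
why it cannot build a null for self-connections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from ._seeds import child_seed, rng_from
from .exceptions import ConditioningError, ParameterError
from .mvar import (
    CoefficientEstimate,
    TimeSeriesPanel,
    estimate_order1,
    estimate_order2,
    lagged_covariance,
)

SurrogateMethod = Literal["RP", "CS", "PR", "STD"]
EstimatorTag = Literal["order1", "order2", "grc"]

_MAX_RETRIES = 5


@dataclass
class NullEnsemble:
    """S surrogate-estimated coefficient (or GRc score) matrices."""

    values: np.ndarray  # (S, N, N) for order1/grc; (S, 2, N, N) for order2
    method: SurrogateMethod
    estimator_tag: EstimatorTag
    seed: int

    @property
    def n_surrogates(self) -> int:
        return self.values.shape[0]

    # conventional symbol for the ensemble size
    @property
    def S(self) -> int:  # noqa: N802
        return self.values.shape[0]


def _surrogate_trial(x: np.ndarray, method: SurrogateMethod, rng) -> np.ndarray:
    n, t = x.shape
    if method == "RP":
        # independent permutation per node, vectorized via random-key argsort
        idx = np.argsort(rng.random((n, t)), axis=1)
        return np.take_along_axis(x, idx, axis=1)
    if method == "CS":
        t0 = rng.integers(1, t + 1, size=n)  # t0 in {1..T}; t0=1 is identity
        idx = (np.arange(t)[None, :] + (t0 - 1)[:, None]) % t
        return np.take_along_axis(x, idx, axis=1)
    if method == "PR":
        spec = np.fft.rfft(x, axis=1)
        n_bins = spec.shape[1]
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(n, n_bins))
        phases[:, 0] = 0.0  # DC stays real
        if t % 2 == 0:
            phases[:, -1] = 0.0  # Nyquist stays real
        return np.fft.irfft(spec * np.exp(1j * phases), n=t, axis=1)
    if method == "STD":
        sbar = float(np.mean(x.std(axis=1)))
        return rng.standard_normal((n, t)) * sbar
    raise ParameterError(f"unknown surrogate method {method!r}")


def make_surrogate(
    panel: TimeSeriesPanel, method: SurrogateMethod = "RP", seed: int = 0
) -> TimeSeriesPanel:
    """One surrogate panel; multi-trial panels are shuffled trial by trial."""
    if panel.n_samples < 2:
        raise ParameterError("need T >= 2")
    if panel.data.ndim == 2:
        rng = rng_from(seed, 3, 0)
        data = _surrogate_trial(panel.data, method, rng)
    else:
        data = np.stack(
            [
                _surrogate_trial(x, method, rng_from(seed, 3, r))
                for r, x in enumerate(panel.trials())
            ]
        )
    return TimeSeriesPanel(data=data, sampling_tag=panel.sampling_tag)


def _estimate_matrix(panel: TimeSeriesPanel, estimator: EstimatorTag) -> np.ndarray:
    if estimator == "order1":
        covs = lagged_covariance(panel, tau_max=1)
        return estimate_order1(covs).a
    if estimator == "order2":
        covs = lagged_covariance(panel, tau_max=2)
        est = estimate_order2(covs)
        return np.stack([est.a, est.a2])
    if estimator == "grc":
        from .granger import grc_matrix

        return grc_matrix(panel)
    raise ParameterError(f"unknown estimator {estimator!r}")


def build_null(
    panel: TimeSeriesPanel,
    n_surrogates: int,
    method: SurrogateMethod = "RP",
    estimator: EstimatorTag = "order1",
    seed: int = 0,
) -> NullEnsemble:
    """Ensemble of S surrogate coefficient matrices.

    Per-surrogate seeds are derived from the master seed with a counter, so
    the ensemble is reproducible and independent of evaluation order.  A
    surrogate whose covariance turns out singular is re-drawn (bounded
    retries).
    """
    if n_surrogates < 1:
        raise ParameterError("need n_surrogates >= 1")
    values = []
    for s in range(n_surrogates):
        for retry in range(_MAX_RETRIES):
            sub = child_seed(seed, s, retry)
            try:
                surr = make_surrogate(panel, method, seed=sub)
                values.append(_estimate_matrix(surr, estimator))
                break
            except ConditioningError:
                continue
        else:
            raise ConditioningError(
                f"surrogate {s} remained singular after {_MAX_RETRIES} redraws"
            )
    return NullEnsemble(
        values=np.asarray(values), method=method, estimator_tag=estimator, seed=seed
    )
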