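"""Multiunit-activity-envelope (MUAe) preprocessing and the pre/post-stimulus
connectivity workflow, exercised on synthetic electrode-like fixtures.

The preprocessing chain emulates the standard MUAe extraction from
extracellular electrode recordings: (integer-factor anti-aliased
downsampling to 1 kHz if needed,) third-order Butterworth high-pass at
400 Hz (0.8 of the Nyquist frequency), full-wave rectification, and
averaging in contiguous 4-ms bins.  The retained window covers the 1000 ms
around stimulus onset (400 ms before, 600 ms after), i.e. exactly 250 bins
with the onset at bin 100.

Because no public recording accompanies the original study, the fixture
generator :func:`synth_electrode_fixture` produces *synthetic* trials x
channels raw traces at 1 kHz: broadband noise carriers whose amplitude
envelopes follow a ground-truth MVAR(1) process at 4-ms resolution, with a
multiplicative activity increase after onset and injectable directed
envelope couplings.  It emulates the qualitative features the connectivity
pipeline relies on (poststimulus activation, exponentially decaying envelope
autocovariance, directed lagged interactions), not any particular animal's
data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from ._seeds import child_seed, rng_from
from .exceptions import ParameterError, ShapeError, StabilityError
from .mvar import CoefficientEstimate, TimeSeriesPanel, estimate_order1, lagged_covariance
from .sigtest import DetectionReport, global_test, local_test
from .surrogate import build_null

BIN_MS = 4
WINDOW_BINS = 250  # 1000 ms at 4-ms bins
PRE_BINS = 100  # 400 ms before onset
POST_BINS = 150  # 600 ms after onset
TEST_WINDOW_BINS = 50  # each of the pre/post analysis windows spans 200 ms


@dataclass
class RawTrialSet:
    """Synthetic raw traces: R trials x C channels x L samples at fs Hz."""

    signals: np.ndarray
    onset_index: int
    fs: float = 1000.0

    def __post_init__(self):
        s = np.asarray(self.signals, dtype=float)
        if s.ndim != 3:
            raise ShapeError(f"signals must be (R, C, L), got {s.shape}")
        self.signals = s

    @property
    def n_trials(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]


@dataclass
class MUAePanel:
    """Rectified-and-binned envelope: R trials x C channels x 250 bins.

    Bin 100 is the first poststimulus bin; the pre/post analysis windows are
    bins [50, 100) and [100, 150) (200 ms each).
    """

    envelope: np.ndarray
    onset_bin: int = PRE_BINS

    def __post_init__(self):
        e = np.asarray(self.envelope, dtype=float)
        if e.ndim != 3 or e.shape[2] != WINDOW_BINS:
            raise ShapeError(f"envelope must be (R, C, {WINDOW_BINS}), got {e.shape}")
        if (e < 0).any():
            raise ParameterError("envelope must be nonnegative")
        self.envelope = e

    def window(self, which: str) -> np.ndarray:
        """(R, C, 50) slice for the 'pre' or 'post' 200-ms analysis window."""
        if which == "pre":
            sl = slice(self.onset_bin - TEST_WINDOW_BINS, self.onset_bin)
        elif which == "post":
            sl = slice(self.onset_bin, self.onset_bin + TEST_WINDOW_BINS)
        else:
            raise ParameterError("window must be 'pre' or 'post'")
        return self.envelope[:, :, sl]

    def mean_activity(self, which: str) -> np.ndarray:
        """Per-channel mean envelope in a window."""
        return self.window(which).mean(axis=(0, 2))


def preprocess_muae(raw: RawTrialSet, highpass_hz: float = 400.0, order: int = 3) -> MUAePanel:
    """High-pass, rectify and bin raw traces into the 250-bin MUAe panel."""
    x = raw.signals
    fs = raw.fs
    onset = raw.onset_index
    if fs < 1000:
        raise ParameterError("need fs >= 1000 Hz")
    if fs > 1000:
        factor = fs / 1000.0
        if abs(factor - round(factor)) > 1e-9:
            raise ParameterError("only integer-factor downsampling to 1 kHz is supported")
        x = signal.decimate(x, int(round(factor)), axis=2, zero_phase=True)
        onset = int(round(onset / factor))
        fs = 1000.0
    pre_samples = PRE_BINS * BIN_MS
    post_samples = POST_BINS * BIN_MS
    if onset < pre_samples or x.shape[2] < onset + post_samples:
        raise ParameterError(
            f"recording too short for the 1000-ms window around onset "
            f"(onset={onset}, L={x.shape[2]})"
        )
    sos = signal.butter(order, highpass_hz, btype="highpass", fs=fs, output="sos")
    filtered = signal.sosfilt(sos, x, axis=2)
    rect = np.abs(filtered[:, :, onset - pre_samples : onset + post_samples])
    r, c, _ = rect.shape
    envelope = rect.reshape(r, c, WINDOW_BINS, BIN_MS).mean(axis=3)
    return MUAePanel(envelope=envelope)


def synth_electrode_fixture(
    n_channels: int = 8,
    n_trials: int = 100,
    coupling: list | None = None,
    onset_gain: float = 2.0,
    seed: int = 0,
    *,
    self_coefficient: float = 0.7,
    envelope_noise: float = 0.4,
    baseline: float = 1.0,
    coupling_window: str = "post",
    length: int = 1200,
    onset_index: int = 500,
    fs: float = 1000.0,
) -> RawTrialSet:
    """Synthetic electrode-like raw trials (stand-in fixture, not real data).

    The per-trial amplitude envelope of channel c follows, at 4-ms
    resolution, ``z_t = A z_{t-1} + xi_t`` with ``A`` carrying
    ``self_coefficient`` on the diagonal and the requested couplings
    ``(source, target, gain)`` off it; the positive envelope is
    ``baseline * (1 + z_t)`` (clipped at 5% of baseline), multiplied by
    ``onset_gain`` from the onset on.  ``coupling_window="post"`` activates
    the couplings only after onset, ``"all"`` throughout.  The raw trace is
    the envelope (held per 4-ms bin) modulating unit white noise.
    """
    if n_channels < 2 or n_trials < 1:
        raise ParameterError("need n_channels >= 2 and n_trials >= 1")
    if onset_index < PRE_BINS * BIN_MS or length < onset_index + POST_BINS * BIN_MS:
        raise ParameterError("onset/length do not cover the 1000-ms analysis window")
    coupling = coupling or []
    a_base = np.eye(n_channels) * self_coefficient
    a_coupled = a_base.copy()
    for edge in coupling:
        src, dst, gain = edge
        a_coupled[dst, src] += gain
    for a in (a_base, a_coupled):
        rho = float(np.max(np.abs(np.linalg.eigvals(a))))
        if rho >= 1.0:
            raise StabilityError(f"envelope dynamics unstable (rho={rho:.3f})")

    n_bins = length // BIN_MS
    onset_bin = onset_index // BIN_MS
    sd_xi = envelope_noise * np.sqrt(1.0 - self_coefficient**2)  # stationary std ~= envelope_noise
    signals = np.empty((n_trials, n_channels, length))
    for r in range(n_trials):
        rng = rng_from(seed, 4, r)
        z = np.zeros(n_channels)
        env = np.empty((n_channels, n_bins))
        for b in range(n_bins):
            a = a_coupled if (coupling_window == "all" or b >= onset_bin) else a_base
            z = a @ z + sd_xi * rng.standard_normal(n_channels)
            env[:, b] = z
        env = baseline * np.clip(1.0 + env, 0.05, None)
        env[:, onset_bin:] *= onset_gain
        carrier = rng.standard_normal((n_channels, length))
        signals[r] = np.repeat(env, BIN_MS, axis=1)[:, :length] * carrier
    return RawTrialSet(signals=signals, onset_index=onset_index, fs=fs)


def screen_channels(panel: MUAePanel, k: float = 5.0) -> np.ndarray:
    """Boolean mask of channels kept by the outlier screen: a channel is
    excluded when its mean envelope exceeds ``k`` times the median channel's."""
    means = panel.envelope.mean(axis=(0, 2))
    return means <= k * np.median(means)


def trial_connectivity(
    panel: MUAePanel,
    window: str = "post",
    surrogate: str = "RP",
    n_surrogates: int = 400,
    alpha: float = 0.01,
    tails: str = "two",
    test: str = "local",
    seed: int = 0,
):
    """MVAR estimate + surrogate significance test on one analysis window.

    Per-trial centering, covariances averaged over trials, Yule-Walker
    order-1 estimate; surrogates shuffle each trial independently.  Returns
    ``(DetectionReport, CoefficientEstimate)``.
    """
    win = panel.window(window)
    if win.shape[0] < 2 or win.shape[2] < 3:
        raise ParameterError("need >=2 trials and >=3 bins per trial")
    ts = TimeSeriesPanel(data=win, sampling_tag=f"{BIN_MS}ms-bin")
    est = estimate_order1(lagged_covariance(ts, 1))
    null = build_null(ts, n_surrogates, surrogate, "order1", seed=child_seed(seed, 5))
    if test == "local":
        rep = local_test(est, null, alpha, tails)
    else:
        rep = global_test(est, null, alpha, tails)
    return rep, est


def node_strength_change(
    pre_report: DetectionReport,
    pre_estimate: CoefficientEstimate,
    post_report: DetectionReport,
    post_estimate: CoefficientEstimate,
    activity_pre: np.ndarray,
    activity_post: np.ndarray,
):
    """Per-channel change of summed significant |weights| versus activity.

    For each channel: Delta(sum of significant incoming |weights|),
    Delta(outgoing), Delta(mean MUAe); plus the Pearson correlation of each
    weight-change column with the activity change (nan when undefined, e.g.
    no significant edges anywhere).

    Returns ``(records, correlations)`` where ``records`` is a structured
    per-channel dict of arrays.
    """
    def _sums(report, estimate):
        w = np.abs(estimate.a) * report.decisions
        off = w.copy()
        np.fill_diagonal(off, 0.0)
        return off.sum(axis=1), off.sum(axis=0)  # incoming (row), outgoing (col)

    in_pre, out_pre = _sums(pre_report, pre_estimate)
    in_post, out_post = _sums(post_report, post_estimate)
    d_in = in_post - in_pre
    d_out = out_post - out_pre
    d_act = np.asarray(activity_post, dtype=float) - np.asarray(activity_pre, dtype=float)
    if d_act.shape != d_in.shape:
        raise ShapeError("activity vectors do not match the channel set")

    def _corr(a, b):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return float("nan"), float("nan")
        r, p = stats.pearsonr(a, b)
        return float(r), float(p)

    r_in, p_in = _corr(d_in, d_act)
    r_out, p_out = _corr(d_out, d_act)
    records = {
        "delta_incoming": d_in,
        "delta_outgoing": d_out,
        "delta_activity": d_act,
    }
    correlations = {
        "incoming": {"r": r_in, "p": p_in},
        "outgoing": {"r": r_out, "p": p_out},
    }
    return records, correlations


def envelope_autocov(panel: MUAePanel, window: str = "post", max_lag: int = 3) -> np.ndarray:
    """Per-channel envelope autocovariance averaged over trials, lags
    0..max_lag (trial-wise centering).  Used for the model-adequacy check:
    an MVAR(1) envelope has log-autocovariance linear in the lag."""
    win = panel.window(window)
    r, c, t = win.shape
    xc = win - win.mean(axis=2, keepdims=True)
    out = np.zeros((c, max_lag + 1))
    for lag in range(max_lag + 1):
        out[:, lag] = np.mean(xc[:, :, lag:] * xc[:, :, : t - lag], axis=(0, 2))
    return out
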