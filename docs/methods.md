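# Methods

## Model

`mvarnet` detects directed connections in networks whose activity follows a
multivariate autoregressive (MVAR) process,

    x_t = A x_{t-1} + zeta_t,            zeta_t ~ N(0, Sigma) i.i.d.,

or, at order 2, `x_t = A1 x_{t-1} + A2 x_{t-2} + zeta_t`.  The entries of
`A` are the connection weights; a connection j -> i exists when
`A_ij != 0`.  Stationarity requires the (companion-form) spectral radius of
the dynamics to be below one.  The innovations may be cross-correlated:
`Sigma = M M^T` with a mixing matrix `M = D + c R` (`D` diagonal positive,
`R` dense random with N(0, 1/N) entries), so the induced correlation level
scales as `O(c^2)` independently of the network size.

## Estimation

Coefficients are estimated from the empirical lagged covariances

    Qhat^tau_ij = (1/(T - tau_max - 1)) sum_{t=1..T-tau_max}
                  (x_i^{t+tau} - xbar_i)(x_j^t - xbar_j)

through the Yule-Walker relation `Q^1 = A Q^0`:

    order 1:  a = Qhat^1 (Qhat^0)^{-1}
    order 2:  (a1 a2) = [Qhat^1 Qhat^2] * [[Qhat^0, Qhat^1],
                                           [Qhat^1', Qhat^0]]^{-1}

This is exactly the OLS regression of `x_t` on its lagged values (verified in
the tests against `numpy.linalg.lstsq`; the only difference, of order 1/T,
comes from mean handling).  All lags share the common summation window
`t = 1..T - tau_max`; a per-lag maximal window is available behind a switch,
as is the plain `1/(T - tau_max)` normalization — ratios and tests are
insensitive to both dialects.  Multi-trial panels are centered per trial and
the per-trial covariance matrices averaged before the single inversion,
matching how trial-segmented electrode envelopes must be handled (the trial
mean is a nuisance parameter per trial).  Inversion refuses matrices with
condition number above 1e12 and names the lowest-variance nodes, because a
silent solve would amplify noise into spurious coefficients.

## Granger baselines

For target i and conditioning set S, the lag-1 regression residual is
`eps(x_i | x_S) = sqrt(RSS)`.  The pairwise (GRu) and conditional (GRc)
scores are the log ratios of the nested residual *variances* —
`value = ln(RSS_reduced / RSS_full)` — so that `exp(value) - 1` is the
relative RSS increase and the parametric decisions

    GRu:  exp(value) - 1 > F_isf(alpha; 1, T-3) / (T-3)
    GRc:  exp(value) - 1 > F_isf(alpha; 1, T-N-1) / (T-N-1)

are standard one-degree F-tests (the variance scale is the one on which the
F statistic is exact; the white-noise positive rate then equals alpha, which
the tests verify).  Whole-matrix GRc scores use the OLS rank-one downdate
`RSS_{-j} = RSS_full + beta_j^2 / (G^{-1})_{jj}`, turning N^2 regressions
into one matrix inversion.  A floor of 1e-12 inside the logs absorbs ties
between nested residuals.

## Surrogate nulls and the significance tests

Null coefficient distributions are built by re-estimating the full
coefficient matrix on S randomized copies of the panel.  Randomizations are
applied to each node independently:

- **RP** — random permutation of time indices (destroys auto- and
  cross-covariances; the reference method);
- **CS** — circular shift by t0 uniform in {1..T} (preserves each node's
  autocovariance up to wrap-around, hence cannot test self-connections);
- **PR** — Fourier phase randomization.  The recipe "rotate every DFT
  coefficient by an independent uniform phase" does not yield a real inverse
  transform, so phases are assigned conjugate-symmetrically (DC and Nyquist
  bins stay real); a take-the-real-part fallback is deliberately not the
  default since it halves the surrogate variance;
- **STD** — replacement by i.i.d. Gaussians whose standard deviation is the
  node-average of the per-node standard deviations (destroys all spatial
  heterogeneity; a control for how much the tests use it).

The **local** test thresholds, for every matrix element, the empirical tail
of its own S surrogate values; the **global** test pools all S*N^2 surrogate
elements into one null.  Thresholds are type-1 empirical quantiles (inverted
ECDF): always realized surrogate values, conservative and well defined at
small S.  With strict exceedance, the exact level of the one-tailed local
test under an exchangeable null is `(S - ceil((1-alpha)S)) / (S+1)` — e.g.
0.01995 at S=400, alpha=0.02 — so no finite-S correction is applied.
Two-tailed tests cut alpha/2 per tail (used for excitatory/inhibitory
networks and the envelope workflow).  p-values carry the +1 permutation
correction.  Global pooling includes the diagonal by default ("all S*N^2
elements"); a flag excludes it because CS surrogates would contaminate the
pool with preserved autocovariances.  No multiple-comparison correction is
applied anywhere; the per-edge p-values are inputs for any such downstream
procedure.

Per-surrogate seeds derive from the master seed through a counter-based
`SeedSequence` scheme, so ensembles are reproducible and element k does not
depend on how many surrogates were requested.

## Synthetic study conditions

The generator defaults define the benchmark conditions:

- **random** networks: every entry (diagonal included) exists with
  probability `density`; benchmarks draw N uniform in [50, 90] (or fix
  N = 70), density uniform in [0.1, 0.3], and per-network weight ranges
  `w_min ~ U[0.01, 0.05]`, `w_max = w_min + U[0.02, 0.06]`.  The weight
  scale follows a stationarity budget: for dense positive matrices the
  spectral radius grows like `N * density * mean(w)`, so mean weights a few
  times 1/(N*density) keep the dynamics stable yet hard enough that
  detection is nontrivial at T = 3000.  Whenever the radius reaches 0.95 all
  weights are rescaled by `0.95/rho` (at order 2, `A1` by `s` and `A2` by
  `s^2`, which scales the companion eigenvalues exactly by `s`); the factor
  is recorded.
- **modular**: two equal groups plus a hub set (5-15% of nodes); intra-group,
  hub<->group and hub-hub edges at the requested density, no direct
  inter-group edges, every hub guaranteed at least one edge into each group.
- **hierarchical**: one center, B ~ U{5..10} intermediates, L ~ U{5..10}
  leaves per intermediate, self-connections everywhere.  Being feedforward,
  the radius tracks the self weights rather than the density, so the weight
  draw is larger (`w_min ~ U[0.1, 0.2]`, `w_max = w_min + U[0.1, 0.3]`);
  the same budget argument as above, applied to a near-nilpotent graph.
- **ei**: a fraction r of source nodes has all outgoing weights negated;
  tested two-tailed.
- innovation mixing strength `c = 0.1` (about 5% input correlations) in the
  "correlated inputs" conditions.  This value was calibrated to the ambient
  behavior the protocol specifies — RP/CS local tests holding the nominal
  false-alarm level under correlated inputs — before any headline quantity
  was computed.  At strong mixing (c >= 0.3) the estimator variance of
  absent edges exceeds what any within-trial randomization reproduces
  ((Q0^{-1})_jj Q0_jj > 1 grows with cross-correlation) and *all* surrogate
  tests drift anti-conservative; see Limitations.

Benchmark replicate counts default to desk scale (20-30 networks per
condition instead of 500); all protocols take a single master seed and are
reproducible record-for-record.

## Electrode-envelope workflow

The MUAe chain: (optional integer-factor decimation to 1 kHz,) third-order
Butterworth high-pass at 400 Hz (0.8 Nyquist, causal `sosfilt`), full-wave
rectification, mean over non-overlapping 4-ms bins — exactly 250 bins
covering 400 ms before to 600 ms after stimulus onset.  "4-ms smoothing" is
implemented as rectify-then-bin (the moving-average-then-decimate variant is
a recognized dialect, not implemented as default).  An outlier screen
excludes channels whose mean envelope exceeds k times the median channel
(default k = 5).

The fixture generator is a *synthetic stand-in* (no public recording exists
for this workflow): channel envelopes follow a ground-truth MVAR(1) at 4-ms
resolution (self coefficient 0.7, stationary fluctuation std 0.4 around a
unit baseline, clipped at 5% of baseline), multiplied by `onset_gain` after
onset; directed couplings can be injected, by default only active
post-onset.  The raw 1-kHz trace is that envelope modulating unit white
noise.  What the fixture reproduces: the post-stimulus activation, an
envelope autocovariance decaying exponentially over the first two 4-ms lags,
and detectable directed lagged interactions.  What it does not reproduce:
spike waveforms, 1/f background, cross-channel volume conduction, latency
jitter, non-Gaussian trial-to-trial variability.  The narrow 400-500 Hz
passband at 1 kHz makes the per-bin rectified noise both larger and more
bin-correlated than an ideal demodulator would give; this multiplicative
measurement noise attenuates the estimated envelope coefficients (the
fixture's planted gains of ~0.25 appear as estimates of ~0.08) and flattens
the autocovariance beyond ~8 ms.  Passing tests therefore show the pipeline
recovers planted envelope dynamics under realistic attenuation — not that it
would recover any particular biological effect size.

Windowed connectivity uses 50-bin (200 ms) pre/post windows, per-trial
centering, trial-averaged covariances, and the local two-tailed test with
per-trial independent shuffling.

## Numerical choices

- Burn-in 100 steps, initial state N(0, Sigma).
- `zeta = M u` with `u` standard normal, so the innovation covariance is
  `M M^T` exactly (no Cholesky of a possibly near-singular Sigma).
- Theoretical covariances via `scipy.linalg.solve_discrete_lyapunov`
  (companion form at order 2), symmetrized against rounding.
- Surrogates with singular covariances are redrawn (at most 5 times) under a
  fresh counter seed.
- ROC/AUC via scikit-learn, Spearman via scipy; self-connections excluded
  from ROC and false-alarm/miss rates unless an experiment targets them.

## Limitations

- The local surrogate tests are exact only against the randomization null;
  under strong innovation cross-correlation they become mildly
  anti-conservative (measured ~3-6% at nominal 2% for mixing c = 0.3-0.5).
  The conditional Granger F-test does not drift, but pays a higher miss
  rate.
- Granger regressions use one lag; model orders above 2, order selection,
  and regularized estimators are out of scope, as are frequency-resolved
  tests and multiple-comparison corrections.
- The envelope fixture is a stand-in: conclusions about real recordings
  require real recordings.
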