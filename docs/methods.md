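# Methods

## Detection model

An SSVEP epoch is modeled as a linear mixture per channel $j$:
$x_{j,t} = r_{1,j}\, s_t + r_{2,j}\, n_t$, with a shared evoked component
$s_t$ (a harmonic stack phase-locked to the flicker) and channel-specific
background noise.  A spatial filter $\omega$ combines channels to recover
$s_t$; since the mixing coefficients are unknown and the ideal
reconstruction constraints are overdetermined, the filter is chosen by an
empirical criterion instead.

The distance-minimizing detector minimizes the summed squared distances
between all ordered pairs of same-target filtered training trials subject
to unit power of the combined training signal, solved as the minimal
generalized eigenvector of $(P, Q)$; see the README for the formulas.
Details that the criterion leaves open, and how this package resolves them:

* **Centering.**  Each trial is per-channel mean-centered before building
  both $P$ and $Q$ (toggle `center=`, default on).  $Q$ is
  covariance-based and therefore centers internally; centering $P$'s trials
  as well keeps the two matrices consistent.  After the 7–70 Hz band-pass
  the means are ≈ 0 and the toggle is immaterial.
* **Covariance estimator.**  Unbiased, divisor $T-1$.
* **Ordered vs unordered pairs.**  Ordered pairs ($m_2 \ne m_1$), as the
  double sum is written; the resulting factor 2 cancels in the eigenvector
  and in the argmin, so the choice is inert but fixed.
* **Regularization.**  $Q \leftarrow Q + \varepsilon I$ with
  $\varepsilon = 10^{-8}\,\mathrm{tr}(Q)/N_c$ before factorization, a guard
  against rank deficiency with few channels/samples that stays far below
  test tolerances otherwise.  A $Q$ that is singular beyond this (e.g.
  constant channels) raises with advice rather than returning garbage.
* **Solver.**  `scipy.linalg.eigh(P, Q)` — the symmetric-definite
  formulation, numerically preferable to forming $Q^{-1}P$; eigenvalue ties
  break deterministically (first eigenvector).  The returned vector is
  rescaled so $\omega' Q \omega = 1$ exactly and sign-canonicalized
  (largest-magnitude entry positive), because the ensemble decision rule is
  sign-sensitive.
* **Templates.**  Plain arithmetic means of the raw (uncentered) training
  trials.
* **Strict shapes.**  A test epoch must match the template geometry
  exactly; no implicit truncation or padding (silent truncation hides
  bugs).

TRCA is included as the standard comparison detector: per target, maximize
the inter-trial covariance of the filtered signal relative to aggregate
variance (maximal generalized eigenvector), classify by Pearson correlation
between the ensemble-filtered test epoch and templates.  The ensemble
variant mirrors the distance detector's structure so benchmarks compare the
criterion, not the architecture.

## Preprocessing

Defaults, in order: polyphase resample to 250 Hz (anti-alias FIR; the
1000 → 250 Hz case is exact integer decimation), second-order IIR notch at
50 Hz with quality factor 30, 4th-order Butterworth band-pass 7–70 Hz, both
filters applied forward–backward (zero phase), then a crop starting 135 ms
(visual-pathway latency) after stimulus onset.  Only the cutoffs and the
latency are inherited conventions; filter family, order and phase behavior
are this package's explicit choices, fixed by the contracts the tests
assert (≥ 20 dB attenuation at 50 Hz and at 2 Hz, < 5 % passband error at
14 Hz, < 1 % amplitude change of a 10 Hz tone through resampling).
Sample indices round half-up: 0.135 s × 250 Hz = 33.75 → sample 34; windows
are 0-based and half-open.

## Synthetic data

The generator realizes the mixture model directly:

* **Evoked component** — $\sum_{k=1}^{K} d^{\,k-1}\sin(2\pi k f t + k\phi)$
  with $K = 3$ harmonics and decay $d = 0.5$ per order; harmonic $k$ rides
  at $k$ times the fundamental phase (phase-locked flicker).
* **Noise** — 1/f$^\alpha$ with $\alpha = 1$ (pink, EEG-like) by FFT
  spectral shaping of white Gaussian noise, unit variance, independent
  across channels, fully seedable.
* **Topography** — signal gains default to an occipital gradient
  (strongest at the Oz-like channel) over the 6-channel PO/O montage;
  noise gains are uniform.
* **SNR calibration** — the target SNR (dB) is the ratio of fundamental
  signal power ($r_{1,j}^2/2$, analytic) to noise power within ±1 Hz of
  the fundamental, averaged over channels.  The noise band power is taken
  from the *expected* spectrum of the shaping construction, not the
  realized periodogram: every trial of a given length then receives the
  same deterministic signal amplitude, and the realized SNR matches the
  target in expectation.  (Calibrating per trial against the realized local
  spectrum was rejected: amplitude jitter between test trials and templates
  grows with epoch length and erases the integration gain that makes longer
  epochs easier.)  The ±1 Hz band is widened to one spectral bin for epochs
  too short to resolve 2 Hz.
* **Datasets** — balanced, target-major order, with train and test noise
  drawn from disjoint seed-sequence children.

What the generator does *not* emulate: volume-conduction forward models,
ocular/motion artifacts, inter-subject variability, non-stationary
background rhythms.  Passing tests therefore demonstrate correctness of the
algorithms under the stated observation model, not expected accuracy on
recorded EEG; absolute accuracies from the motivating in-car study are
explicitly not reproduction targets, and only qualitative trends (accuracy
rising with SNR, duration, channels, training trials) are asserted.

Study-condition defaults are fixed once: 10/12/14 Hz targets, 250 Hz, 6
channels; trend tests use 50 trials/target, 0.5 s epochs for the SNR sweep
(−20/−10/0/+10 dB) and −10 dB for the duration sweep (0.2/0.5/1.0 s) —
a mid-range level at which accuracy is neither floored nor saturated.
The duration trend is statistical and tolerates one inversion.

## Evaluation

Leave-one-out cross-validation refits the model in every fold (each trial
held out once; requires ≥ 3 trials/target so folds retain the 2 trials the
pairwise objective needs).  The ITR uses the Wolpaw formula with
$T_0$ = flicker + rest; the worked operating points are consistent with the
rest being 0.5 s and the visual latency being excluded from $T_0$.  A
mathematical note: the formula is *nonnegative*, with its minimum of
exactly 0 bits at chance accuracy $P = 1/N_f$ — below-chance accuracies
yield small positive values that carry no usable information, so they are
flagged with a warning rather than clamped.  Display rounding is half-up to
2 decimals.

## Energy model

Longitudinal force balance
$F = mgf + \delta m\,\dot v + \tfrac{1}{2}\rho C_D A v^2$, discretized with
forward Euler at $\Delta t = 0.01$ s; mechanical energy accumulates as
$\sum \max(F, 0)\, v\, \Delta t / \eta$ — motoring only, since the
reference energy curves jump only at restarts, implying braking is not an
energy cost; no regeneration.  Driving modes follow
$a = a_\mathrm{ideal} + (1-\lambda)\, a_\mathrm{user}$ — the reading of the
mode law consistent with "λ = 1 pins acceleration to the recommendation"
and "smaller λ is more aggressive".

Scenario defaults: 5 km at 15 m/s cruise, full stops at 1000 m and 3000 m,
constant 3 m/s² braking (unstated in the source; exposed as a parameter),
no terminal braking, $g = 9.81$ m/s², $\eta = 1$ (the source's power
conversion to battery draw is unspecified, so absolute kJ totals are
declared non-reproducible and only orderings and trace shapes are
asserted).  Vehicle defaults: $m = 1500$ kg, $f = 0.015$, $\delta = 1.2$,
$\rho = 1.2258$ kg/m³, $C_D = 0.3$, $A = 2$ m².  During braking toward a
stop the integrator caps position at the intersection (the car cannot pass
the point it stops at), which keeps the recorded trace monotone despite
Euler overshoot; halving $\Delta t$ moves the total by < 0.05 %.

The misselection coupling samples the executed mode from the intended
mode's confusion row (or a scalar fixed accuracy expanded to a symmetric
confusion matrix) and replays the deterministic drive per draw, giving the
energy distribution induced by imperfect BCI mode selection.

## Known limitations

* The synthetic observation model is deliberately simple (see above); it
  can rank algorithms and verify contracts, not predict field accuracy.
* LOOCV refits $N_f \times N_t$ models; for the sizes used here that is
  milliseconds per fold, but no incremental-update path is provided.
* The energy integrator is first-order; the convergence test bounds the
  step-size error rather than eliminating it.
* EDF support is read-only and returns whole recordings; event/trigger
  parsing beyond an `onset_s` attribute is out of scope.
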