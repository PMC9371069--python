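# itdma — SSVEP detection by inter-trial distance minimization

`itdma` is a Python library for training-based detection of steady-state
visual-evoked potentials (SSVEPs), the periodic occipital EEG responses
elicited by flickering visual targets that drive many brain–computer
interfaces (BCIs).  The motivating application is hands-free driving-mode
selection: three dashboard targets flicker at 10, 12 and 14 Hz, the driver
gazes at one, and the detector decides which mode (sport / comfort /
economical) was intended.  The package bundles everything needed to study
such a system without recorded EEG:

* the distance-minimizing detector and a TRCA baseline,
* the standard preprocessing chain (resample to 250 Hz, 50 Hz notch,
  7–70 Hz band-pass, 135 ms visual-latency crop),
* a seedable synthetic SSVEP generator (harmonic stacks in pink noise,
  occipital gain topography, calibrated narrowband SNR),
* leave-one-out accuracy and information-transfer-rate (ITR) evaluation,
* a longitudinal vehicle-dynamics energy model that couples detection
  errors to the energy cost of driving in the wrong mode.

## The detector

For each target $i$ with training trials
$\Gamma_i^1,\dots,\Gamma_i^{N_t} \in \mathbb{R}^{N_c \times T}$
(channels × samples), a spatial filter $\omega_i \in \mathbb{R}^{N_c}$ is
chosen to make same-target trials maximally alike after spatial
combination:

$$\min_{\omega}\ \sum_{m_1 \ne m_2}
  \lVert \omega' \Gamma_i^{m_1} - \omega' \Gamma_i^{m_2} \rVert_2^2
  \quad \text{s.t.} \quad \omega' Q_i\, \omega = 1,$$

where $Q_i$ sums the per-trial channel covariances (unit power of the
combined training signal).  Writing the objective as $\omega' P_i\,\omega$
with $P_i = \sum_{m_1 \ne m_2} (\Gamma^{m_1}-\Gamma^{m_2})
(\Gamma^{m_1}-\Gamma^{m_2})'$, the solution is the generalized eigenvector
of $(P_i, Q_i)$ with the smallest eigenvalue.  The per-target filters are
stacked into an ensemble $E = [\omega_1,\dots,\omega_{N_f}]$ and a test
epoch $S$ is assigned by nearest filtered template,

$$\pi = \arg\min_i\ \lVert E'S - E'\bar{\Gamma}_i \rVert_F,
\qquad \bar{\Gamma}_i = \tfrac{1}{N_t}\sum_m \Gamma_i^m .$$

The decision metric is a distance, not a correlation — that is what
distinguishes the method from TRCA-style detectors, which are included for
comparison.

Evaluation uses the standard ITR of an $N_f$-choice synchronous interface
with accuracy $P$ and command time $T_0$:

$$\mathrm{ITR} = \frac{1}{T_0}\Big[\log_2 N_f + P\log_2 P +
  (1-P)\log_2\frac{1-P}{N_f-1}\Big] \ \text{bit/s}.$$

## Worked example

```sh
python examples/03_evaluate_loocv_itr.py
```

trains and cross-validates both detectors on a fixed-seed synthetic session
(3 targets, 6 channels, 20 trials/target, 0.5 s epochs, −5 dB narrowband
SNR) and prints:

```
itdma: accuracy 0.767 (46/60), ITR 0.57 bit/s
confusion (rows = true target):
[[17  1  2]
 [ 1 15  4]
 [ 4  2 14]]

trca: accuracy 0.767 (46/60), ITR 0.57 bit/s
...
```

Each of the 60 trials was held out once and classified by a model refit on
the rest; 46 correct decisions give 76.7 % accuracy, worth 0.57 bit/s at
one command per second (the 3-target ceiling is log₂3 ≈ 1.585 bit/s).  The
other example scripts cover simulation + classification
(`01_simulate_and_detect.py`), the preprocessing chain
(`02_preprocess_chain.py`, which prints the 50 Hz line power falling from
0.42 to 0.0005 while 10 Hz survives), and the driving-energy model
(`04_driving_energy.py`: the sport mode's 2095.5 kJ vs the economical
mode's 2094.3 kJ over the same 5 km stop-and-go route, and the effect of an
85 %-accurate mode selector).

A thin CLI mirrors the library (`itdma simulate|train|classify|evaluate|
energy|bench`, see `itdma --help`).

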