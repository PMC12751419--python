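# Methods

## The coupled ODE model

The generator is a five-state dynamical system. Two states `(x, y)` form a
limit-cycle oscillator: the radial term `alpha = 1 - sqrt(x^2 + y^2)`
attracts trajectories to the unit circle, and the angular velocity
`omega = 2*pi*f` sweeps the phase `theta = atan2(y, x)` through one cardiac
cycle per rotation. The third state is the ECG trace:

    dz/dt = -sum_i a_i * dtheta_i * exp(-dtheta_i^2 / (2 b_i^2)) - (z - z0)

where `dtheta_i = theta - theta_i` (wrapped into `(-pi, pi]`) and
`z0 = A sin(2*pi*f0*t)` is a small baseline wander (`A = 0.01`,
`f0 = 0.25`). Each cardiac wave is a Gaussian-shaped pull with amplitude
`a_i`, angular width `b_i` and reference angle `theta_i`; the regular-
sinus-rhythm preset uses the five canonical P/Q/R/S/T waves, the sinus-
arrhythmia preset seven, and the atrial-fibrillation preset eleven
(low-amplitude fibrillatory undulation replaces coherent P/T activity).

Two further states couple the ECG to an optical pulse: `dw/dt = z^2 - B2*w`
integrates the squared ECG (a rectified surrogate for ventricular
contraction) and `dv/dt = -B0*v + B1*w` low-passes it into the PPG trace
`v(t)`, with `B0 = 0.5`, `B1 = 0.5`, `B2 = 1.25` per ODE time unit. From
the initial state `u0 = [1/sqrt(2), 1/sqrt(2), 0.2, 0.005, 0]` the squared
forcing keeps `v >= 0` after a short transient.

### Time scaling and heart-rate variability

One output sample corresponds to `1 / (fbar * mean(RR))` ODE time units
(`fbar = 0.1`), so a cycle at the base frequency spans exactly the mean RR
in samples: with the mean RR equal to the sampling rate, the simulated
heart rate is 60 BPM. Given a per-cycle schedule of RR intervals in
samples, the rotation frequency of cycle `c` is
`f_c = fbar * mean(RR) / RR_c`, held constant within the cycle.

**Where the frequency switches.** The frequency is piecewise-constant and
updated at the upward `theta = 0` crossing — the R peak. This choice pins
every inter-peak gap to exactly one schedule entry (the sub-sample
switching error is below 0.1 sample), so a peak detector recovers the
driving schedule entry-for-entry; switching anywhere else makes each
detected interval a mixture of two adjacent entries and visibly distorts
the RR distribution on the 8 ms lattice that a 125 Hz sampling rate
imposes. The cost is a small morphological asymmetry within a beat (the
P side of a beat runs at the previous cycle's rate); in practice this is
within the range of natural beat-to-beat variation.

### Integration and reproducibility

Classical fixed-step 4th-order Runge–Kutta, one step per output sample.
A fixed step keeps the output bitwise reproducible for a given
(preset, schedule, sampling rate, seed, noise fraction) — an adaptive
integrator would trade that determinism for accuracy the application does
not need (halving the step changes the waveform by under 1e-4 RMS).

### Parameter noise

Morphological diversity is created by adding zero-mean white noise with
standard deviation equal to 10% of each parameter's magnitude, drawn once
per generated pair (not per cycle). Widths are floored at 5% of their
nominal value to keep the Gaussian pulls well defined, and if perturbed
reference angles lose their ordering the three vectors are re-sorted
jointly by angle — the wave set is unchanged, only its labeling. A
parameter whose nominal value is zero (notably the R-peak angle) receives
no noise, which keeps the R peak anchored at `theta = 0`.

## RR tools

The default R-peak detector is local-maximum search with a minimum
separation of 50 samples and a prominence floor of 0.3x the signal range.
The prominence floor is what keeps T waves of the presets from being
counted as R peaks; it is configurable, and any detector with the same
call signature can be plugged in. HRV is summarized as the mean and
*population* standard deviation of the RR intervals (the convention is not
observable from rounded summary tables; population STD was chosen and is
used consistently).

A note on PPG-derived schedules: the optical pulse is a smooth low-passed
response, so individual systolic peak times jitter by a few samples when
the RR interval varies. Schedules measured from PPG therefore match the
underlying RR sequence exactly for constant rhythms but only at the
distribution level (mean within ~2 samples, KS < 0.25) for variable ones.
ECG-derived round trips are exact.

## Preprocessing

4th-order Butterworth bandpass applied forward-backward (zero phase —
peak positions must not shift, or every RR metric downstream is biased):
0.4–45 Hz for ECG, 0.3–8 Hz for PPG. Resampling is polyphase with
anti-aliasing. The two channels are synchronized by truncating the
later-starting one so their first detected peaks coincide. Min-max scaling
to [-1, 1] is applied per record *before* windowing, so windows of one
record share a scale; a constant record maps to zeros with a warning.
Windows are 512 samples (~4.1 s at 125 Hz) with 50% overlap; an
incomplete tail window is dropped. Indices are 0-based, windows half-open.

## Metrics

RR-distribution metrics are computed on unit-width (1 ms) histograms over
integer edges spanning the union support of the two samples, so binning
cannot tilt a comparison:

- **rHI** = sum of per-bin minima / smaller total count, in [0, 1];
- **rRMSE** = RMSE between the sorted interval samples divided by the
  reference mean. The pairing of the two samples is not defined by the
  formula alone when counts differ; monotone (sorted/quantile) coupling
  was chosen, with B quantile-interpolated onto A's size;
- **rEMD** = L1 distance between cumulative counts (B rescaled to A's
  total), normalized by the maximum possible cost: A's total count times
  the largest inter-bin distance. Verified against a linear-programming
  optimal-transport oracle on all small histograms;
- **KL** divergence with natural log, both histograms normalized and
  smoothed additively (1e-9) so empty bins stay finite; asymmetric by
  construction, reported as KL(reference || other);
- **KS**: the exact two-sample sup-gap between empirical CDFs.

Waveform metrics: plain RMSE between equal-length signals; MAE_HR, the
mean absolute beat-wise heart-rate difference in BPM after truncating to
the common beat count; and the Fréchet distance between Gaussian fits
(mean, covariance) of per-window feature vectors,

    FD = ||mu_r - mu_g||^2 + Tr(S_r + S_g - 2 (S_r S_g)^{1/2}),

with the cross square root evaluated in its symmetrized PSD form via
eigendecomposition (negative eigenvalues clipped at zero). The feature
extractor is deliberately simple and deterministic — flattened
log-magnitude spectrogram frames by default, raw samples as an option —
and its identity is recorded with every report, since FD values are only
comparable under the same extractor.

## The reconstruction objective

Two encoder/decoder generators are trained jointly: `G_P` reconstructs
PPG from PPG, `G_E` reconstructs ECG from ECG, and the cross path decodes
the PPG latent with `G_E`'s decoder. The objective combines:

- **NT-Xent** contrastive loss (temperature `tau = 0.1`) between the two
  encoders' latent vectors for the same window; positives are
  index-aligned pairs, the denominator runs over all batch items including
  the positive. The printed form of the loss places the temperature
  outside the exponential; the standard NT-Xent form (temperature inside)
  is implemented, which is the formulation the loss's name refers to;
- three **smooth-L1** reconstruction losses (transition at 1, mean
  reduction): PPG->PPG, ECG->ECG, PPG->ECG;
- for the vector-quantized generator, the **dictionary** term
  `||sg[z_e] - e||^2` (gradient reaches only the codebook) and
  `lambda = 0.25` times the **commitment** term `||z_e - sg[e]||^2`
  (gradient reaches only the encoder), with a straight-through gradient
  copy from the quantized to the continuous latent on the reconstruction
  path — the routing is verified by finite differences in the tests;
- **adversarial** value functions `E[log D(real)] + E[log(1 - D(fake))]`
  for a 1-D patch discriminator on waveforms and a 2-D patch
  discriminator on magnitude spectrograms (Hann window 128, hop 32). The
  generator descends the saturating fake term; discriminator outputs are
  clamped to (0, 1) by an epsilon of 1e-7 before the logarithm.

The composite loss is `alpha*L_gen + beta*L_t + gamma*L_f` with
`alpha = 30, beta = 3, gamma = 1`. Setting `beta = gamma = 0` disables the
discriminators entirely (the ablation path). Only the PPG->ECG direction
has a contrastive term; no symmetric ECG->PPG term is added.

## Networks and training

No GPU tensor framework is assumed: the package carries its own compact
reverse-mode automatic-differentiation engine over numpy arrays
(`cardiosynth.autodiff`), with exactly the operator set the networks need
(broadcast arithmetic, matmul, im2col-based 1-D/2-D convolution, framing,
elementwise nonlinearities, reductions). All gradients are validated
against central finite differences in the test suite.

The default generator is a 1-D attention U-Net: two-conv blocks with
instance normalization and leaky ReLU, stride-2 downsampling,
nearest-neighbour upsampling, additive attention gates on the skip
connections (coefficients exportable for inspection) and a tanh output.
The alternative generator is a 1-D VQ-VAE (stride-2 encoder, nearest-code
quantization with ties to the lowest index, codebook 64 x 32 by default).
Because the cross-modal path decodes the PPG latent with the ECG decoder,
the attention U-Net's skip connections on that path come from `G_P`'s
encoder — the same wiring used at inference, where only `G_P`'s encoder
and `G_E`'s decoder run (instrumentation counters assert this).

Optimization is Adam (learning rate 2e-4, betas (0.5, 0.999) as GAN
practice; smoke configurations use 1e-3, optionally stepped down by x0.1
late in the run, which stabilizes the adversarial dynamics at small
scale), alternating one generator update and one discriminator update per
batch, batch size 32, window 512. Every
run is fully determined by the config seed: initialization, batch order,
and therefore the entire loss history and checkpoint.

**Scale.** Default desk-scale settings (depth 3–4, base 8–16 channels,
tens of epochs, tens of training pairs) are chosen so a full train/eval
cycle runs in minutes on one CPU core. These are deliberately far below
the scale of a GPU campaign; the synthetic task remains learnable because
the ECG–PPG relationship in the simulator is fixed and noise-free, which
is also why near-perfect synthetic results say little about real
recordings (see below).

## The demo corpus

`demo_pairs` / `make_demo_dataset` generate `n` pairs per rhythm with
per-record RR mean drawn uniformly from 600–1000 ms (75–100 BPM region)
and RR STD from 10–50 ms, schedules drawn i.i.d. normal per cycle
(clipped to 300–2000 ms), 10% waveform-parameter noise, at 125 Hz. These
ranges bracket typical adult resting heart rates and short-term HRV. What
the generator does *not* emulate: measurement noise and motion artifacts,
electrode/sensor transfer functions, ectopic beats, autocorrelated RR
dynamics (respiratory sinus arrhythmia appears only as inflated STD, not
as oscillation), or any demographic variability. Passing tests on this
corpus therefore demonstrate correctness of the pipeline and learnability
of a clean, fixed ECG–PPG relationship — not performance on clinical
recordings.

## Numerical choices and degenerate inputs

- Angle wrapping into `(-pi, pi]`; the boundary value maps to `+pi`.
- Constant signals: peak detection returns an empty result (not an
  error); min-max scaling maps to zeros with a warning.
- Single-bin rEMD grids: after renormalization both histograms coincide,
  so the distance is 0 by continuity.
- KL smoothing epsilon 1e-9, renormalized after smoothing.
- Matrix square roots: symmetric eigendecomposition with negative
  eigenvalues clipped at zero; FD clipped at 0 against rounding.
- Vector-quantization ties break to the lowest codebook index.
- Discriminator probabilities clamped by 1e-7 before logs.
- Resampling ratios are approximated by a rational with denominator
  <= 1000 for the polyphase filter.

## Known limitations

- The PPG model (two linear states driven by `z^2`) reproduces pulse
  timing and gross shape, not dicrotic-notch morphology or vascular
  effects; PPG-derived RR schedules carry a few samples of peak-time
  jitter.
- The sinus-arrhythmia preset's tall T-like waves are close enough in
  prominence to its R waves that distance-based peak detection
  occasionally mislabels them — the known failure mode that motivates the
  prominence floor; RR-level guarantees are therefore stated for the RSR
  and AFib presets.
- Training at desk scale with small numpy networks reaches reconstruction
  errors well above what a full-scale GPU campaign achieves on the same
  task; the harness is built for correctness and reproducibility first.
- WFDB reading requires the optional `wfdb` package; CSV and HDF5 are the
  first-class formats.
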