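# Methods

This note documents the models, estimators and numerical choices behind
`strfdev`, and what the synthetic-data generator does and does not emulate.

## The linear–nonlinear cell model

Each synthetic simple cell is a linear–nonlinear (LN) cascade. The linear
stage is a space-time kernel on the 1-D bar axis,

    K(x, t) = A · exp(−x²/2σ_x² − (t−t_c)²/2σ_t²)
                · cos(2π(sf·x + τ·(t−t_c)) + φ),

a Gabor in space (carrier at the stimulus spatial frequency, 0.08 cpd)
under a Gaussian temporal envelope. The tilt τ (cycles/ms) turns the
separable envelope into a drifting wave: τ = 0 gives a space-time-separable
kernel with exactly zero predicted direction selectivity, and the predicted
DSI grows monotonically with |τ|. Subthreshold membrane potential is the
discrete convolution of the kernel with the stimulus contrast plus the
resting potential and additive Gaussian background noise. The noise is
low-pass filtered to a ~30 ms correlation time, emulating slow synaptic
background rather than instrument noise; `simulate_vm` defaults to white
noise, and the cell presets opt in to the correlated form.

Kernel amplitude is calibrated per cell so that the linear response to the
preferred-direction grating at 4 Hz has the preset Vm amplitude (13.1 mV
naive, 17.3 mV experienced — the measured preferred-direction group means).
Preferred direction is derived from the kernel's Fourier transform at the
grating frequency, not assumed from the tilt sign.

### Spiking

The nonlinear stage is the rectified power law FR(V) = b·⌊V − V_th⌋₊^α
applied to baseline-subtracted voltage. Spikes are drawn per sample
(Bernoulli thinning of an inhomogeneous Poisson process) with an absolute
refractory period, with three deliberate properties:

- **Integration window.** The rate follows the membrane potential averaged
  over non-overlapping 30 ms blocks (the same partition the analysis bins
  use), not the instantaneous noisy sample. Without this, convexity of the
  power law (Jensen's inequality over within-bin fluctuations) smears the
  measured threshold and makes the transform unidentifiable from binned
  data at any finite recording length.
- **Dead-time compensation.** Thinning by an absolute refractory τ
  depresses the realized rate to λ/(1 + λτ); the generator draws at
  λ/(1 − λτ_eff) (τ_eff = τ − dt in discrete time) so the realized rate
  equals the transform exactly. Rates are verified to match within Poisson
  error across the operating range.
- **Ceiling.** The instantaneous rate saturates at 150 Hz, a physiological
  ceiling that the preset gains are chosen never to reach under the study
  stimuli, so the fitted power law is not distorted by saturation.

### Spike waveforms

Action potentials are injected as additive templates, piecewise linear in
time: a brief sub-kink foot (slope safely below the kink criterion), an
accelerating upstroke, a constant-slope tip spanning two samples — so the
discrete-difference max dV/dt equals the tip slope regardless of sampling
phase — a one-sample plateau at the peak, a linear fall through the
half-height point (setting the FWHM), and a steeper return. The template is
anchored in absolute voltage: its take-off equals the configured kink when
the underlying trace sits at (kink − foot), i.e. at a physiological
take-off approach voltage. Internal parameters are calibrated numerically
at construction until the *measured* kink, max dV/dt and FWHM match the
settings (typically < 0.1 mV / exact / < 0.02 ms at 10 kHz).

Spike-shape metrics require digitization at 8 kHz or better (the
recordings the analysis emulates were sampled at 8–11 kHz): a 250 mV/ms
upstroke on a ~1 ms-wide spike cannot be represented at 1 ms sampling, so
the template's measurable slope saturates at coarse rates and the
sampling-robustness test compares 8 kHz with 4 kHz rather than with 1 kHz.

### Group presets

| parameter | naive | experienced | basis |
|---|---|---|---|
| kernel tilt (cyc/ms) | 0.0003 ± 0.0001 | 0.0008 ± 0.0002 | chosen so predicted DSI ≈ 0.1–0.2 vs 0.4–0.6 |
| σ_t (ms) / t_center (ms) | 45 / 120 | 75 / 95 | elongation, shorter min latency with experience |
| Vm preferred amplitude (mV) | 13.1 | 17.3 | printed group means |
| max dV/dt (mV/ms) | 162.1 ± 51.1 | 264.4 ± 61.9 | printed slice means |
| spike kink (mV) | −25 ± 3.5 | −30.2 ± 3.7 | printed slice means |
| spike FWHM (ms) | 1.6 ± 0.7 | 1.0 ± 0.4 | printed in vivo means |
| V-F gain b (Hz/mV^α) | 0.12 ± 0.03 | 0.42 ± 0.06 | chosen: ~3.5× gain increase, rates in the tens of Hz |
| V-F threshold (mV above rest) | 6.0 ± 1.0 | 4.0 ± 0.8 | chosen: lowered threshold with experience |
| V-F exponent α | 1.8 ± 0.2 | 1.8 ± 0.2 | within the fit's [1, 4] constraint |

Gains were placed so that a ~10 mV suprathreshold depolarization produces
tens of spikes per second (matching the scale of the measured empirical
voltage-to-rate curves) while peak rates stay below the 150 Hz ceiling.
Draw distributions are normal with the listed SDs; max dV/dt is clipped to
[60, 360] mV/ms (the representable range of the template at 10 kHz), FWHM
to [0.5, 2.5] ms (spikes much wider than 2.5 ms cannot be removed by an
8 ms median filter, see below), and b away from zero.

What the generator does **not** emulate: 2-D receptive fields, conductance
or other biophysical dynamics, spike-rate adaptation or bursting,
eye-position or electrode artifacts, complex cells, and any correlation
between a cell's receptive-field and intrinsic parameters beyond the group
structure. Passing tests therefore show that the estimators recover the
truth of this LN world at realistic SNR and data volumes — not that real
recordings satisfy the LN assumptions.

## Estimators

**Spike removal.** An 8 ms running median with reflect padding. The
injected templates are ≤ ~4 ms wide, so isolated spikes vanish into the
median exactly; slow wide spikes (FWHM ≳ 2.5 ms, near the clip bound) and
refractory-limited doublets can leave residuals — real wide juvenile
spikes pose the same problem for this filter.

**Baseline.** 20th percentile (linear interpolation between order
statistics) of the 5 s pre-stimulus window, truncated to available data.

**Savitzky–Golay.** The 60 Hz smoothing step uses a 25 ms window (1.5 line
periods), polynomial order 3: this attenuates a 60 Hz component to 0.25 of
its amplitude while passing constants and ramps exactly. A one-period
(17 ms) window was rejected because it only attenuates 60 Hz to 0.75.

**Reverse correlation.** Per bar position, the Pearson correlation between
the zero-order-hold-upsampled contrast and the spike-removed Vm at lags
0–400 ms, computed by FFT with zero padding and normalized with the global
(whole-trace) standard deviations — accurate to O(lag/duration). Lags are
averaged into 10 ms bins, giving the STRF pixel grid (one bar × 10 ms per
pixel) on which the ≥ 20-pixel subunit rule is defined. No whitening is
applied; maps carry the 100 ms frame blur, and the estimator's target is
therefore the boxcar-blurred kernel, against which a 10-minute recording
achieves pixelwise correlation ≈ 0.99.

**Subunits and ellipses.** Thresholds at the 5%/95% quantiles of the whole
image (ON pixels additionally required positive, OFF negative, guarding
degenerate maps); 8-connected components; clusters under 20 pixels
discarded. Ellipses match the cluster's normalized second central moments
(via `skimage.measure.regionprops`, the standard counterpart of the MATLAB
`regionprops` workflow); a collinear cluster gets a one-pixel minor-axis
floor. Orientation is the magnitude of the angle between the major axis and
the space axis, in [0°, 90°]. Extents and latency bounds use the ellipse's
tangent extremes: half-extents √(a²cos²θ + b²sin²θ) on the space axis and
√(a²sin²θ + b²cos²θ) on the lag axis (verified against dense boundary
sampling to < 10⁻⁶ px). Minimum latency may be negative because of the
stimulus blur; no causality clipping is applied.

**Spectral DSI.** 2-D FFT amplitudes summed over sf ∈ (0, 0.2] cpd crossed
with tf ∈ (0, 10] Hz and tf ∈ [−10, 0) Hz; DC row/column excluded; the
larger sum is the preferred response. For separable kernels the two sums
are equal by conjugate symmetry and DSI_pr = 0 to machine precision.

**Direction tuning.** The double Gaussian R(θ) = R₀ + R_p·G(θ−θ_p) +
R_n·G(θ−θ_p−180°) uses a shared width and wrapped angular distance, fit by
multi-start least squares over the sampled directions. The fit only
locates θ_p; DSI uses the empirical responses at the sampled directions
nearest θ_p and its opposite, with negative values rectified at zero.

**V-F transform fit.** Count-weighted least squares on 1 mV binned mean
rates (the same summary the empirical curves use), restricted to bins
holding at least 15 pairs — the reliability rule the empirical curve
applies — because sparser bins carry Poisson-noisy means at high leverage
and destabilize the threshold; sparse recordings fall back to all populated
bins. V_th is non-smooth, so the fit multi-starts on a 1 mV grid over the
observed voltage range (ties resolved toward the lowest threshold) and then
refines the best grid point by bounded scalar minimization; for fixed
(V_th, α) the gain has a closed-form weighted solution, and α is bounded in
[1, 4]. At 200 s per cell the threshold and exponent recover with median
absolute errors ≈ 0.8 mV and 0.2; the raw gain b is only weakly identified
(it trades off exponentially against V_th and α — the error surface's
valley genuinely passes below the truth under finite Poisson noise), but
the *transform output* is: predicted rates at V_th + 5 and V_th + 10 mV
recover with ~4% median relative error, which is what downstream analyses
consume.

**Mixture model.** Waveform-donor and transform-donor draws are
independent with replacement, per cell slot. The preferred direction of a
simulated pairing is the waveform donor's Vm preferred direction (a
monotone transform cannot move it). Pairings whose predicted preferred
rate is zero are dropped from that simulation's mean rather than imputed.
All (donor, transform) pair responses are precomputed, so a 10,000 × 20
bootstrap is an indexing operation and bit-reproducible under a fixed
seed. The overestimation check compares the expected independent-pairing
preferred rate with the self-paired population mean; the ratio exceeds 1
when gain is anticorrelated with waveform amplitude (by the covariance
inequality), equals 1 for identical or independent cells.

## Problem sizes

Validation uses desk-scale versions of the study conditions: 10 minutes of
sparse noise for STRF consistency, 200 s per cell × 50 cells for transform
recovery, 30 cells spanning tilts for the spectral-prediction check, 16
cells per group × 2,000 bootstrap simulations of 20-cell experiments for
the mixture-model ordering, and spike metrics at 10 kHz sampling. The
pipeline's default configuration (8 cells per group, 2 minutes of noise) is
sized for interactive runs and is fully configurable.

## Known limitations

- In-vivo group statistics of the original recordings are not reproduced;
  the deposited raw data is out of the test path (a stub adapter documents
  the expected HDF5 schema).
- Naive-preset cells spike sparsely under noise stimulation (as real naive
  cells did); their individual V-F fits are correspondingly weak, and
  population-level transform validation uses the experienced preset.
- DSI values of power-law-transformed responses saturate near 1 more
  readily than measured spiking DSIs, because the synthetic model lacks
  the response floor (spontaneous activity) of real cells; the
  mixture-model analysis therefore targets condition *ordering*, not
  absolute DSI levels.
- The kink of pipeline-simulated spikes rides on the local membrane
  potential at spike time; absolute kink presets are recovered exactly only
  in controlled injections at the take-off approach voltage.
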