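"""Synthetic simple cells for testing the analysis pipeline end to end.

Generates 1-D visual stimuli (drifting sinusoidal gratings and sparse bar
noise), ground-truth space-time kernels with a controllable direction-
selective tilt, linear membrane-potential responses with additive Gaussian
noise, spiking through a rectified power-law voltage-to-firing-rate transform,
and injectable action-potential templates with controlled kink, max dV/dt and
width.  Two parameter presets emulate visually naive and visually experienced
simple cells: experienced cells have more strongly tilted, more eccentric
kernels with shorter minimum latencies, lower spike thresholds, higher
input-output gain, faster and narrower spikes.

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from . import intrinsic

__all__ = [
    "StimulusMovie",
    "KernelSTRF",
    "VmTrace",
    "SpikeTrain",
    "SpikeShape",
    "VFParams",
    "SyntheticCell",
    "make_grating_stimulus",
    "make_sparse_noise",
    "make_ground_truth_kernel",
    "simulate_vm",
    "simulate_spikes",
    "make_spike_template",
    "inject_spike_waveforms",
    "make_cell_population",
    "GROUP_PRESETS",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusMovie:
    """Space x time contrast matrix with physical axes.

    ``contrast`` has shape (n_positions, n_frames); values lie in [-1, 1]
    (sparse noise takes values in {-1, 0, +1}).
    """

    contrast: np.ndarray
    frame_ms: float
    bar_width_deg: float
    kind: str  # "grating" | "sparse_noise"
    orientation_deg: float = 0.0
    direction_deg: float | None = None
    tf_hz: float | None = None
    sf_cpd: float | None = None

    def __post_init__(self):
        if self.frame_ms <= 0:
            raise ValueError("frame_ms must be positive")

    @property
    def n_positions(self):
        return self.contrast.shape[0]

    @property
    def n_frames(self):
        return self.contrast.shape[1]

    @property
    def space_axis_deg(self):
        n = self.n_positions
        return (np.arange(n) - (n - 1) / 2.0) * self.bar_width_deg

    @property
    def duration_ms(self):
        return self.n_frames * self.frame_ms


@dataclass(frozen=True)
class KernelSTRF:
    """Ground-truth linear space-time kernel (mV per unit contrast per lag
    sample).  ``weights`` has shape (n_positions, n_lags); a zero ``tilt``
    makes the kernel space-time separable."""

    weights: np.ndarray
    space_axis_deg: np.ndarray
    lag_axis_ms: np.ndarray
    tilt_cyc_per_ms: float = 0.0
    sigma_x_deg: float = np.nan
    sigma_t_ms: float = np.nan
    t_center_ms: float = np.nan

    def __post_init__(self):
        if np.any(np.asarray(self.lag_axis_ms) < 0):
            raise ValueError("lag axis must be non-negative")

    @property
    def lag_dt_ms(self):
        return float(self.lag_axis_ms[1] - self.lag_axis_ms[0])


@dataclass(frozen=True)
class VmTrace:
    """Membrane potential trace in mV sampled at fixed dt."""

    samples: np.ndarray
    dt_ms: float
    t0_ms: float = 0.0

    def __post_init__(self):
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")

    @property
    def times_ms(self):
        return self.t0_ms + np.arange(len(self.samples)) * self.dt_ms

    @property
    def duration_ms(self):
        return len(self.samples) * self.dt_ms


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times in ms."""

    times_ms: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_ms, dtype=float)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")
        object.__setattr__(self, "times_ms", t)

    def __len__(self):
        return len(self.times_ms)


@dataclass(frozen=True)
class SpikeShape:
    """Target action-potential waveform parameters.

    ``kink_mV`` is the absolute take-off voltage, ``amplitude_mV`` the height
    of the peak above the kink, and ``foot_mV`` the depth of the brief
    sub-kink foot through which the template approaches take-off.
    """

    kink_mV: float
    max_dvdt_mV_per_ms: float
    fwhm_ms: float
    amplitude_mV: float = 90.0
    foot_mV: float = 4.0


@dataclass(frozen=True)
class VFParams:
    """Rectified power-law voltage-to-rate transform FR = b*max(V-Vth,0)^alpha.

    ``vth_mV`` is expressed relative to the cell's baseline (the transforms
    operate on baseline-subtracted voltage throughout).
    """

    b: float
    vth_mV: float
    alpha: float

    def clipped(self, lo=0.01):
        """Copy with gain floored away from zero (guards degenerate draws)."""
        return VFParams(b=max(self.b, lo), vth_mV=self.vth_mV, alpha=self.alpha)

    def rate(self, v):
        dv = np.maximum(np.asarray(v, dtype=float) - self.vth_mV, 0.0)
        return self.b * dv ** self.alpha


@dataclass(frozen=True)
class SyntheticCell:
    """Ground-truth description of one synthetic simple cell."""

    cell_id: str
    group: str  # "naive" | "experienced"
    kernel: KernelSTRF
    vf: VFParams
    spike_shape: SpikeShape
    noise_sd: float = 2.0
    noise_tau_ms: float = 30.0
    baseline_mV: float = -70.0
    refractory_ms: float = 5.0
    max_rate_hz: float = 150.0
    integration_ms: float = 30.0
    pref_direction_deg: float = 0.0
    seed: int = 0


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

def make_grating_stimulus(direction_deg, tf_hz=4.0, sf_cpd=0.08, duration_s=4.0,
                          n_positions=24, bar_width_deg=3.1, frame_ms=10.0):
    """Drifting sinusoidal grating sampled along the 1-D bar axis.

    The grating's spatial frequency projects onto the bar axis as
    sf*cos(direction), so contrast(x, t) = cos(2*pi*(sf*cos(theta)*x - tf*t));
    opposite directions differ only in the sign of the temporal term.
    """
    if duration_s <= 0 or n_positions <= 0:
        raise ValueError("duration_s and n_positions must be positive")
    n_frames = int(round(duration_s * 1000.0 / frame_ms))
    t_s = (np.arange(n_frames) * frame_ms) / 1000.0
    n = n_positions
    x_deg = (np.arange(n) - (n - 1) / 2.0) * bar_width_deg
    kx = sf_cpd * np.cos(np.deg2rad(direction_deg))
    phase = 2.0 * np.pi * (kx * x_deg[:, None] - tf_hz * t_s[None, :])
    return StimulusMovie(contrast=np.cos(phase), frame_ms=frame_ms,
                         bar_width_deg=bar_width_deg, kind="grating",
                         direction_deg=float(direction_deg), tf_hz=tf_hz,
                         sf_cpd=sf_cpd)


def make_sparse_noise(n_positions=24, duration_s=600.0, frame_ms=100.0,
                      p_black=0.1, p_white=0.1, bar_width_deg=3.1, seed=0):
    """Sparse 1-D bar noise: per position per frame i.i.d. black (-1), white
    (+1) or gray (0) with the given probabilities."""
    if not (0 <= p_black <= 1 and 0 <= p_white <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if p_black + p_white > 1:
        raise ValueError("p_black + p_white must not exceed 1")
    if duration_s <= 0 or n_positions <= 0:
        raise ValueError("duration_s and n_positions must be positive")
    n_frames = int(round(duration_s * 1000.0 / frame_ms))
    rng = np.random.default_rng(seed)
    contrast = rng.choice(np.array([-1.0, 0.0, 1.0]),
                          size=(n_positions, n_frames),
                          p=[p_black, 1.0 - p_black - p_white, p_white])
    return StimulusMovie(contrast=contrast, frame_ms=frame_ms,
                         bar_width_deg=bar_width_deg, kind="sparse_noise")


# ---------------------------------------------------------------------------
# ground-truth kernels
# ---------------------------------------------------------------------------

def make_ground_truth_kernel(sigma_x_deg, sigma_t_ms, sf_cpd=0.08,
                             tilt_cyc_per_ms=0.0, phase_rad=0.0,
                             t_center_ms=100.0, amplitude=1.0,
                             space_axis_deg=None, lag_axis_ms=None):
    """Gabor-in-space, Gaussian-in-time kernel with a space-time tilt.

    K(x, t) = A * exp(-x^2/2sx^2 - (t-tc)^2/2st^2)
                * cos(2*pi*(sf*x + tilt*(t-tc)) + phase)

    A nonzero tilt turns the separable envelope into a drifting wave, giving
    the kernel a directional slant in space-time; tilt = 0 yields a separable
    kernel with zero predicted direction selectivity.
    """
    if sigma_x_deg <= 0 or sigma_t_ms <= 0:
        raise ValueError("sigma_x_deg and sigma_t_ms must be positive")
    if space_axis_deg is None:
        space_axis_deg = (np.arange(24) - 11.5) * 3.1
    if lag_axis_ms is None:
        lag_axis_ms = np.arange(0.0, 400.0, 1.0)
    space_axis_deg = np.asarray(space_axis_deg, dtype=float)
    lag_axis_ms = np.asarray(lag_axis_ms, dtype=float)
    if np.any(lag_axis_ms < 0):
        raise ValueError("lag axis must be non-negative")
    x = space_axis_deg[:, None]
    t = lag_axis_ms[None, :] - t_center_ms
    envelope = np.exp(-x**2 / (2 * sigma_x_deg**2) - t**2 / (2 * sigma_t_ms**2))
    carrier = np.cos(2 * np.pi * (sf_cpd * x + tilt_cyc_per_ms * t) + phase_rad)
    return KernelSTRF(weights=amplitude * envelope * carrier,
                      space_axis_deg=space_axis_deg, lag_axis_ms=lag_axis_ms,
                      tilt_cyc_per_ms=tilt_cyc_per_ms,
                      sigma_x_deg=sigma_x_deg, sigma_t_ms=sigma_t_ms,
                      t_center_ms=t_center_ms)


# ---------------------------------------------------------------------------
# forward LN simulation
# ---------------------------------------------------------------------------

def upsample_stimulus(stimulus, dt_ms):
    """Zero-order-hold upsampling of the frame sequence to the Vm sampling
    grid.  frame_ms must be an integer multiple of dt_ms."""
    rep = stimulus.frame_ms / dt_ms
    if abs(rep - round(rep)) > 1e-9:
        raise ValueError("frame_ms must be an integer multiple of dt_ms")
    return np.repeat(stimulus.contrast, int(round(rep)), axis=1)


def _kernel_on_dt_grid(kernel, dt_ms):
    """Resample kernel lag axis onto the simulation grid, conserving the
    summed weight (weights are per lag sample)."""
    native_dt = kernel.lag_dt_ms
    if abs(native_dt - dt_ms) < 1e-9:
        return kernel.weights
    new_lags = np.arange(kernel.lag_axis_ms[0], kernel.lag_axis_ms[-1] + dt_ms / 2,
                         dt_ms)
    out = np.empty((kernel.weights.shape[0], len(new_lags)))
    for i, row in enumerate(kernel.weights):
        out[i] = np.interp(new_lags, kernel.lag_axis_ms, row)
    return out * (dt_ms / native_dt)


def simulate_vm(stimulus, kernel, noise_sd=0.0, baseline_mV=-70.0, dt_ms=1.0,
                seed=0, noise_tau_ms=0.0):
    """Linear Vm response: baseline + sum_x sum_tau K(x,tau)*c(x,t-tau) plus
    additive Gaussian noise.  Exactly linear in the stimulus at noise_sd=0.

    ``noise_tau_ms`` > 0 low-pass filters the noise to that correlation time
    (emulating slow synaptic background rather than instrument noise) while
    keeping its standard deviation at ``noise_sd``.
    """
    if kernel.weights.shape[0] != stimulus.n_positions:
        raise ValueError("kernel and stimulus position counts differ")
    c = upsample_stimulus(stimulus, dt_ms)
    k = _kernel_on_dt_grid(kernel, dt_ms)
    n_t = c.shape[1]
    # causal convolution per position, truncated to the trace length
    drive = signal.fftconvolve(c, k, mode="full", axes=1)[:, :n_t].sum(axis=0)
    vm = baseline_mV + drive
    if noise_sd > 0:
        noise = np.random.default_rng(seed).normal(0.0, 1.0, size=n_t)
        if noise_tau_ms > 0:
            from scipy.ndimage import gaussian_filter1d
            noise = gaussian_filter1d(noise, sigma=noise_tau_ms / dt_ms)
            sd = noise.std()
            if sd > 0:
                noise = noise / sd
        vm = vm + noise_sd * noise
    return VmTrace(samples=vm, dt_ms=dt_ms)


def simulate_spikes(vm_subthreshold, vf_params, refractory_ms=2.0, dt_ms=None,
                    seed=0, baseline_mV=0.0, max_rate_hz=None,
                    integration_ms=0.0):
    """Bernoulli-per-sample (inhomogeneous Poisson with absolute refractory)
    spiking from the rectified power-law rate.

    ``vm_subthreshold`` may be a VmTrace or an array (then dt_ms is required);
    the transform is applied to (Vm - baseline_mV).  ``max_rate_hz``
    saturates the instantaneous rate (the generative model's ceiling);
    without it a rate exceeding 1/dt is an error.  ``integration_ms`` > 0
    applies the transform to the running mean of Vm over that window,
    emulating the integration timescale of spike generation.
    """
    if isinstance(vm_subthreshold, VmTrace):
        v = vm_subthreshold.samples
        dt_ms = vm_subthreshold.dt_ms
        t0 = vm_subthreshold.t0_ms
    else:
        v = np.asarray(vm_subthreshold, dtype=float)
        if dt_ms is None:
            raise ValueError("dt_ms required for array input")
        t0 = 0.0
    if integration_ms > 0:
        # block averaging over non-overlapping windows anchored at the trace
        # start: the rate is piecewise constant at the integration timescale,
        # so the transform is exactly identifiable from windowed Vm/rate pairs
        size = max(1, int(round(integration_ms / dt_ms)))
        v = np.asarray(v, dtype=float)
        n_blocks = int(np.ceil(len(v) / size))
        pad = n_blocks * size - len(v)
        vb = np.concatenate([v, np.full(pad, v[-1])]) if pad else v
        block_means = vb.reshape(n_blocks, size).mean(axis=1)
        v = np.repeat(block_means, size)[: len(v)]
    rate_hz = vf_params.rate(v - baseline_mV)
    if max_rate_hz is not None:
        rate_hz = np.minimum(rate_hz, max_rate_hz)
    # dead-time compensation: a Poisson process thinned by an absolute
    # refractory tau realizes lambda/(1 + lambda*tau); drawing at
    # lambda/(1 - lambda*tau) makes the realized rate match the transform.
    # In discrete time the dead interval excludes the sample exactly at the
    # refractory boundary, so the effective dead time is tau - dt.
    tau_s = max(refractory_ms - dt_ms, 0.0) / 1000.0
    comp = 1.0 - rate_hz * tau_s
    if np.any(comp <= 0.05):
        raise ValueError("rate too close to the refractory limit; "
                         "lower max_rate_hz or refractory_ms")
    p = (rate_hz / comp) * dt_ms / 1000.0
    if np.any(p > 1.0):
        raise ValueError("rate*dt exceeds 1; decrease dt_ms")
    draws = np.random.default_rng(seed).random(len(p)) < p
    idx = np.nonzero(draws)[0]
    times = []
    last = -np.inf
    for i in idx:
        t = t0 + i * dt_ms
        if t - last >= refractory_ms:
            times.append(t)
            last = t
    return SpikeTrain(times_ms=np.asarray(times, dtype=float))


# ---------------------------------------------------------------------------
# spike templates
# ---------------------------------------------------------------------------

def _build_template(kink_mV, max_dvdt, fwhm_ms, amplitude_mV, foot_mV, dt_ms):
    """Sample one action-potential waveform in absolute mV on the dt grid.

    The waveform is piecewise linear in time: a slow foot from (kink - foot)
    to the kink at a slope safely below the kink criterion, an accelerating
    upstroke, a constant-slope tip segment spanning two full samples (so the
    discrete-difference max dV/dt equals the tip slope regardless of sample
    phase), a one-sample plateau at the peak, a linear fall through the
    half-height point (setting the FWHM), and a steeper return to the
    starting voltage.  Sampling is exact via interpolation of the segment
    breakpoints.
    """
    frac = intrinsic.KINK_FRACTION
    v_start = kink_mV - foot_mV
    v_peak = kink_mV + amplitude_mV

    # voltage budget: a constant-slope tip spanning two full samples (so the
    # discrete max dV/dt is phase-independent), capped by the available
    # amplitude; at coarse sampling (dt > 0.2 ms) the tip duration is capped
    # instead and the measurable slope saturates -- spike metrics are meant
    # to be taken at digitization rates of 8 kHz or more
    tip_dur = min(2.0 * dt_ms, 0.4)
    tip_mV = min(max_dvdt * tip_dur, 0.85 * amplitude_mV)
    tip_slope = tip_mV / tip_dur
    mid_mV = amplitude_mV - tip_mV
    s_foot = 0.7 * frac * max_dvdt
    s1 = 0.06 * max_dvdt  # just above the kink criterion
    q1 = min(mid_mV, 3.0)
    q2 = mid_mV - q1
    s2 = 0.5 * max_dvdt
    plateau = min(dt_ms, 0.2)

    t_pts = [0.0]
    v_pts = [v_start]

    def seg(dv, slope):
        t_pts.append(t_pts[-1] + dv / slope)
        v_pts.append(v_pts[-1] + dv)

    seg(foot_mV, s_foot)          # foot -> kink
    if q1 > 0:
        seg(q1, s1)               # slow start of the upstroke
    if q2 > 0:
        seg(q2, s2)               # mid upstroke
    seg(tip_mV, tip_slope)        # constant-slope tip -> peak
    t_pts.append(t_pts[-1] + plateau)  # plateau so a sample lands at the peak
    v_pts.append(v_peak)
    t_peak = t_pts[-1]

    # rise-side half-height time (within the piecewise-linear upstroke)
    v_half = 0.5 * (kink_mV + v_peak)
    t_half_rise = float(np.interp(v_half, v_pts, t_pts))
    rise_half_width = t_peak - plateau - t_half_rise
    fall_to_half = fwhm_ms - rise_half_width - plateau
    if fall_to_half <= 0:
        fall_to_half = 0.25 * fwhm_ms
    m_fall = (v_peak - v_half) / fall_to_half
    seg(-(v_peak - v_half), -m_fall)  # fall through half height
    m2 = max(6.0 * m_fall, 60.0)
    seg(-(v_half - v_start), -m2)     # steeper return to the start

    t_samp = np.arange(0.0, t_pts[-1] + dt_ms, dt_ms)
    return np.interp(t_samp, t_pts, v_pts)


def make_spike_template(spike_shape, dt_ms, max_iter=12):
    """Absolute-voltage spike waveform whose *measured* kink, max dV/dt and
    FWHM (via :mod:`strfdev.intrinsic`) match ``spike_shape``.

    The template is calibrated numerically: internal shape parameters are
    iterated until the discrete-sampled waveform reproduces the targets.
    """
    kink_t = spike_shape.kink_mV
    dvdt_t = spike_shape.max_dvdt_mV_per_ms
    fwhm_t = spike_shape.fwhm_ms
    kink_i, dvdt_i, fwhm_i = kink_t, dvdt_t, fwhm_t
    if dt_ms > 0.2:
        # coarse sampling cannot resolve the metrics; return the nominal shape
        return _build_template(kink_i, dvdt_i, fwhm_i,
                               spike_shape.amplitude_mV, spike_shape.foot_mV,
                               dt_ms)
    tpl = None
    for _ in range(max_iter):
        tpl = _build_template(kink_i, dvdt_i, fwhm_i,
                              spike_shape.amplitude_mV, spike_shape.foot_mV,
                              dt_ms)
        m_dvdt = intrinsic.max_dvdt(tpl, dt_ms)
        m_kink = intrinsic.spike_kink(tpl, dt_ms)
        m_fwhm = intrinsic.spike_fwhm(tpl, dt_ms)
        if (abs(m_kink - kink_t) < 0.1 and abs(m_dvdt - dvdt_t) / dvdt_t < 0.01
                and abs(m_fwhm - fwhm_t) < 0.01):
            break
        kink_i += 0.8 * (kink_t - m_kink)
        dvdt_i *= (dvdt_t / m_dvdt) ** 0.8
        fwhm_i = max(0.2, fwhm_i + 0.8 * (fwhm_t - m_fwhm))
    return tpl


def inject_spike_waveforms(vm, spikes, spike_shape, dt_ms=None):
    """Add action-potential waveforms to a subthreshold trace.

    The template is anchored in absolute voltage (its take-off equals the
    configured kink when the underlying trace sits at kink - foot); the
    injected bump is template minus its own starting value, added starting at
    each spike time, so non-overlapping injections sum and an empty train
    leaves the trace unchanged.
    """
    if isinstance(vm, VmTrace):
        samples = vm.samples.copy()
        dt_ms = vm.dt_ms
        t0 = vm.t0_ms
    else:
        samples = np.array(vm, dtype=float)
        if dt_ms is None:
            raise ValueError("dt_ms required for array input")
        t0 = 0.0
    times = spikes.times_ms if isinstance(spikes, SpikeTrain) else np.asarray(spikes)
    if len(times) == 0:
        return VmTrace(samples=samples, dt_ms=dt_ms, t0_ms=t0)
    tpl = make_spike_template(spike_shape, dt_ms)
    bump = tpl - tpl[0]
    n = len(samples)
    for t in times:
        i = int(round((t - t0) / dt_ms))
        if i < 0 or i >= n:
            raise ValueError("spike time outside trace span")
        j = min(n, i + len(bump))
        samples[i:j] += bump[: j - i]
    return VmTrace(samples=samples, dt_ms=dt_ms, t0_ms=t0)


# ---------------------------------------------------------------------------
# population presets
# ---------------------------------------------------------------------------

#: Group presets.  Spike-shape means/SDs follow the printed intrinsic
#: measurements in synaptically isolated cells (max dV/dt 162.1+-51.1 vs
#: 264.4+-61.9 mV/ms; kink -25+-3.5 vs -30.2+-3.7 mV) and the in vivo spike
#: widths (1.6+-0.7 vs 1.0+-0.4 ms).  Kernel tilt/envelope are chosen so that
#: naive kernels predict DSI ~0.1-0.2 and experienced kernels ~0.4-0.6, and
#: V-F parameters so that experienced transforms have lower thresholds and
#: higher gain.
GROUP_PRESETS = {
    "naive": dict(
        tilt_mean=0.0003, tilt_sd=0.0001,
        sigma_x_deg=6.0, sigma_t_ms=45.0, t_center_ms=120.0,
        vm_pref_amp_mV=13.1,
        vf_b=0.12, vf_b_sd=0.03, vf_vth=6.0, vf_vth_sd=1.0,
        vf_alpha=1.8, vf_alpha_sd=0.2,
        max_dvdt=162.1, max_dvdt_sd=51.1,
        kink=-25.0, kink_sd=3.5,
        fwhm=1.6, fwhm_sd=0.7,
    ),
    "experienced": dict(
        tilt_mean=0.0008, tilt_sd=0.0002,
        sigma_x_deg=5.0, sigma_t_ms=75.0, t_center_ms=95.0,
        vm_pref_amp_mV=17.3,
        vf_b=0.42, vf_b_sd=0.06, vf_vth=4.0, vf_vth_sd=0.8,
        vf_alpha=1.8, vf_alpha_sd=0.2,
        max_dvdt=264.4, max_dvdt_sd=61.9,
        kink=-30.2, kink_sd=3.7,
        fwhm=1.0, fwhm_sd=0.4,
    ),
}


def _kernel_pref_response_amplitude(kernel, tf_hz=4.0, sf_cpd=0.08):
    """Amplitude of the linear Vm response to the kernel's preferred-direction
    grating at unit contrast: |sum_{x,tau} K e^{-i 2 pi (sf x - s tf tau)}|,
    maximized over drift sign."""
    x = kernel.space_axis_deg[:, None]
    t = kernel.lag_axis_ms[None, :] / 1000.0
    # for direction 0 the stimulus is cos(2*pi*(sf*x - tf*t)); the linear
    # response amplitude is |sum K(x,tau) e^{i 2 pi (sf x + tf tau)}|
    amps = []
    for s in (+1.0, -1.0):
        basis = np.exp(2j * np.pi * (sf_cpd * x + s * tf_hz * t))
        amps.append(abs(np.sum(kernel.weights * basis)))
    pref_direction = 0.0 if amps[0] >= amps[1] else 180.0
    return max(amps), pref_direction


def make_synthetic_cell(group, seed, cell_id=None, n_positions=24,
                        bar_width_deg=3.1, lag_dt_ms=1.0, max_lag_ms=400.0):
    """Draw one synthetic cell from the given group's preset distributions."""
    if group not in GROUP_PRESETS:
        raise ValueError(f"unknown group {group!r}")
    p = GROUP_PRESETS[group]
    rng = np.random.default_rng(seed)
    sign = rng.choice([-1.0, 1.0])
    tilt = sign * abs(rng.normal(p["tilt_mean"], p["tilt_sd"]))
    sigma_x = p["sigma_x_deg"] * rng.uniform(0.85, 1.15)
    sigma_t = p["sigma_t_ms"] * rng.uniform(0.85, 1.15)
    t_center = p["t_center_ms"] + rng.uniform(-10.0, 10.0)
    space_axis = (np.arange(n_positions) - (n_positions - 1) / 2.0) * bar_width_deg
    lag_axis = np.arange(0.0, max_lag_ms, lag_dt_ms)
    kernel = make_ground_truth_kernel(
        sigma_x, sigma_t, sf_cpd=0.08, tilt_cyc_per_ms=tilt,
        phase_rad=rng.uniform(0, 2 * np.pi), t_center_ms=t_center,
        amplitude=1.0, space_axis_deg=space_axis, lag_axis_ms=lag_axis)
    # scale the kernel so the preferred-direction grating response has the
    # preset Vm amplitude
    raw_amp, pref = _kernel_pref_response_amplitude(kernel)
    scale = p["vm_pref_amp_mV"] / raw_amp
    kernel = replace(kernel, weights=kernel.weights * scale)
    vf = VFParams(
        b=float(np.clip(rng.normal(p["vf_b"], p["vf_b_sd"]),
                        0.3 * p["vf_b"], p["vf_b"] + 2 * p["vf_b_sd"])),
        vth_mV=rng.normal(p["vf_vth"], p["vf_vth_sd"]),
        alpha=float(np.clip(rng.normal(p["vf_alpha"], p["vf_alpha_sd"]), 1.0, 4.0)),
    )
    shape = SpikeShape(
        kink_mV=rng.normal(p["kink"], p["kink_sd"]),
        max_dvdt_mV_per_ms=float(np.clip(
            rng.normal(p["max_dvdt"], p["max_dvdt_sd"]), 60.0, 360.0)),
        fwhm_ms=float(np.clip(rng.normal(p["fwhm"], p["fwhm_sd"]), 0.5, 2.5)),
    )
    return SyntheticCell(
        cell_id=cell_id or f"{group[0]}{seed}",
        group=group, kernel=kernel, vf=vf, spike_shape=shape,
        pref_direction_deg=pref, seed=int(seed))


def make_cell_population(group, n_cells, seed=0, **kwargs):
    """Deterministic list of synthetic cells for one experience group."""
    if group not in GROUP_PRESETS:
        raise ValueError(f"unknown group {group!r}")
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=int(n_cells))
    return [make_synthetic_cell(group, int(s), cell_id=f"{group[0]}{i:03d}",
                                **kwargs)
            for i, s in enumerate(seeds)]
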