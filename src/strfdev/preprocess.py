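"""Vm trace preprocessing: spike detection and removal, smoothing, baseline.

Order of operations for downstream analyses: detect spikes, remove them with
an 8 ms running median, optionally apply a 60 Hz Savitzky-Golay smoother, and
subtract a baseline defined as the 20th percentile of the pre-stimulus window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .synthetic import SpikeTrain, VmTrace

__all__ = [
    "PreprocessedTrace",
    "detect_spikes",
    "remove_spikes_median",
    "smooth_60hz",
    "estimate_baseline",
    "preprocess_trace",
]

#: default dV/dt criterion for automatic spike detection (mV/ms)
DVDT_THRESHOLD = 20.0
#: spikes closer than this are merged into one detection (ms)
MERGE_WINDOW_MS = 2.0


@dataclass(frozen=True)
class PreprocessedTrace:
    vm_filtered: VmTrace
    spikes: SpikeTrain
    baseline_mV: float
    baseline_window_s: float


def _as_trace(vm, dt_ms):
    if isinstance(vm, VmTrace):
        return vm
    if dt_ms is None:
        raise ValueError("dt_ms required for array input")
    return VmTrace(samples=np.asarray(vm, dtype=float), dt_ms=dt_ms)


def detect_spikes(vm, mode="dvdt", threshold_mV=-20.0,
                  dvdt_threshold=DVDT_THRESHOLD, dt_ms=None):
    """Detect spikes by upward threshold crossings.

    mode="dvdt": criterion is a forward-difference rate of rise at or above
    ``dvdt_threshold`` (mV/ms).  mode="voltage": a fixed voltage threshold.
    One spike is reported per suprathreshold excursion (time of the upward
    crossing); crossings within ``MERGE_WINDOW_MS`` are merged.
    """
    trace = _as_trace(vm, dt_ms)
    v = trace.samples
    if mode == "dvdt":
        crit = np.diff(v) / trace.dt_ms >= dvdt_threshold
        crit = np.append(crit, False)
    elif mode == "voltage":
        crit = v >= threshold_mV
    else:
        raise ValueError(f"unknown mode {mode!r}")
    onsets = np.nonzero(~crit[:-1] & crit[1:])[0] + 1
    if crit.size and crit[0]:
        onsets = np.insert(onsets, 0, 0)
    times = trace.t0_ms + onsets * trace.dt_ms
    kept = []
    last = -np.inf
    for t in times:
        if t - last > MERGE_WINDOW_MS:
            kept.append(t)
            last = t
    return SpikeTrain(times_ms=np.asarray(kept, dtype=float))


def remove_spikes_median(vm, window_ms=8.0, dt_ms=None):
    """Remove action potentials with a running median (reflect padding).

    The window is converted to an odd sample count; windows shorter than
    3 samples are rejected.
    """
    trace = _as_trace(vm, dt_ms)
    n_win = int(round(window_ms / trace.dt_ms))
    if n_win % 2 == 0:
        n_win += 1
    if n_win < 3:
        raise ValueError("median window must span at least 3 samples")
    filtered = ndimage.median_filter(trace.samples, size=n_win, mode="reflect")
    return VmTrace(samples=filtered, dt_ms=trace.dt_ms, t0_ms=trace.t0_ms)


def smooth_60hz(vm, window_ms=25.0, polyorder=3, dt_ms=None):
    """Savitzky-Golay smoothing sized to suppress 60 Hz line noise.

    The default 25 ms window (1.5 line-noise periods) attenuates a 60 Hz
    component to under a third of its amplitude while polynomial least
    squares preserves the DC component (and any polynomial up to
    ``polyorder``) exactly.
    """
    trace = _as_trace(vm, dt_ms)
    n_win = int(round(window_ms / trace.dt_ms))
    if n_win % 2 == 0:
        n_win += 1
    if polyorder >= n_win:
        raise ValueError("polyorder must be smaller than the window length")
    smoothed = signal.savgol_filter(trace.samples, n_win, polyorder)
    return VmTrace(samples=smoothed, dt_ms=trace.dt_ms, t0_ms=trace.t0_ms)


def estimate_baseline(vm, stim_onset_ms=None, prestim_window_s=5.0,
                      percentile=20.0, dt_ms=None):
    """Baseline voltage: the given percentile (default 20th) of the samples in
    the pre-stimulus window, truncated to the available data.

    ``stim_onset_ms`` defaults to the end of the trace (i.e. the whole trace
    is treated as pre-stimulus).
    """
    trace = _as_trace(vm, dt_ms)
    v = trace.samples
    if stim_onset_ms is None:
        i_end = len(v)
    else:
        i_end = int(round((stim_onset_ms - trace.t0_ms) / trace.dt_ms))
    i_start = max(0, i_end - int(round(prestim_window_s * 1000.0 / trace.dt_ms)))
    window = v[i_start:i_end]
    if window.size == 0:
        raise ValueError("empty pre-stimulus window")
    return float(np.percentile(window, percentile))


def preprocess_trace(vm, spike_mode="dvdt", window_ms=8.0, smooth=False,
                     stim_onset_ms=None, prestim_window_s=5.0, **detect_kwargs):
    """Standard preprocessing chain returning spikes, the spike-removed trace
    and the pre-stimulus baseline."""
    trace = _as_trace(vm, None) if isinstance(vm, VmTrace) else vm
    spikes = detect_spikes(trace, mode=spike_mode, **detect_kwargs)
    filtered = remove_spikes_median(trace, window_ms=window_ms)
    if smooth:
        filtered = smooth_60hz(filtered)
    baseline = estimate_baseline(filtered, stim_onset_ms=stim_onset_ms,
                                 prestim_window_s=prestim_window_s)
    return PreprocessedTrace(vm_filtered=filtered, spikes=spikes,
                             baseline_mV=baseline,
                             baseline_window_s=prestim_window_s)
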