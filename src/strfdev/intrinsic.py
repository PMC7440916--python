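"""Spike-waveform excitability metrics and F-I curve slopes.

Metrics follow the phase-plane tradition: the rate of rise dV/dt is computed
from successive-sample differences, the spike *kink* (a threshold estimate) is
the voltage at which dV/dt first exceeds a fixed fraction (default 0.033) of
its maximum, and spike width is the full width at half maximum measured from
the kink voltage to the peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SpikeShapeMetrics",
    "FICurve",
    "extract_spike_waveforms",
    "max_dvdt",
    "spike_kink",
    "spike_fwhm",
    "spike_shape_metrics",
    "fi_slope",
]

#: kink search is restricted to this window preceding the spike peak (ms)
KINK_SEARCH_WINDOW_MS = 5.0
#: fraction of max dV/dt defining the kink voltage
KINK_FRACTION = 0.033


@dataclass(frozen=True)
class SpikeShapeMetrics:
    """Per-cell spike-shape summary."""

    max_dvdt: float  # mV/ms
    kink_mV: float
    fwhm_ms: float
    n_spikes: int


@dataclass(frozen=True)
class FICurve:
    """Firing rate vs injected current, with fitted linear slope."""

    currents_pA: np.ndarray
    rates_hz: np.ndarray
    slope_hz_per_pA: float


def extract_spike_waveforms(vm, spikes_ms, dt_ms, pre_ms=5.0, post_ms=5.0, t0_ms=0.0):
    """Cut peak-aligned spike waveforms out of a Vm trace.

    For each spike time, the local maximum within +-2 ms is used as the
    alignment point.  Spikes whose window overlaps the trace edge are dropped.

    Returns
    -------
    waveforms : ndarray, shape (n_spikes, n_samples)
    mean_waveform : ndarray or None
    """
    vm = np.asarray(vm, dtype=float)
    n_pre = int(round(pre_ms / dt_ms))
    n_post = int(round(post_ms / dt_ms))
    half_search = max(1, int(round(2.0 / dt_ms)))
    rows = []
    for t in np.atleast_1d(np.asarray(spikes_ms, dtype=float)):
        i = int(round((t - t0_ms) / dt_ms))
        lo = max(0, i - half_search)
        hi = min(len(vm), i + half_search + 1)
        if hi <= lo:
            continue
        ipk = lo + int(np.argmax(vm[lo:hi]))
        if ipk - n_pre < 0 or ipk + n_post + 1 > len(vm):
            continue  # window overlaps trace edge; drop with no fuss
        rows.append(vm[ipk - n_pre : ipk + n_post + 1])
    if not rows:
        return np.empty((0, n_pre + n_post + 1)), None
    waveforms = np.vstack(rows)
    return waveforms, waveforms.mean(axis=0)


def _dvdt(waveform, dt_ms):
    return np.diff(np.asarray(waveform, dtype=float)) / dt_ms


def max_dvdt(waveform, dt_ms):
    """Maximum rate of rise (mV/ms) over the rising phase, by successive-sample
    differences."""
    w = np.asarray(waveform, dtype=float)
    if w.size < 2:
        raise ValueError("waveform must contain at least 2 samples")
    ipk = int(np.argmax(w))
    d = _dvdt(w, dt_ms)
    rise = d[:ipk] if ipk >= 1 else d
    return float(np.max(rise))


def spike_kink(waveform, dt_ms, frac=KINK_FRACTION):
    """Voltage at which dV/dt first exceeds ``frac`` of its maximum.

    The search is bounded to the ``KINK_SEARCH_WINDOW_MS`` preceding the peak;
    within that window the first sample whose forward difference reaches the
    criterion defines the kink voltage.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size < 3:
        raise ValueError("waveform too short for kink analysis")
    ipk = int(np.argmax(w))
    if ipk < 1:
        raise ValueError("waveform has no rising phase")
    start = max(0, ipk - int(round(KINK_SEARCH_WINDOW_MS / dt_ms)))
    d = _dvdt(w, dt_ms)[start:ipk]
    if d.size == 0 or np.max(d) <= 0:
        raise ValueError("no positive rate of rise before the peak")
    thresh = frac * np.max(d)
    idx = np.nonzero(d >= thresh)[0]
    return float(w[start + idx[0]])


def spike_fwhm(waveform, dt_ms, frac=KINK_FRACTION):
    """Full width at half maximum (ms), half height measured from the kink
    voltage to the peak, crossings located by linear interpolation."""
    w = np.asarray(waveform, dtype=float)
    ipk = int(np.argmax(w))
    v_kink = spike_kink(w, dt_ms, frac=frac)
    v_half = 0.5 * (v_kink + w[ipk])

    # rising crossing: last upward crossing of v_half before the peak
    above = w[: ipk + 1] >= v_half
    idx_up = np.nonzero(~above[:-1] & above[1:])[0]
    if idx_up.size == 0:
        raise ValueError("waveform does not cross half height on the rise")
    i = idx_up[-1]
    t_up = (i + (v_half - w[i]) / (w[i + 1] - w[i])) * dt_ms

    # falling crossing: first downward crossing of v_half after the peak
    post = w[ipk:]
    below = post < v_half
    idx_dn = np.nonzero(~below[:-1] & below[1:])[0]
    if idx_dn.size == 0:
        raise ValueError("waveform does not cross half height on the fall")
    j = ipk + idx_dn[0]
    t_dn = (j + (v_half - w[j]) / (w[j + 1] - w[j])) * dt_ms
    return float(t_dn - t_up)


def spike_shape_metrics(waveform, dt_ms, n_spikes=1):
    """All three spike-shape metrics on one (typically mean) waveform."""
    return SpikeShapeMetrics(
        max_dvdt=max_dvdt(waveform, dt_ms),
        kink_mV=spike_kink(waveform, dt_ms),
        fwhm_ms=spike_fwhm(waveform, dt_ms),
        n_spikes=int(n_spikes),
    )


def fi_slope(currents_pA, rates_hz):
    """OLS slope (Hz/pA) of firing rate vs injected current over the
    suprathreshold (nonzero-rate) range.  All-zero rates give slope 0."""
    c = np.asarray(currents_pA, dtype=float)
    r = np.asarray(rates_hz, dtype=float)
    if c.size < 3:
        raise ValueError("need at least 3 current levels")
    if np.all(r == 0):
        return FICurve(c, r, 0.0)
    nz = np.nonzero(r > 0)[0]
    lo = nz[0]
    cc, rr = c[lo:], r[lo:]
    if cc.size < 2 or np.ptp(cc) == 0:
        return FICurve(c, r, 0.0)
    res = stats.linregress(cc, rr)
    return FICurve(c, r, float(res.slope))
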