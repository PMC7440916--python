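"""Grating-response analysis: F0/F1, cell class, tuning fits, DSI, latency.

Responses to drifting gratings are decomposed into the mean (F0) and the
amplitude at the stimulus temporal frequency (F1).  A spiking cell is simple
when its spike modulation ratio F1/F0 is at least 1; a non-spiking cell is
simple when its Vm modulation ratio exceeds 0.5.  Direction tuning curves are
fit with a double Gaussian (shared width, peaks 180 degrees apart) used to
locate the preferred direction; the direction selectivity index is
(Rp - Rn)/Rp with Rn rectified at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .synthetic import VmTrace

__all__ = [
    "CycleResponse",
    "DoubleGaussianFit",
    "DSIResult",
    "cycle_fourier",
    "classify_simple_complex",
    "wrapped_angle_diff",
    "fit_double_gaussian",
    "dsi",
    "dsi_from_curve",
    "responsiveness_anova",
    "response_latency",
]


@dataclass(frozen=True)
class CycleResponse:
    F0: float
    F1: float
    tf_hz: float


@dataclass(frozen=True)
class DoubleGaussianFit:
    R0: float
    theta_pref_deg: float
    sigma_deg: float
    Rp_fit: float
    Rn_fit: float
    converged: bool = True

    def predict(self, theta_deg):
        theta_deg = np.asarray(theta_deg, dtype=float)
        d1 = wrapped_angle_diff(theta_deg, self.theta_pref_deg)
        d2 = wrapped_angle_diff(theta_deg, self.theta_pref_deg + 180.0)
        return (self.R0
                + self.Rp_fit * np.exp(-d1**2 / (2 * self.sigma_deg**2))
                + self.Rn_fit * np.exp(-d2**2 / (2 * self.sigma_deg**2)))


@dataclass(frozen=True)
class DSIResult:
    dsi: float
    Rp: float
    Rn: float
    component: str = "F0+F1"
    signal: str = "vm"
    theta_pref_deg: float = np.nan


def cycle_fourier(values, tf_hz, dt_ms=None, baseline=0.0):
    """F0 (mean) and F1 (amplitude at the stimulus temporal frequency) of a
    response trace, truncated to an integer number of stimulus cycles.

    ``values`` may be a VmTrace or an array with ``dt_ms``.  ``baseline`` is
    subtracted before the decomposition (use the pre-stimulus baseline for Vm,
    0 for firing rates).
    """
    if isinstance(values, VmTrace):
        x = values.samples.astype(float)
        dt_ms = values.dt_ms
    else:
        x = np.asarray(values, dtype=float)
        if dt_ms is None:
            raise ValueError("dt_ms required for array input")
    x = x - baseline
    samples_per_cycle = 1000.0 / (tf_hz * dt_ms)
    n_cycles = int(np.floor(len(x) / samples_per_cycle))
    if n_cycles < 1:
        raise ValueError("window shorter than one stimulus cycle")
    n = int(round(n_cycles * samples_per_cycle))
    x = x[:n]
    spectrum = np.fft.rfft(x)
    f0 = float(np.mean(x))
    # the stimulus frequency falls on DFT bin n_cycles by construction
    f1 = float(2.0 * np.abs(spectrum[n_cycles]) / n)
    return CycleResponse(F0=f0, F1=f1, tf_hz=tf_hz)


def classify_simple_complex(spike_mod_ratio=None, vm_mod_ratio=None,
                            has_spikes=True):
    """Simple/complex classification from modulation ratios (F1/F0).

    Spiking cells are simple when the spike modulation ratio is >= 1.0;
    non-spiking cells are simple when the Vm modulation ratio is > 0.5.
    """
    if has_spikes:
        if spike_mod_ratio is None:
            raise ValueError("spike_mod_ratio required for spiking cells")
        return "simple" if spike_mod_ratio >= 1.0 else "complex"
    if vm_mod_ratio is None:
        raise ValueError("vm_mod_ratio required for non-spiking cells")
    return "simple" if vm_mod_ratio > 0.5 else "complex"


def modulation_ratio(resp: CycleResponse):
    if resp.F0 == 0:
        raise ZeroDivisionError("modulation ratio undefined for F0 = 0")
    return resp.F1 / resp.F0


def wrapped_angle_diff(a_deg, b_deg):
    """Smallest absolute angular difference in degrees (0..180)."""
    d = np.abs(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 360.0
    return np.where(d > 180.0, 360.0 - d, d)


def fit_double_gaussian(directions_deg, responses):
    """Least-squares double-Gaussian fit of a direction tuning curve.

    R(theta) = R0 + Rp*exp(-d(theta,thetap)^2/2s^2)
                  + Rn*exp(-d(theta,thetap+180)^2/2s^2)

    with d the wrapped angular difference and a shared width.  Multi-start
    over the sampled directions for thetap; on non-convergence a flagged fit
    anchored at the empirical peak is returned.
    """
    th = np.asarray(directions_deg, dtype=float)
    r = np.asarray(responses, dtype=float)
    if len(np.unique(th % 360.0)) < 6:
        raise ValueError("need at least 6 distinct directions")

    def model(theta, r0, rp, rn, thetap, sigma):
        d1 = wrapped_angle_diff(theta, thetap)
        d2 = wrapped_angle_diff(theta, thetap + 180.0)
        return (r0 + rp * np.exp(-d1**2 / (2 * sigma**2))
                + rn * np.exp(-d2**2 / (2 * sigma**2)))

    spread = max(np.ptp(r), 1e-9)
    best = None
    i_peak = int(np.argmax(r))
    for thetap0 in th:
        p0 = [float(np.min(r)), spread, spread / 2.0, float(thetap0), 30.0]
        try:
            popt, _ = optimize.curve_fit(
                model, th, r, p0=p0,
                bounds=([-np.inf, 0.0, 0.0, -360.0, 5.0],
                        [np.inf, np.inf, np.inf, 720.0, 180.0]),
                maxfev=5000)
        except RuntimeError:
            continue
        err = float(np.sum((model(th, *popt) - r) ** 2))
        if best is None or err < best[0]:
            best = (err, popt)
    if best is None:
        return DoubleGaussianFit(R0=float(np.min(r)), theta_pref_deg=float(th[i_peak]),
                                 sigma_deg=30.0, Rp_fit=float(r[i_peak] - np.min(r)),
                                 Rn_fit=0.0, converged=False)
    r0, rp, rn, thetap, sigma = best[1]
    # orient so the larger lobe is the preferred one
    if rn > rp:
        rp, rn = rn, rp
        thetap += 180.0
    return DoubleGaussianFit(R0=float(r0), theta_pref_deg=float(thetap % 360.0),
                             sigma_deg=float(sigma), Rp_fit=float(rp),
                             Rn_fit=float(rn))


def dsi(Rp, Rn):
    """(Rp - Rn)/Rp with Rn rectified at 0; requires Rp > 0."""
    if Rp <= 0:
        raise ValueError("DSI undefined for non-positive preferred response")
    return float((Rp - max(Rn, 0.0)) / Rp)


def dsi_from_curve(directions_deg, responses, component="F0+F1", signal="vm",
                   fit=None):
    """DSI from a direction tuning curve.

    The double-Gaussian fit is used only to locate the preferred direction;
    Rp and Rn are the empirical responses at the sampled direction nearest to
    thetap and at the direction nearest its opposite.  Returns None when the
    preferred response is non-positive (cell excluded).
    """
    th = np.asarray(directions_deg, dtype=float)
    r = np.asarray(responses, dtype=float)
    if fit is None and len(np.unique(th % 360.0)) >= 6:
        fit = fit_double_gaussian(th, r)
    theta_p = fit.theta_pref_deg if fit is not None else th[int(np.argmax(r))]
    ip = int(np.argmin(wrapped_angle_diff(th, theta_p)))
    inn = int(np.argmin(wrapped_angle_diff(th, theta_p + 180.0)))
    if r[inn] > r[ip]:  # empirical opposite lobe dominates; swap
        ip, inn = inn, ip
    Rp, Rn = float(r[ip]), float(max(r[inn], 0.0))
    if Rp <= 0:
        return None
    return DSIResult(dsi=dsi(Rp, Rn), Rp=Rp, Rn=Rn, component=component,
                     signal=signal, theta_pref_deg=float(th[ip]))


def responsiveness_anova(trial_responses_by_stimulus):
    """One-way ANOVA p-value for response variation across stimuli.

    Cells with p >= 0.05 are conventionally excluded from DSI analysis.
    Degenerate (zero-variance) data returns p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in trial_responses_by_stimulus]
    if len(groups) < 2:
        raise ValueError("need at least 2 stimuli")
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least 2 trials per stimulus")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.f_oneway(*groups).pvalue
    return 1.0 if np.isnan(p) else float(p)


def response_latency(vm, stim_onset_ms, baseline_mean, baseline_sd, k=6.0):
    """First post-onset time (ms, relative to onset) at which Vm exceeds the
    baseline mean by k baseline SDs; None when never reached."""
    if baseline_sd <= 0:
        raise ValueError("baseline SD must be positive")
    v = vm.samples
    i0 = int(round((stim_onset_ms - vm.t0_ms) / vm.dt_ms))
    post = v[i0:]
    above = np.nonzero(post - baseline_mean >= k * baseline_sd)[0]
    if above.size == 0:
        return None
    return float(above[0] * vm.dt_ms)
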