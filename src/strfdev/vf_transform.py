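"""Voltage-to-firing-rate transform estimation.

Spike-removed, smoothed, baseline-subtracted Vm and the spike train are
averaged in non-overlapping 30 ms bins to form (Vm, rate) pairs; the
relationship is fit with a rectified power law FR(V) = b*max(V-Vth,0)^alpha
with alpha constrained to [1, 4], by weighted least squares on 1 mV binned
means (weights = pair counts per bin) with a multi-start grid over Vth.
An empirical mean +- SEM curve in 1 mV bins, truncated at the first bin with
fewer than 15 pairs, summarizes the raw relationship.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .synthetic import SpikeTrain, VFParams, VmTrace

__all__ = [
    "VmRatePairs",
    "VFTransformFit",
    "EmpiricalCurve",
    "bin_vm_rate",
    "fit_power_law",
    "empirical_curve",
    "predict_rate",
]


@dataclass(frozen=True)
class VmRatePairs:
    vm_mV: np.ndarray
    rate_hz: np.ndarray
    bin_ms: float

    def __post_init__(self):
        if len(self.vm_mV) != len(self.rate_hz):
            raise ValueError("vm and rate sequences must have equal length")


@dataclass(frozen=True)
class VFTransformFit:
    params: VFParams
    fit_error: float  # RMSE on the fitting objective
    degenerate: bool = False

    @property
    def b(self):
        return self.params.b

    @property
    def vth_mV(self):
        return self.params.vth_mV

    @property
    def alpha(self):
        return self.params.alpha


@dataclass(frozen=True)
class EmpiricalCurve:
    bin_centers_mV: np.ndarray
    mean_rate: np.ndarray
    sem_rate: np.ndarray
    count: np.ndarray
    truncation_mV: float


def bin_vm_rate(vm_filtered, spikes, bin_ms=30.0, baseline_mV=0.0):
    """Mean Vm (baseline-subtracted) and firing rate in non-overlapping bins;
    the partial trailing bin is dropped."""
    if not isinstance(vm_filtered, VmTrace):
        raise TypeError("vm_filtered must be a VmTrace")
    per_bin = int(round(bin_ms / vm_filtered.dt_ms))
    n_bins = len(vm_filtered.samples) // per_bin
    if n_bins < 1:
        raise ValueError("trace shorter than one bin")
    v = vm_filtered.samples[: n_bins * per_bin] - baseline_mV
    vm_means = v.reshape(n_bins, per_bin).mean(axis=1)
    times = spikes.times_ms if isinstance(spikes, SpikeTrain) else np.asarray(spikes)
    rel = np.asarray(times, dtype=float) - vm_filtered.t0_ms
    idx = np.floor(rel / bin_ms).astype(int)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    counts = np.bincount(idx, minlength=n_bins)
    rates = counts / (bin_ms / 1000.0)
    return VmRatePairs(vm_mV=vm_means, rate_hz=rates, bin_ms=bin_ms)


def _binned_means(pairs, bin_mV=1.0):
    """Group (Vm, rate) pairs into 1 mV voltage bins."""
    edges_lo = np.floor(pairs.vm_mV.min() / bin_mV) * bin_mV
    idx = np.floor((pairs.vm_mV - edges_lo) / bin_mV).astype(int)
    n_bins = idx.max() + 1
    count = np.bincount(idx, minlength=n_bins)
    mean_v = np.full(n_bins, np.nan)
    mean_r = np.full(n_bins, np.nan)
    sem_r = np.full(n_bins, np.nan)
    for i in range(n_bins):
        sel = idx == i
        if count[i]:
            mean_v[i] = pairs.vm_mV[sel].mean()
            mean_r[i] = pairs.rate_hz[sel].mean()
            sem_r[i] = (pairs.rate_hz[sel].std(ddof=1) / np.sqrt(count[i])
                        if count[i] > 1 else 0.0)
    centers = edges_lo + (np.arange(n_bins) + 0.5) * bin_mV
    return centers, mean_v, mean_r, sem_r, count


def fit_power_law(pairs, weight_by_count=True, alpha_bounds=(1.0, 4.0),
                  vth_grid_mV=1.0, min_bin_count=15):
    """Least-squares rectified power-law fit over (b, Vth, alpha).

    Default objective: weighted least squares on the 1 mV binned mean rates
    (weights = pair counts), matching how the empirical curves are
    summarized; only bins holding at least ``min_bin_count`` pairs enter the
    objective — the same 15-pair reliability rule the empirical curve uses —
    because sparser bins carry Poisson-noisy means at high leverage.
    ``weight_by_count=False`` fits the raw 30 ms pairs instead.  The
    non-smooth Vth dependence is handled with a multi-start grid at
    ``vth_grid_mV`` spacing over the observed Vm range (ties -> lowest Vth);
    for each (Vth, alpha) the gain b has a closed-form weighted solution.
    """
    if len(pairs.vm_mV) < 30:
        raise ValueError("need at least 30 Vm/rate pairs")
    if np.all(pairs.rate_hz == 0):
        return VFTransformFit(
            params=VFParams(b=0.0, vth_mV=float(pairs.vm_mV.max()), alpha=1.0),
            fit_error=0.0, degenerate=True)

    if weight_by_count:
        _, v_fit, r_fit, _, counts = _binned_means(pairs)
        ok = counts >= min_bin_count
        if ok.sum() < 5:  # sparse recordings: fall back to all populated bins
            ok = counts > 0
        v_fit, r_fit, w = v_fit[ok], r_fit[ok], counts[ok].astype(float)
    else:
        v_fit, r_fit = pairs.vm_mV, pairs.rate_hz
        w = np.ones_like(v_fit)

    v_lo, v_hi = pairs.vm_mV.min(), pairs.vm_mV.max()
    vth_grid = np.arange(v_lo, v_hi, vth_grid_mV)

    def sse_for(vth, alpha):
        x = np.maximum(v_fit - vth, 0.0) ** alpha
        denom = np.sum(w * x * x)
        b = np.sum(w * r_fit * x) / denom if denom > 0 else 0.0
        resid = r_fit - b * x
        return float(np.sum(w * resid * resid)), b

    def eval_vth(vth):
        res = optimize.minimize_scalar(
            lambda a: sse_for(vth, a)[0], bounds=alpha_bounds, method="bounded",
            options={"xatol": 1e-3})
        alpha = float(res.x)
        sse, b = sse_for(vth, alpha)
        return sse, b, float(vth), alpha

    best = None
    for vth in vth_grid:
        cand = eval_vth(vth)
        if best is None or cand[0] < best[0] - 1e-12:  # ties keep lowest Vth
            best = cand
    # local refinement of the non-smooth Vth coordinate around the best
    # grid point
    res = optimize.minimize_scalar(lambda t: eval_vth(t)[0],
                                   bounds=(best[2] - vth_grid_mV,
                                           best[2] + vth_grid_mV),
                                   method="bounded", options={"xatol": 1e-3})
    cand = eval_vth(float(res.x))
    if cand[0] < best[0]:
        best = cand
    sse, b, vth, alpha = best
    rmse = float(np.sqrt(sse / np.sum(w)))
    return VFTransformFit(params=VFParams(b=b, vth_mV=vth, alpha=alpha),
                          fit_error=rmse)


def empirical_curve(pairs, bin_mV=1.0, min_count=15):
    """Mean +- SEM firing rate in 1 mV voltage bins, reported contiguously
    from the lowest populated bin up to (exclusive) the first bin with fewer
    than ``min_count`` pairs."""
    centers, _, mean_r, sem_r, count = _binned_means(pairs, bin_mV=bin_mV)
    first = np.argmax(count > 0)
    keep = []
    for i in range(first, len(count)):
        if count[i] < min_count:
            break
        keep.append(i)
    if not keep:
        return EmpiricalCurve(bin_centers_mV=np.array([]), mean_rate=np.array([]),
                              sem_rate=np.array([]), count=np.array([], dtype=int),
                              truncation_mV=float(centers[first]))
    keep = np.asarray(keep)
    trunc = centers[keep[-1]] + bin_mV
    return EmpiricalCurve(bin_centers_mV=centers[keep], mean_rate=mean_r[keep],
                          sem_rate=sem_r[keep], count=count[keep].astype(int),
                          truncation_mV=float(trunc))


def predict_rate(transform, vm_filtered, bin_ms=30.0, baseline_mV=0.0):
    """Predicted firing rate per 30 ms bin from a fitted (or known) transform
    applied to the bin-mean Vm."""
    params = transform.params if isinstance(transform, VFTransformFit) else transform
    pairs = bin_vm_rate(vm_filtered, SpikeTrain(times_ms=np.array([])),
                        bin_ms=bin_ms, baseline_mV=baseline_mV)
    return params.rate(pairs.vm_mV)
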