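"""STRF estimation by reverse correlation and subunit shape analysis.

The spike-removed Vm trace is cross-correlated with the sparse-noise contrast
sequence at every bar position, giving a positions x lags map (the STRF).
Raw correlations are used throughout: no whitening is attempted, so maps are
blurred in time by the 100 ms stimulus frame.  ON and OFF subunits are the
8-connected components of the brightest and darkest 5% of map pixels
(clusters under 20 pixels discarded), each summarized by the ellipse with the
same normalized second central moments and nine derived shape parameters.
A direction-selectivity prediction is read out from the 2-D Fourier amplitude
spectrum by comparing energy in the two motion-direction quadrants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, stats
from skimage import measure

from .synthetic import KernelSTRF, VmTrace, upsample_stimulus

__all__ = [
    "STRFMap",
    "PixelCluster",
    "SubunitShape",
    "SpectralPrediction",
    "reverse_correlate",
    "kernel_to_strf",
    "extract_subunits",
    "fit_ellipse",
    "shape_parameters",
    "analyze_subunits",
    "cell_average",
    "subunit_peak_values",
    "peak_correlation_check",
    "predict_dsi_fft",
]

SHAPE_PARAMETER_NAMES = (
    "eccentricity", "major_axis_px", "minor_axis_px", "orientation_deg",
    "area_px", "spatial_extent_deg", "temporal_extent_ms",
    "min_latency_ms", "max_latency_ms",
)


@dataclass(frozen=True)
class STRFMap:
    """Positions x lag-bins stimulus-Vm correlation map with physical axes."""

    corr: np.ndarray
    space_axis_deg: np.ndarray
    lag_axis_ms: np.ndarray  # bin centers
    normalized: bool = True

    @property
    def space_step_deg(self):
        return float(self.space_axis_deg[1] - self.space_axis_deg[0])

    @property
    def lag_step_ms(self):
        return float(self.lag_axis_ms[1] - self.lag_axis_ms[0])


@dataclass(frozen=True)
class PixelCluster:
    polarity: str  # "ON" | "OFF"
    mask: np.ndarray  # boolean, same shape as the STRF map

    @property
    def pixel_count(self):
        return int(self.mask.sum())


@dataclass(frozen=True)
class SubunitShape:
    """Fitted ellipse of one subunit and its nine shape parameters."""

    polarity: str
    pixel_count: int
    centroid_space_px: float
    centroid_lag_px: float
    eccentricity: float
    major_axis_px: float
    minor_axis_px: float
    orientation_deg: float  # angle of major axis to the space axis, [0, 90]
    area_px: float
    spatial_extent_deg: float = np.nan
    temporal_extent_ms: float = np.nan
    min_latency_ms: float = np.nan
    max_latency_ms: float = np.nan
    peak_corr: float = np.nan

    def parameters(self):
        return {name: getattr(self, name) for name in SHAPE_PARAMETER_NAMES}


@dataclass(frozen=True)
class SpectralPrediction:
    R_pref: float
    R_null: float
    dsi_pr: float
    pref_tf_sign: int


# ---------------------------------------------------------------------------
# reverse correlation
# ---------------------------------------------------------------------------

def reverse_correlate(vm_filtered, stimulus, max_lag_ms=400.0, lag_bin_ms=10.0,
                      normalize=True):
    """Cross-correlate the stimulus contrast with the spike-removed Vm.

    For each bar position independently, the Pearson correlation between the
    contrast sequence (zero-order-hold upsampled to the Vm sampling grid) and
    the Vm at lags 0..max_lag is computed, then averaged into lag bins of
    ``lag_bin_ms``.  With ``normalize=False`` the raw covariance is returned
    instead of the correlation coefficient.  Zero-variance positions yield a
    zero column (with a warning when normalized).
    """
    if not isinstance(vm_filtered, VmTrace):
        raise TypeError("vm_filtered must be a VmTrace")
    dt = vm_filtered.dt_ms
    c = upsample_stimulus(stimulus, dt)
    n = min(c.shape[1], len(vm_filtered.samples))
    c = c[:, :n]
    v = vm_filtered.samples[:n] - np.mean(vm_filtered.samples[:n])
    n_lags = int(round(max_lag_ms / dt))
    sd_v = np.std(v)

    v_pad = np.concatenate([v, np.zeros(n_lags)])
    corr = np.empty((c.shape[0], n_lags))
    for i, cx in enumerate(c):
        cx = cx - cx.mean()
        sd_c = np.std(cx)
        if sd_c == 0 or sd_v == 0:
            if normalize and sd_c == 0:
                warnings.warn(f"position {i} has zero stimulus variance; "
                              "column set to 0")
            corr[i] = 0.0
            continue
        # xc[tau] = sum_t c(t) * v(t + tau), tau = 0..n_lags-1
        spec = np.fft.rfft(v_pad) * np.conj(np.fft.rfft(cx, n=n + n_lags))
        xc = np.fft.irfft(spec, n=n + n_lags)[:n_lags]
        if normalize:
            corr[i] = xc / (n * sd_c * sd_v)
        else:
            corr[i] = xc / n
    # average into lag bins
    per_bin = max(1, int(round(lag_bin_ms / dt)))
    n_bins = n_lags // per_bin
    corr = corr[:, : n_bins * per_bin].reshape(c.shape[0], n_bins, per_bin)
    corr = corr.mean(axis=2)
    lag_centers = (np.arange(n_bins) + 0.5) * per_bin * dt
    return STRFMap(corr=corr, space_axis_deg=stimulus.space_axis_deg,
                   lag_axis_ms=lag_centers, normalized=normalize)


def kernel_to_strf(kernel: KernelSTRF, lag_bin_ms=10.0):
    """Resample a ground-truth kernel onto the STRF pixel grid (used to apply
    map-level analyses directly to known-truth kernels)."""
    dt = kernel.lag_dt_ms
    per_bin = max(1, int(round(lag_bin_ms / dt)))
    n_bins = kernel.weights.shape[1] // per_bin
    w = kernel.weights[:, : n_bins * per_bin]
    w = w.reshape(w.shape[0], n_bins, per_bin).mean(axis=2)
    lag_centers = kernel.lag_axis_ms[0] + (np.arange(n_bins) + 0.5) * per_bin * dt
    return STRFMap(corr=w, space_axis_deg=kernel.space_axis_deg,
                   lag_axis_ms=lag_centers, normalized=False)


# ---------------------------------------------------------------------------
# subunits
# ---------------------------------------------------------------------------

_CONNECTIVITY = {8: np.ones((3, 3), dtype=int),
                 4: ndimage.generate_binary_structure(2, 1)}


def extract_subunits(strf, pixel_fraction=0.05, min_pixels=20, connectivity=8):
    """ON/OFF pixel clusters from the brightest/darkest tails of the map.

    Thresholds are the (1 - pixel_fraction) and pixel_fraction quantiles of
    the whole image; connected components (8-connected by default) smaller
    than ``min_pixels`` are discarded as spurious.
    """
    img = strf.corr
    if img.size == 0:
        return []
    structure = _CONNECTIVITY[connectivity]
    hi = np.quantile(img, 1.0 - pixel_fraction)
    lo = np.quantile(img, pixel_fraction)
    clusters = []
    # ON pixels must be positive and OFF negative: guards degenerate maps
    # whose tail quantiles sit at zero
    for polarity, mask in (("ON", (img >= hi) & (img > 0)),
                           ("OFF", (img <= lo) & (img < 0))):
        labels, n = ndimage.label(mask, structure=structure)
        for lab in range(1, n + 1):
            m = labels == lab
            if m.sum() >= min_pixels:
                clusters.append(PixelCluster(polarity=polarity, mask=m))
    return clusters


def fit_ellipse(cluster, strf=None):
    """Ellipse with the same normalized second central moments as the pixel
    cluster (geometry fields only; physical extents added by
    :func:`shape_parameters`)."""
    mask = cluster.mask if isinstance(cluster, PixelCluster) else np.asarray(cluster)
    polarity = cluster.polarity if isinstance(cluster, PixelCluster) else "ON"
    props = measure.regionprops(mask.astype(int))[0]
    major = props.axis_major_length
    minor = props.axis_minor_length
    if minor < 1.0:  # degenerate (collinear) cluster: one-pixel floor
        minor = 1.0
        major = max(major, minor)
    ecc = float(np.sqrt(max(0.0, 1.0 - (minor / major) ** 2))) if major > 0 else 0.0
    # props.orientation is the angle between axis 0 (our space axis) and the
    # major axis, in (-pi/2, pi/2]; report its magnitude in degrees
    orientation = float(np.degrees(abs(props.orientation)))
    peak = np.nan
    if strf is not None:
        vals = strf.corr[mask]
        peak = float(np.max(np.abs(vals)))
    return SubunitShape(
        polarity=polarity, pixel_count=int(mask.sum()),
        centroid_space_px=float(props.centroid[0]),
        centroid_lag_px=float(props.centroid[1]),
        eccentricity=ecc, major_axis_px=float(major),
        minor_axis_px=float(minor), orientation_deg=orientation,
        area_px=float(mask.sum()), peak_corr=peak)


def shape_parameters(ellipse: SubunitShape, space_axis_deg, lag_axis_ms):
    """Fill in physical extents and latency bounds from the ellipse tangent
    extremes.

    For an ellipse with semi-axes (a, b) and major-axis angle theta to the
    space axis, the half-extent of its bounding projection is
    sqrt(a^2 cos^2 + b^2 sin^2) on the space axis and
    sqrt(a^2 sin^2 + b^2 cos^2) on the lag axis; the min/max latencies are the
    ellipse's lower/upper tangent bounds on the lag axis (the lower bound may
    be negative because of the stimulus-step blur).
    """
    space_axis_deg = np.asarray(space_axis_deg, dtype=float)
    lag_axis_ms = np.asarray(lag_axis_ms, dtype=float)
    dx = float(space_axis_deg[1] - space_axis_deg[0])
    dtl = float(lag_axis_ms[1] - lag_axis_ms[0])
    a = ellipse.major_axis_px / 2.0
    b = ellipse.minor_axis_px / 2.0
    th = np.deg2rad(ellipse.orientation_deg)
    half_space_px = np.sqrt((a * np.cos(th)) ** 2 + (b * np.sin(th)) ** 2)
    half_lag_px = np.sqrt((a * np.sin(th)) ** 2 + (b * np.cos(th)) ** 2)
    center_lag_ms = lag_axis_ms[0] + ellipse.centroid_lag_px * dtl
    return replace(
        ellipse,
        spatial_extent_deg=float(2 * half_space_px * abs(dx)),
        temporal_extent_ms=float(2 * half_lag_px * dtl),
        min_latency_ms=float(center_lag_ms - half_lag_px * dtl),
        max_latency_ms=float(center_lag_ms + half_lag_px * dtl),
    )


def analyze_subunits(strf, pixel_fraction=0.05, min_pixels=20, connectivity=8):
    """Full subunit pipeline on one STRF: clusters -> ellipses -> shape
    parameters."""
    out = []
    for cluster in extract_subunits(strf, pixel_fraction=pixel_fraction,
                                    min_pixels=min_pixels,
                                    connectivity=connectivity):
        ell = fit_ellipse(cluster, strf=strf)
        out.append(shape_parameters(ell, strf.space_axis_deg, strf.lag_axis_ms))
    return out


def cell_average(subunits):
    """Unweighted mean of the nine shape parameters across a cell's ON and
    OFF subunits; None for a cell with no accepted subunit."""
    if not subunits:
        return None
    return {name: float(np.mean([s.parameters()[name] for s in subunits]))
            for name in SHAPE_PARAMETER_NAMES}


def subunit_peak_values(strf, subunits):
    """Absolute peak correlation of each subunit (SNR control quantity)."""
    return [float(np.max(np.abs(strf.corr[s.mask]))) if isinstance(s, PixelCluster)
            else s.peak_corr
            for s in subunits]


def peak_correlation_check(peaks_by_class):
    """One-way ANOVA across polarity x group classes of absolute peak
    correlations (e.g. Naive_ON, Naive_OFF, Exp_ON, Exp_OFF); an
    indistinguishable result (p > 0.05) indicates matched map SNR."""
    groups = {k: np.asarray(v, dtype=float) for k, v in peaks_by_class.items()}
    if any(len(v) < 2 for v in groups.values()) or len(groups) < 2:
        raise ValueError("need at least 2 values in each of >= 2 classes")
    return float(stats.f_oneway(*groups.values()).pvalue)


# ---------------------------------------------------------------------------
# spectral direction-selectivity prediction
# ---------------------------------------------------------------------------

def predict_dsi_fft(strf, sf_max=0.2, tf_max=10.0):
    """Predicted DSI from the 2-D Fourier amplitude spectrum of the STRF.

    Amplitudes are summed over the quadrant sf in (0, sf_max], tf in
    (0, tf_max] and the quadrant sf in (0, sf_max], tf in [-tf_max, 0); the
    larger sum is the preferred response and
    DSI_pr = (R_pref - R_null)/R_pref.  DC rows/columns are excluded.
    """
    img = strf.corr
    if not np.any(img):
        raise ValueError("cannot predict DSI from an all-zero map")
    amp = np.abs(np.fft.fft2(img))
    sf = np.fft.fftfreq(img.shape[0], d=abs(strf.space_step_deg))
    tf = np.fft.fftfreq(img.shape[1], d=strf.lag_step_ms / 1000.0)
    sf_sel = (sf > 0) & (sf <= sf_max)
    tf_pos = (tf > 0) & (tf <= tf_max)
    tf_neg = (tf < 0) & (tf >= -tf_max)
    r_a = float(amp[np.ix_(sf_sel, tf_pos)].sum())
    r_b = float(amp[np.ix_(sf_sel, tf_neg)].sum())
    r_pref, r_null = max(r_a, r_b), min(r_a, r_b)
    sign = +1 if r_a >= r_b else -1
    if r_pref == 0:
        raise ValueError("no spectral energy in the analysis band")
    return SpectralPrediction(R_pref=r_pref, R_null=r_null,
                              dsi_pr=(r_pref - r_null) / r_pref,
                              pref_tf_sign=sign)
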