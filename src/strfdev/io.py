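"""Serialization of synthetic recordings.

One recording = Vm trace + spike times + stimulus + metadata, stored in an
HDF5 container with groups /vm, /spikes, /stimulus and /meta.  Ground-truth
parameter tables export to CSV via pandas.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import SpikeTrain, StimulusMovie, SyntheticCell, VmTrace


def save_recording(path, vm: VmTrace, spikes: SpikeTrain,
                   stimulus: StimulusMovie, meta=None):
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("vm")
        g.create_dataset("samples", data=vm.samples)
        g.attrs["dt_ms"] = vm.dt_ms
        g.attrs["t0_ms"] = vm.t0_ms
        f.create_group("spikes").create_dataset("times_ms", data=spikes.times_ms)
        s = f.create_group("stimulus")
        s.create_dataset("contrast", data=stimulus.contrast)
        s.attrs["frame_ms"] = stimulus.frame_ms
        s.attrs["bar_width_deg"] = stimulus.bar_width_deg
        s.attrs["kind"] = stimulus.kind
        m = f.create_group("meta")
        for k, v in (meta or {}).items():
            m.attrs[k] = v


def load_recording(path):
    import h5py

    with h5py.File(path, "r") as f:
        vm = VmTrace(samples=f["vm/samples"][...],
                     dt_ms=float(f["vm"].attrs["dt_ms"]),
                     t0_ms=float(f["vm"].attrs["t0_ms"]))
        spikes = SpikeTrain(times_ms=f["spikes/times_ms"][...])
        stim = StimulusMovie(contrast=f["stimulus/contrast"][...],
                             frame_ms=float(f["stimulus"].attrs["frame_ms"]),
                             bar_width_deg=float(f["stimulus"].attrs["bar_width_deg"]),
                             kind=str(f["stimulus"].attrs["kind"]))
        meta = dict(f["meta"].attrs)
    return vm, spikes, stim, meta


def ground_truth_table(cells):
    """Ground-truth parameters of a synthetic population as a DataFrame."""
    rows = []
    for c in cells:
        rows.append({
            "cell_id": c.cell_id, "group": c.group, "seed": c.seed,
            "tilt_cyc_per_ms": c.kernel.tilt_cyc_per_ms,
            "sigma_x_deg": c.kernel.sigma_x_deg,
            "sigma_t_ms": c.kernel.sigma_t_ms,
            "t_center_ms": c.kernel.t_center_ms,
            "vf_b": c.vf.b, "vf_vth_mV": c.vf.vth_mV, "vf_alpha": c.vf.alpha,
            "kink_mV": c.spike_shape.kink_mV,
            "max_dvdt_mV_per_ms": c.spike_shape.max_dvdt_mV_per_ms,
            "fwhm_ms": c.spike_shape.fwhm_ms,
            "baseline_mV": c.baseline_mV, "noise_sd": c.noise_sd,
            "pref_direction_deg": c.pref_direction_deg,
        })
    return pd.DataFrame(rows)


def load_dryad_recording(path):  # pragma: no cover - stub adapter
    """Stub adapter for the deposited raw recordings.

    The published dataset ships MATLAB-format files whose parsing is outside
    this package's scope; a caller with those files should convert them to
    the HDF5 schema of :func:`save_recording` (groups /vm, /spikes,
    /stimulus, /meta) and use :func:`load_recording`.
    """
    raise NotImplementedError(
        "raw-archive parsing is out of scope; convert to the documented "
        "HDF5 schema and use load_recording()")
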