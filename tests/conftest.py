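import numpy as np
import pytest

from strfdev import preprocess, synthetic


@pytest.fixture(scope="session")
def experienced_cell():
    return synthetic.make_synthetic_cell("experienced", seed=11)


@pytest.fixture(scope="session")
def naive_cell():
    return synthetic.make_synthetic_cell("naive", seed=7)


def simulate_recording(cell, duration_s, seed, dt_ms=1.0, inject=True):
    """Sparse-noise recording for one synthetic cell: stimulus, subthreshold
    Vm, spikes, and the full trace with injected action potentials."""
    stim = synthetic.make_sparse_noise(
        n_positions=cell.kernel.weights.shape[0], duration_s=duration_s,
        bar_width_deg=float(np.diff(cell.kernel.space_axis_deg)[0]),
        seed=seed)
    vm = synthetic.simulate_vm(stim, cell.kernel, noise_sd=cell.noise_sd,
                               baseline_mV=cell.baseline_mV, dt_ms=dt_ms,
                               seed=seed + 1, noise_tau_ms=cell.noise_tau_ms)
    spikes = synthetic.simulate_spikes(
        vm, cell.vf, refractory_ms=cell.refractory_ms, seed=seed + 2,
        baseline_mV=cell.baseline_mV, max_rate_hz=cell.max_rate_hz,
        integration_ms=cell.integration_ms)
    vm_full = (synthetic.inject_spike_waveforms(vm, spikes, cell.spike_shape)
               if inject else vm)
    return stim, vm, spikes, vm_full


@pytest.fixture(scope="session")
def experienced_noise_recording(experienced_cell):
    """A 10-minute sparse-noise recording (shared by STRF-estimation tests)."""
    return simulate_recording(experienced_cell, duration_s=600.0, seed=55)
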