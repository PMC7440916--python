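"""Group-comparison statistics and the end-to-end synthetic experiment.

Thin, explicit wrappers around the standard nonparametric tests used for
group comparisons (Wilcoxon rank-sum for unpaired, signed-rank for paired
within-cell, Fisher exact for proportions, Kruskal-Wallis for slopes, one-way
ANOVA for responsiveness), Bonferroni correction within declared families,
ordinary least-squares correlations of shape parameters against Vm DSI, and
``run_pipeline`` which drives every analysis stage over a synthetic
two-group experiment and assembles a report.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import intrinsic, mixture_model, preprocess, receptive_field, synthetic, \
    tuning, vf_transform

__all__ = [
    "GroupComparison",
    "compare_groups",
    "linear_corr",
    "percent_increase",
    "run_pipeline",
    "DEFAULT_CONFIG",
]

#: Bonferroni families: the nine subunit shape parameters form one family,
#: the intrinsic spike metrics another.
FAMILIES = {
    "shape": 9,
    "intrinsic": 3,
}


@dataclass(frozen=True)
class GroupComparison:
    parameter: str
    test: str
    statistic: float
    p_raw: float
    p_bonferroni: float
    n_a: int
    n_b: int


def compare_groups(values_a, values_b, test="wrs", paired=False, n_family=1,
                   parameter=""):
    """Two-group comparison with the test the analysis convention assigns:
    unpaired -> Wilcoxon rank-sum, paired within-cell -> signed-rank,
    proportions -> Fisher exact, slopes -> Kruskal-Wallis.  All tests are
    two-sided; Bonferroni-adjusted p = min(1, p * n_family)."""
    if test == "fisher":
        # values are (successes, total) per group
        (ka, na), (kb, nb) = values_a, values_b
        table = [[ka, na - ka], [kb, nb - kb]]
        statistic, p = stats.fisher_exact(table, alternative="two-sided")
        n_a, n_b = na, nb
    else:
        a = np.asarray(values_a, dtype=float)
        b = np.asarray(values_b, dtype=float)
        if a.size == 0 or b.size == 0:
            raise ValueError("empty group")
        n_a, n_b = a.size, b.size
        if paired or test == "signed_rank":
            res = stats.wilcoxon(a, b)
            test = "signed_rank"
        elif test == "wrs":
            res = stats.ranksums(a, b)
        elif test == "kruskal_wallis":
            res = stats.kruskal(a, b)
        elif test == "anova":
            res = stats.f_oneway(a, b)
        else:
            raise ValueError(f"unknown test {test!r}")
        statistic, p = res.statistic, res.pvalue
    return GroupComparison(parameter=parameter, test=test,
                           statistic=float(statistic), p_raw=float(p),
                           p_bonferroni=float(min(1.0, p * n_family)),
                           n_a=int(n_a), n_b=int(n_b))


def linear_corr(x, y, return_loo=False):
    """OLS linear correlation: returns (r_squared, p, slope).

    With ``return_loo`` a leave-one-out array of r-squared values is appended,
    for outlier-sensitivity checks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor")
    res = stats.linregress(x, y)
    out = (float(res.rvalue**2), float(res.pvalue), float(res.slope))
    if not return_loo:
        return out
    loo = []
    for i in range(x.size):
        keep = np.arange(x.size) != i
        loo.append(float(stats.linregress(x[keep], y[keep]).rvalue ** 2))
    return out + (np.asarray(loo),)


def percent_increase(before, after):
    """Percent change from ``before`` to ``after``: 100*(after-before)/before."""
    if before == 0:
        raise ValueError("undefined percent increase from zero")
    return 100.0 * (after - before) / before


# ---------------------------------------------------------------------------
# end-to-end synthetic experiment
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 0,
    "groups": {"naive": 8, "experienced": 8},
    "grating": {"tf_hz": 4.0, "duration_s": 4.0, "n_trials": 4, "dt_ms": 1.0},
    "noise": {"duration_s": 120.0, "frame_ms": 100.0, "dt_ms": 1.0},
    "strf": {"max_lag_ms": 400.0, "lag_bin_ms": 10.0,
             "pixel_fraction": 0.05, "min_pixels": 20},
    "vf": {"bin_ms": 30.0},
    "mixture": {"n_sim": 2000, "n_cells": 20, "waveform_duration_s": 5.0},
    "intrinsic_dt_ms": 0.1,
}


def _merge(base, override):
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(
            base.get(k), dict) else v
    return out


def _tuning_stage(cells, cfg, seed):
    """Preferred/null grating responses (Vm and spikes) per cell."""
    g = cfg["grating"]
    rows = []
    for idx, cell in enumerate(cells):
        rec = {"cell_id": cell.cell_id, "group": cell.group}
        resp = {}
        for k, direction in enumerate((cell.pref_direction_deg,
                                       (cell.pref_direction_deg + 180) % 360)):
            stim = synthetic.make_grating_stimulus(
                direction, tf_hz=g["tf_hz"], duration_s=g["duration_s"],
                n_positions=cell.kernel.weights.shape[0],
                bar_width_deg=float(np.diff(cell.kernel.space_axis_deg)[0]))
            vm_f0f1, sp_f0f1, n_spk = [], [], 0
            for trial in range(g["n_trials"]):
                s = (seed + 7919 * idx + 211 * k + trial) % (2**31 - 1)
                vm = synthetic.simulate_vm(stim, cell.kernel,
                                           noise_sd=cell.noise_sd,
                                           baseline_mV=cell.baseline_mV,
                                           dt_ms=g["dt_ms"], seed=s,
                                           noise_tau_ms=cell.noise_tau_ms)
                spikes = synthetic.simulate_spikes(
                    vm, cell.vf, refractory_ms=cell.refractory_ms,
                    seed=s + 1, baseline_mV=cell.baseline_mV,
                    max_rate_hz=cell.max_rate_hz)
                vm_full = synthetic.inject_spike_waveforms(vm, spikes,
                                                           cell.spike_shape)
                pp = preprocess.preprocess_trace(vm_full)
                cr = tuning.cycle_fourier(pp.vm_filtered, g["tf_hz"],
                                          baseline=cell.baseline_mV)
                vm_f0f1.append((max(cr.F0, 0.0), cr.F1))
                rate = np.zeros(len(vm.samples))
                for t in spikes.times_ms:
                    rate[int(t / g["dt_ms"])] += 1000.0 / g["dt_ms"]
                sr = tuning.cycle_fourier(rate, g["tf_hz"], dt_ms=g["dt_ms"])
                sp_f0f1.append((sr.F0, sr.F1))
                n_spk += len(spikes)
            resp[k] = {"vm": np.mean(vm_f0f1, axis=0),
                       "spike": np.mean(sp_f0f1, axis=0),
                       "n_spikes": n_spk}
        vm_p = resp[0]["vm"].sum()
        vm_n = resp[1]["vm"].sum()
        rec["vm_dsi_total"] = tuning.dsi(vm_p, vm_n) if vm_p > 0 else np.nan
        rec["vm_pref_total"] = vm_p
        rec["vm_null_total"] = vm_n
        sp_p = resp[0]["spike"].sum()
        sp_n = resp[1]["spike"].sum()
        rec["fires"] = (resp[0]["n_spikes"] + resp[1]["n_spikes"]) > 0
        rec["spike_dsi_total"] = tuning.dsi(sp_p, sp_n) if sp_p > 0 else np.nan
        rec["spike_pref_total"] = sp_p
        f0, f1 = resp[0]["spike"]
        vf0, vf1 = resp[0]["vm"]
        spike_mr = f1 / f0 if f0 > 0 else None
        vm_mr = vf1 / vf0 if vf0 > 0 else np.inf
        rec["cell_class"] = tuning.classify_simple_complex(
            spike_mod_ratio=spike_mr, vm_mod_ratio=vm_mr,
            has_spikes=bool(rec["fires"] and spike_mr is not None))
        rows.append(rec)
    return pd.DataFrame(rows)


def _strf_stage(cells, cfg, seed):
    """Sparse-noise STRFs, subunit shape parameters and predicted DSI."""
    nz, sc = cfg["noise"], cfg["strf"]
    sub_rows, cell_rows = [], []
    for idx, cell in enumerate(cells):
        stim = synthetic.make_sparse_noise(
            n_positions=cell.kernel.weights.shape[0],
            duration_s=nz["duration_s"], frame_ms=nz["frame_ms"],
            bar_width_deg=float(np.diff(cell.kernel.space_axis_deg)[0]),
            seed=(seed + 104729 * idx) % (2**31 - 1))
        vm = synthetic.simulate_vm(stim, cell.kernel, noise_sd=cell.noise_sd,
                                   baseline_mV=cell.baseline_mV,
                                   dt_ms=nz["dt_ms"],
                                   seed=(seed + 104729 * idx + 1) % (2**31 - 1),
                                   noise_tau_ms=cell.noise_tau_ms)
        spikes = synthetic.simulate_spikes(vm, cell.vf,
                                           refractory_ms=cell.refractory_ms,
                                           seed=(seed + 104729 * idx + 2) % (2**31 - 1),
                                           baseline_mV=cell.baseline_mV,
                                           max_rate_hz=cell.max_rate_hz)
        vm_full = synthetic.inject_spike_waveforms(vm, spikes, cell.spike_shape)
        filtered = preprocess.remove_spikes_median(vm_full)
        strf = receptive_field.reverse_correlate(
            filtered, stim, max_lag_ms=sc["max_lag_ms"],
            lag_bin_ms=sc["lag_bin_ms"])
        subunits = receptive_field.analyze_subunits(
            strf, pixel_fraction=sc["pixel_fraction"],
            min_pixels=sc["min_pixels"])
        for s in subunits:
            row = {"cell_id": cell.cell_id, "group": cell.group,
                   "polarity": s.polarity, **s.parameters(),
                   "peak_corr": s.peak_corr}
            sub_rows.append(row)
        avg = receptive_field.cell_average(subunits)
        pred = receptive_field.predict_dsi_fft(strf)
        crow = {"cell_id": cell.cell_id, "group": cell.group,
                "n_subunits": len(subunits), "dsi_pr": pred.dsi_pr}
        if avg:
            crow.update({f"avg_{k}": v for k, v in avg.items()})
        cell_rows.append(crow)
    return pd.DataFrame(sub_rows), pd.DataFrame(cell_rows)


def _intrinsic_stage(cells, cfg):
    """Spike-shape metrics from injected templates at fine sampling."""
    dt = cfg["intrinsic_dt_ms"]
    rows = []
    for cell in cells:
        hold = cell.spike_shape.kink_mV - cell.spike_shape.foot_mV
        n = int(round(200.0 / dt))
        base = synthetic.VmTrace(samples=np.full(n, hold), dt_ms=dt)
        times = np.arange(20.0, 200.0 - 20.0, 40.0)
        vm = synthetic.inject_spike_waveforms(
            base, synthetic.SpikeTrain(times_ms=times), cell.spike_shape)
        waveforms, mean_wf = intrinsic.extract_spike_waveforms(
            vm.samples, times + 2.0, dt, pre_ms=8.0, post_ms=8.0)
        m = intrinsic.spike_shape_metrics(mean_wf, dt, n_spikes=len(waveforms))
        rows.append({"cell_id": cell.cell_id, "group": cell.group,
                     "max_dvdt": m.max_dvdt, "kink_mV": m.kink_mV,
                     "fwhm_ms": m.fwhm_ms,
                     "true_max_dvdt": cell.spike_shape.max_dvdt_mV_per_ms,
                     "true_kink_mV": cell.spike_shape.kink_mV,
                     "true_fwhm_ms": cell.spike_shape.fwhm_ms})
    return pd.DataFrame(rows)


def _vf_stage(cells, cfg, seed):
    """Fit each cell's transform from a sparse-noise recording."""
    nz = cfg["noise"]
    rows = []
    for idx, cell in enumerate(cells):
        stim = synthetic.make_sparse_noise(
            n_positions=cell.kernel.weights.shape[0],
            duration_s=nz["duration_s"], frame_ms=nz["frame_ms"],
            bar_width_deg=float(np.diff(cell.kernel.space_axis_deg)[0]),
            seed=(seed + 15485863 * idx) % (2**31 - 1))
        vm = synthetic.simulate_vm(stim, cell.kernel, noise_sd=cell.noise_sd,
                                   baseline_mV=cell.baseline_mV,
                                   dt_ms=nz["dt_ms"],
                                   seed=(seed + 15485863 * idx + 1) % (2**31 - 1),
                                   noise_tau_ms=cell.noise_tau_ms)
        spikes = synthetic.simulate_spikes(vm, cell.vf,
                                           refractory_ms=cell.refractory_ms,
                                           seed=(seed + 15485863 * idx + 2) % (2**31 - 1),
                                           baseline_mV=cell.baseline_mV,
                                           max_rate_hz=cell.max_rate_hz)
        vm_full = synthetic.inject_spike_waveforms(vm, spikes, cell.spike_shape)
        filtered = preprocess.smooth_60hz(preprocess.remove_spikes_median(vm_full))
        pairs = vf_transform.bin_vm_rate(filtered, spikes,
                                         bin_ms=cfg["vf"]["bin_ms"],
                                         baseline_mV=cell.baseline_mV)
        fit = vf_transform.fit_power_law(pairs)
        rows.append({"cell_id": cell.cell_id, "group": cell.group,
                     "b": fit.b, "vth_mV": fit.vth_mV, "alpha": fit.alpha,
                     "rmse": fit.fit_error, "degenerate": fit.degenerate,
                     "true_b": cell.vf.b, "true_vth_mV": cell.vf.vth_mV,
                     "true_alpha": cell.vf.alpha})
    return pd.DataFrame(rows)


def _mixture_stage(populations, cfg, seed):
    mx = cfg["mixture"]
    mix_cells = {
        g: [mixture_model.mixture_cell_from_synthetic(
                c, duration_s=mx["waveform_duration_s"],
                dt_ms=cfg["grating"]["dt_ms"], tf_hz=cfg["grating"]["tf_hz"])
            for c in cells]
        for g, cells in populations.items()
    }
    results = {}
    names = sorted(populations)
    for i, wg in enumerate(names):
        for j, tg in enumerate(names):
            cond = mixture_model.MixtureCondition(wg, tg)
            res = mixture_model.bootstrap_mixture(
                mix_cells[wg], mix_cells[tg], n_sim=mx["n_sim"],
                n_cells=mx["n_cells"], seed=seed + 31 * i + 7 * j,
                condition=cond)
            results[cond.label] = {
                "mean_dsi": float(np.nanmean(res.sim_mean_dsi)),
                "mean_rate": float(np.nanmean(res.sim_mean_rate)),
                "pct5": res.pct5, "pct95": res.pct95,
            }
    overest = {g: mixture_model.overestimation_check(cells)
               for g, cells in mix_cells.items()}
    return results, overest


def _stats_stage(tuning_df, strf_cells_df, intrinsic_df):
    comps = {}
    nai = tuning_df[tuning_df.group == "naive"]
    exp = tuning_df[tuning_df.group == "experienced"]
    for col in ("vm_dsi_total", "spike_dsi_total", "vm_pref_total",
                "spike_pref_total"):
        a, b = nai[col].dropna(), exp[col].dropna()
        if len(a) and len(b):
            comps[col] = asdict(compare_groups(a, b, test="wrs", parameter=col))
    comps["fires_fraction"] = asdict(compare_groups(
        (int(nai.fires.sum()), len(nai)), (int(exp.fires.sum()), len(exp)),
        test="fisher", parameter="fires_fraction"))
    ni = intrinsic_df[intrinsic_df.group == "naive"]
    ei = intrinsic_df[intrinsic_df.group == "experienced"]
    for col in ("max_dvdt", "kink_mV", "fwhm_ms"):
        comps[col] = asdict(compare_groups(ni[col], ei[col], test="wrs",
                                           n_family=FAMILIES["intrinsic"],
                                           parameter=col))
    shape_cols = [c for c in strf_cells_df.columns if c.startswith("avg_")]
    ns = strf_cells_df[strf_cells_df.group == "naive"]
    es = strf_cells_df[strf_cells_df.group == "experienced"]
    for col in shape_cols:
        a, b = ns[col].dropna(), es[col].dropna()
        if len(a) > 1 and len(b) > 1:
            comps[col] = asdict(compare_groups(a, b, test="wrs",
                                               n_family=FAMILIES["shape"],
                                               parameter=col))
    return comps


def run_pipeline(config=None, out_dir=None):
    """Run the full synthetic two-group experiment and assemble the report.

    Stages: generate -> tuning -> STRF/subunits -> intrinsic -> V-F ->
    mixture model -> group statistics.  A stage failure is recorded in the
    report and independent stages continue.  Fixed seed gives a bit-identical
    report.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    seed = int(cfg["seed"])
    report = {"config": cfg, "stages": {}, "failures": {}}
    populations = {g: synthetic.make_cell_population(g, n, seed=seed + i)
                   for i, (g, n) in enumerate(sorted(cfg["groups"].items()))}
    cells = [c for cc in populations.values() for c in cc]
    frames = {}

    def stage(name, fn):
        try:
            report["stages"][name] = fn()
        except Exception as exc:  # keep independent stages running
            report["failures"][name] = f"{type(exc).__name__}: {exc}"

    def do_tuning():
        df = _tuning_stage(cells, cfg, seed)
        frames["tuning"] = df
        return {"n_cells": len(df),
                "mean_vm_dsi": {g: float(df[df.group == g].vm_dsi_total.mean())
                                for g in populations}}

    def do_strf():
        sub_df, cell_df = _strf_stage(cells, cfg, seed)
        frames["subunits"], frames["strf_cells"] = sub_df, cell_df
        return {"n_subunits": len(sub_df),
                "mean_dsi_pr": {g: float(cell_df[cell_df.group == g].dsi_pr.mean())
                                for g in populations}}

    def do_intrinsic():
        df = _intrinsic_stage(cells, cfg)
        frames["intrinsic"] = df
        return {"mean_max_dvdt": {g: float(df[df.group == g].max_dvdt.mean())
                                  for g in populations}}

    def do_vf():
        df = _vf_stage(cells, cfg, seed)
        frames["vf"] = df
        return {"mean_b": {g: float(df[df.group == g].b.mean())
                           for g in populations},
                "mean_vth": {g: float(df[df.group == g].vth_mV.mean())
                             for g in populations}}

    def do_mixture():
        results, overest = _mixture_stage(populations, cfg, seed)
        return {"conditions": results, "overestimation_ratio": overest}

    stage("tuning", do_tuning)
    stage("strf", do_strf)
    stage("intrinsic", do_intrinsic)
    stage("vf", do_vf)
    stage("mixture", do_mixture)
    if all(k in frames for k in ("tuning", "strf_cells", "intrinsic")):
        stage("stats", lambda: _stats_stage(frames["tuning"],
                                            frames["strf_cells"],
                                            frames["intrinsic"]))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in frames.items():
            df.to_csv(out / f"{name}.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        with open(out / "log.txt", "w") as fh:
            fh.write(f"seed={seed}\nconfig={cfg}\n"
                     f"failures={report['failures']}\n")
    report["_frames"] = frames
    return report
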