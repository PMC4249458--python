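"""Scripted, seeded in-silico experiments on the microzone model.

Each experiment returns an :class:`ExperimentReport` holding every number it
computed together with the seeds and settings that produced it, so any
reported value can be regenerated exactly.

The experiments:

* ``exp_isolated`` — firing statistics of a single neuron with no synaptic
  input (regular firing driven purely by the stochastic endogenous current);
* ``exp_network`` — the intact 16-PKJ / 160-MLI microzone (irregular
  firing, rate diversity, rate-CV anticorrelation);
* ``exp_feedforward`` — a two-neuron MLI->PKJ motif probing how a single
  timed inhibitory conductance prolongs the Purkinje inter-spike interval;
* ``exp_pruning`` — network statistics as MLI->MLI or PKJ->MLI synapses are
  randomly removed;
* ``calibrate_spont`` — grid search over the gamma drive (kappa, beta)
  matching a target isolated rate and CV;
* ``exp_robustness`` — re-instantiation consistency and tolerance to ±10%
  parameter perturbation.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import analysis
from .engine import SimSettings, SimResult, run_simulation, force_spike
from .network import (
    ConnectionType,
    Network,
    NetworkConfig,
    Neuron,
    Synapse,
    build_network,
    prune_synapses,
)
from .neuron import CellClass, NeuronParams, DEFAULT_PARAMS, DT_MS

__all__ = [
    "ExperimentReport",
    "single_neuron_network",
    "two_neuron_motif",
    "exp_isolated",
    "exp_network",
    "exp_feedforward",
    "exp_pruning",
    "calibrate_spont",
    "CalibrationResult",
    "exp_robustness",
]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class ExperimentReport:
    """Name, settings, seeds and results of one experiment run.

    ``results`` holds scalars and small arrays (JSON-serializable);
    ``tables`` holds any per-neuron / per-condition DataFrames.
    """

    name: str
    settings: Dict
    seeds: Dict
    results: Dict
    tables: Dict[str, pd.DataFrame] = field(default_factory=dict)

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = {
            "experiment": self.name,
            "settings": _jsonable(self.settings),
            "seeds": _jsonable(self.seeds),
            "results": _jsonable(self.results),
        }
        report_path = out / f"{self.name}_report.json"
        report_path.write_text(json.dumps(payload, indent=1))
        for key, df in self.tables.items():
            df.to_csv(out / f"{self.name}_{key}.csv", index=False)
        return report_path


# ---------------------------------------------------------------------------
# hand-built micro-networks


def single_neuron_network(cell_class: CellClass) -> Network:
    """A one-neuron, zero-synapse network (the isolated-neuron preparation)."""
    config = NetworkConfig(n_pkj=1, mli_per_pkj=1, lower_mli_per_pkj=1)
    neuron = Neuron(
        id=0,
        cell_class=cell_class,
        territory=0,
        within_territory=0,
        lower_ml=False,
        position_um=0.0,
    )
    return Network(config=config, neurons=[neuron], synapses=[], mli_direction={}, pkj_direction={})


def two_neuron_motif(peak_ipsc_ns: float) -> Network:
    """PKJ (id 0) receiving one MLI (id 1) synapse of the given peak
    conductance.

    The peak is an explicit override in nS: the synapse weight is chosen so
    that ``weight * g_gaba_peak(PKJ)`` equals it, which allows probing
    conductances beyond the anatomical weight bounds.
    """
    if peak_ipsc_ns < 0:
        raise ValueError("peak conductance must be non-negative")
    config = NetworkConfig(n_pkj=1, mli_per_pkj=1, lower_mli_per_pkj=1)
    pkj = Neuron(0, CellClass.PKJ, 0, 0, False, 0.0)
    mli = Neuron(1, CellClass.MLI, 0, 0, True, 0.0)
    weight = peak_ipsc_ns / DEFAULT_PARAMS[CellClass.PKJ].g_gaba_peak
    synapses = [Synapse(1, 0, ConnectionType.MLI_PKJ, weight)]
    return Network(config=config, neurons=[pkj, mli], synapses=synapses,
                   mli_direction={1: 1}, pkj_direction={0: 1})


# ---------------------------------------------------------------------------
# experiments


def exp_isolated(
    cell_class: CellClass,
    duration_ms: float = 300_000.0,
    seed: int = 0,
    dt: float = DT_MS,
    drive_scale: float = 1.0,
    params: Optional[Mapping[CellClass, NeuronParams]] = None,
) -> ExperimentReport:
    """Isolated-neuron firing statistics (no synaptic currents)."""
    net = single_neuron_network(cell_class)
    settings = SimSettings(duration_ms=duration_ms, dt=dt, sim_seed=seed)
    result = run_simulation(net, settings, params=params, current_scale=drive_scale)
    train = result.train(0)
    rate = analysis.mean_rate(train, duration_ms)
    cv = analysis.isi_cv(train)
    hist_counts, hist_edges = analysis.isi_histogram(train, 1.0)
    ac_counts, ac_edges = analysis.autocorrelogram(train, 1.0, 100.0)
    results = {
        "cell_class": cell_class.value,
        "rate_hz": rate,
        "isi_cv": cv,
        "n_spikes": len(train),
    }
    if len(train) >= analysis.MIN_SPIKES_FOR_CV:
        w, p = analysis.normality_test(analysis.isis(train))
        results["shapiro_w"], results["shapiro_p"] = w, p
    tables = {
        "isi_hist": pd.DataFrame({"bin_left_ms": hist_edges[:-1], "count": hist_counts}),
        "autocorr": pd.DataFrame({"lag_bin_left_ms": ac_edges[:-1], "count": ac_counts}),
    }
    return ExperimentReport(
        name=f"isolated_{cell_class.value.lower()}",
        settings={"duration_ms": duration_ms, "dt": dt, "drive_scale": drive_scale},
        seeds={"sim_seed": seed},
        results=results,
        tables=tables,
    )


def exp_network(
    duration_ms: float = 300_000.0,
    wiring_seed: int = 0,
    sim_seed: int = 0,
    config: Optional[NetworkConfig] = None,
    params: Optional[Mapping[CellClass, NeuronParams]] = None,
    dt: float = DT_MS,
) -> ExperimentReport:
    """The intact default microzone: per-class population statistics and the
    rate-CV rank correlation."""
    config = config if config is not None else NetworkConfig(seed=wiring_seed)
    if config.seed != wiring_seed:
        config = replace(config, seed=wiring_seed)
    net = build_network(config)
    settings = SimSettings(duration_ms=duration_ms, dt=dt, sim_seed=sim_seed)
    result = run_simulation(net, settings, params=params)

    results: Dict = {"n_neurons": net.n_neurons}
    tables: Dict[str, pd.DataFrame] = {"edges": net.to_frame()}
    for cls in (CellClass.MLI, CellClass.PKJ):
        ids = net.ids_of(cls)
        stats = analysis.population_stats(
            {i: result.train(i) for i in ids}, duration_ms
        )
        rho, p = analysis.rate_cv_correlation(stats)
        key = cls.value.lower()
        results[key] = {
            "rate": stats.rate,
            "cv": stats.cv,
            "spearman_rho": rho,
            "spearman_p": p,
        }
        tables[f"{key}_stats"] = stats.per_neuron
    return ExperimentReport(
        name="network",
        settings={"duration_ms": duration_ms, "dt": dt, "config": config.to_dict()},
        seeds={"wiring_seed": wiring_seed, "sim_seed": sim_seed},
        results=results,
        tables=tables,
    )


def _first_two_spikes(train: np.ndarray) -> Tuple[float, float]:
    if len(train) < 2:
        raise RuntimeError("trial window too short: fewer than two spikes")
    return float(train[0]), float(train[1])


def exp_feedforward(
    ipsc_peaks_ns: Sequence[float] = (0.0, 1.0, 2.0, 4.0, 8.0),
    n_trials: int = 500,
    mli_delay_ms: float = 12.0,
    seed: int = 0,
    detail_peak_ns: float = 4.0,
    window_ms: float = 1000.0,
    dt: float = DT_MS,
) -> ExperimentReport:
    """Feedforward-inhibition prolongation of the Purkinje ISI.

    Per trial the PKJ of a two-neuron motif runs until its second spike,
    once without and once with a single MLI spike forced ``mli_delay_ms``
    after the PKJ's first spike.  Control and inhibited runs of a trial
    share the same spontaneous-current stream (paired design), so the ISI
    difference isolates the synaptic effect.  The MLI never fires
    spontaneously (clamped in both runs).
    """
    peaks = list(ipsc_peaks_ns)
    if detail_peak_ns not in peaks:
        peaks.append(detail_peak_ns)
    trial_seeds = np.random.default_rng(seed).integers(2**31, size=n_trials)
    settings = [SimSettings(duration_ms=window_ms, dt=dt, sim_seed=int(s)) for s in trial_seeds]

    # control trajectories do not depend on the synaptic peak (MLI clamped,
    # never fires), so they are computed once per trial
    control_isi = np.empty(n_trials)
    first_spike = np.empty(n_trials)
    control_net = two_neuron_motif(0.0)
    for i, s in enumerate(settings):
        t1, t2 = _first_two_spikes(run_simulation(control_net, s, clamped_ids=(1,)).train(0))
        first_spike[i] = t1
        control_isi[i] = t2 - t1

    ffi_isi: Dict[float, np.ndarray] = {}
    for peak in peaks:
        net = two_neuron_motif(peak)
        out = np.empty(n_trials)
        for i, s in enumerate(settings):
            res = force_spike(net, s, neuron_id=1, t_fire_ms=first_spike[i] + mli_delay_ms)
            t1, t2 = _first_two_spikes(res.train(0))
            out[i] = t2 - t1
        ffi_isi[peak] = out

    mean_curve = [(p, float(np.mean(ffi_isi[p]))) for p in sorted(set(peaks))]
    slope, intercept, r, _, _ = sps.linregress(
        [p for p, _ in mean_curve], [m for _, m in mean_curve]
    )
    u, pval = analysis.compare_distributions(ffi_isi[detail_peak_ns], control_isi)
    results = {
        "n_trials": n_trials,
        "mli_delay_ms": mli_delay_ms,
        "control_mean_isi_ms": float(np.mean(control_isi)),
        "mean_isi_by_peak_ns": {str(p): m for p, m in mean_curve},
        "detail_peak_ns": detail_peak_ns,
        "detail_mean_isi_ms": float(np.mean(ffi_isi[detail_peak_ns])),
        "mannwhitney_u": u,
        "mannwhitney_p": pval,
        "isi_vs_peak_slope_ms_per_ns": float(slope),
        "isi_vs_peak_intercept_ms": float(intercept),
        "isi_vs_peak_r": float(r),
    }
    tables = {
        "trial_isis": pd.DataFrame(
            {"trial": np.arange(n_trials), "control_isi_ms": control_isi}
            | {f"ffi_{p}nS_isi_ms": ffi_isi[p] for p in sorted(set(peaks))}
        )
    }
    return ExperimentReport(
        name="feedforward",
        settings={
            "ipsc_peaks_ns": peaks,
            "window_ms": window_ms,
            "dt": dt,
            "mli_delay_ms": mli_delay_ms,
        },
        seeds={"seed": seed, "trial_seeds": trial_seeds.tolist()},
        results=results,
        tables=tables,
    )


def exp_pruning(
    conn_type: ConnectionType,
    fractions: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    duration_ms: float = 60_000.0,
    wiring_seed: int = 0,
    sim_seed: int = 0,
    prune_seed: int = 0,
    config: Optional[NetworkConfig] = None,
    dt: float = DT_MS,
) -> ExperimentReport:
    """Network statistics as a random subset of one connection type is removed.

    One wiring realization; independent prune draws per fraction; the same
    dynamics seed across conditions so the conditions differ only by wiring.
    """
    conn_type = ConnectionType(conn_type)
    config = config if config is not None else NetworkConfig(seed=wiring_seed)
    if config.seed != wiring_seed:
        config = replace(config, seed=wiring_seed)
    base = build_network(config)
    children = np.random.SeedSequence(prune_seed).spawn(len(fractions))

    per_class_rates: Dict[str, Dict[float, np.ndarray]] = {"mli": {}, "pkj": {}}
    condition_rows = []
    for frac, child in zip(fractions, children):
        net = prune_synapses(base, conn_type, frac, np.random.default_rng(child))
        settings = SimSettings(duration_ms=duration_ms, dt=dt, sim_seed=sim_seed)
        result = run_simulation(net, settings)
        for cls in (CellClass.MLI, CellClass.PKJ):
            ids = net.ids_of(cls)
            stats = analysis.population_stats({i: result.train(i) for i in ids}, duration_ms)
            key = cls.value.lower()
            per_class_rates[key][frac] = stats.per_neuron["rate_hz"].to_numpy()
            condition_rows.append(
                {
                    "fraction": frac,
                    "cell_class": cls.value,
                    "n_synapses_of_type": len(net.synapses_of(conn_type)),
                    **{f"rate_{k}": v for k, v in stats.rate.items()},
                    **{f"cv_{k}": v for k, v in stats.cv.items()},
                }
            )

    results: Dict = {"conn_type": conn_type.value, "fractions": list(fractions)}
    lo, hi = min(fractions), max(fractions)
    for key in ("mli", "pkj"):
        u, p = analysis.compare_distributions(
            per_class_rates[key][lo], per_class_rates[key][hi]
        )
        results[f"{key}_rate_mwu_u_intact_vs_pruned"] = u
        results[f"{key}_rate_mwu_p_intact_vs_pruned"] = p
    summary = pd.DataFrame(condition_rows)
    results["conditions"] = summary.to_dict(orient="records")
    return ExperimentReport(
        name=f"pruning_{conn_type.value.replace('->', '_to_').lower()}",
        settings={
            "duration_ms": duration_ms,
            "dt": dt,
            "fractions": list(fractions),
            "config": config.to_dict(),
        },
        seeds={"wiring_seed": wiring_seed, "sim_seed": sim_seed, "prune_seed": prune_seed},
        results=results,
        tables={"conditions": summary},
    )


@dataclass
class CalibrationResult:
    kappa: float
    beta: float
    achieved_rate_hz: float
    achieved_cv: float
    loss: float
    grid: pd.DataFrame


def calibrate_spont(
    cell_class: CellClass,
    target_rate_hz: float,
    target_cv: float,
    kappa_grid: Sequence[float],
    beta_grid: Sequence[float],
    duration_ms: float = 60_000.0,
    seed: int = 0,
    dt: float = DT_MS,
) -> CalibrationResult:
    """Exhaustive grid search over the gamma-drive parameters.

    Every (kappa, beta) point is simulated in isolation with the same
    dynamics seed; the loss is the sum of relative errors of the achieved
    rate and CV against the targets.  Ties break toward smaller kappa, then
    smaller beta.  A point that fires too rarely for a defined CV gets
    infinite loss.
    """
    base = DEFAULT_PARAMS[cell_class]
    rows = []
    for kappa in kappa_grid:
        for beta in beta_grid:
            p = base.with_updates(kappa=float(kappa), beta=float(beta))
            rep = exp_isolated(
                cell_class, duration_ms=duration_ms, seed=seed, dt=dt,
                params={cell_class: p},
            )
            rate, cv = rep.results["rate_hz"], rep.results["isi_cv"]
            if math.isnan(cv) or rate == 0:
                loss = math.inf
            else:
                loss = abs(rate - target_rate_hz) / target_rate_hz + abs(cv - target_cv) / target_cv
            rows.append({"kappa": float(kappa), "beta": float(beta),
                         "rate_hz": rate, "isi_cv": cv, "loss": loss})
    grid = pd.DataFrame(rows)
    best = grid.sort_values(["loss", "kappa", "beta"], kind="mergesort").iloc[0]
    return CalibrationResult(
        kappa=float(best.kappa),
        beta=float(best.beta),
        achieved_rate_hz=float(best.rate_hz),
        achieved_cv=float(best.isi_cv),
        loss=float(best.loss),
        grid=grid,
    )


def _perturbed_params(params: NeuronParams, fraction: float, rng: np.random.Generator) -> NeuronParams:
    fields = {}
    for f in dataclasses.fields(params):
        val = getattr(params, f.name)
        if isinstance(val, float):
            fields[f.name] = val * (1.0 + rng.uniform(-fraction, fraction))
    return params.with_updates(**fields)


def exp_robustness(
    n_instantiations: int = 5,
    perturb_fraction: float = 0.10,
    duration_ms: float = 60_000.0,
    seed: int = 0,
    config: Optional[NetworkConfig] = None,
    dt: float = DT_MS,
) -> ExperimentReport:
    """Consistency across network re-instantiations and tolerance to random
    ±``perturb_fraction`` scaling of every neuron parameter and weight bound."""
    config = config if config is not None else NetworkConfig()
    rng = np.random.default_rng(seed)
    inst_seeds = rng.integers(2**31, size=(n_instantiations, 2))

    inst_rows = []
    for w, s in inst_seeds:
        rep = exp_network(
            duration_ms=duration_ms, wiring_seed=int(w), sim_seed=int(s),
            config=config, dt=dt,
        )
        inst_rows.append(
            {
                "wiring_seed": int(w),
                "sim_seed": int(s),
                "mli_rate_mean": rep.results["mli"]["rate"]["mean"],
                "mli_cv_mean": rep.results["mli"]["cv"]["mean"],
                "pkj_rate_mean": rep.results["pkj"]["rate"]["mean"],
                "pkj_cv_mean": rep.results["pkj"]["cv"]["mean"],
            }
        )
    inst = pd.DataFrame(inst_rows)
    spread = {
        col: float(inst[col].max() - inst[col].min())
        for col in ("mli_rate_mean", "mli_cv_mean", "pkj_rate_mean", "pkj_cv_mean")
    }

    perturbed = {
        cls: _perturbed_params(DEFAULT_PARAMS[cls], perturb_fraction, rng)
        for cls in (CellClass.PKJ, CellClass.MLI)
    }
    bounds = {
        ct: (lo * (1.0 + rng.uniform(-perturb_fraction, perturb_fraction)),
             hi * (1.0 + rng.uniform(-perturb_fraction, perturb_fraction)))
        for ct, (lo, hi) in config.weight_bounds.items()
    }
    p_config = replace(config, weight_bounds=bounds, seed=int(inst_seeds[0][0]))
    net = build_network(p_config)
    result = run_simulation(
        net, SimSettings(duration_ms=duration_ms, dt=dt, sim_seed=int(inst_seeds[0][1])),
        params=perturbed,
    )
    perturbed_stats = {}
    for cls in (CellClass.MLI, CellClass.PKJ):
        stats = analysis.population_stats(
            {i: result.train(i) for i in net.ids_of(cls)}, duration_ms
        )
        perturbed_stats[cls.value.lower()] = {"rate": stats.rate, "cv": stats.cv}
    pkj_rates = [
        analysis.mean_rate(result.train(i), duration_ms) for i in net.ids_of(CellClass.PKJ)
    ]
    results = {
        "instantiation_spread": spread,
        "instantiations": inst.to_dict(orient="records"),
        "perturb_fraction": perturb_fraction,
        "perturbed": perturbed_stats,
        "perturbed_min_pkj_rate_hz": float(min(pkj_rates)),
        "all_pkj_active_after_perturbation": bool(min(pkj_rates) > 0),
    }
    return ExperimentReport(
        name="robustness",
        settings={
            "duration_ms": duration_ms,
            "dt": dt,
            "n_instantiations": n_instantiations,
            "config": config.to_dict(),
        },
        seeds={"seed": seed, "instantiation_seeds": inst_seeds.tolist()},
        results=results,
        tables={"instantiations": inst},
    )
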