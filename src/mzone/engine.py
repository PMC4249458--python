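"""Whole-network simulation: fixed-step Euler integration with zero-delay
inhibitory transmission.

Two independent random streams govern a run: the wiring seed (inside
:class:`~mzone.network.NetworkConfig`) and the dynamics seed
(``SimSettings.sim_seed``).  Spontaneous currents are drawn per step for all
neurons in fixed id order, so results are bit-reproducible regardless of how
the integrator is chunked internally.

Spike times are recorded as ``k*dt`` where ``k`` is the step whose
post-update membrane potential crossed threshold.  Spikes emitted at step
``k`` first affect their targets' membrane update at step ``k+1``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .neuron import (
    CellClass,
    NeuronParams,
    DEFAULT_PARAMS,
    DT_MS,
    NA_TO_PA,
    ParameterError,
)
from .network import Network

__all__ = ["SimSettings", "SimResult", "SimulationError", "run_simulation", "force_spike"]

_CHUNK_STEPS = 16000


class SimulationError(RuntimeError):
    """Numerical failure (NaN / divergent state) during integration."""


@dataclass(frozen=True)
class SimSettings:
    """Duration, step size, dynamics seed and voltage-recording options."""

    duration_ms: float
    dt: float = DT_MS
    sim_seed: int = 0
    record_voltage_ids: Tuple[int, ...] = ()
    voltage_sample_stride: int = 1

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ParameterError("dt must be positive")
        if self.duration_ms < self.dt:
            raise ParameterError("duration must be at least one step")
        if self.voltage_sample_stride < 1:
            raise ParameterError("voltage_sample_stride must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_ms / self.dt))


@dataclass
class SimResult:
    """Spike trains (sorted, ms) per neuron, optional voltage traces, and the
    full provenance (network config, settings) needed to re-run exactly."""

    spike_times: Dict[int, np.ndarray]
    settings: SimSettings
    network_config: dict
    cell_class: Dict[int, CellClass]
    voltages: Dict[int, np.ndarray] = field(default_factory=dict)
    voltage_times: Optional[np.ndarray] = None

    def train(self, neuron_id: int) -> np.ndarray:
        return self.spike_times[neuron_id]

    def ids_of(self, cls: CellClass) -> list:
        return [i for i, c in self.cell_class.items() if c is cls]

    def n_spikes(self) -> int:
        return sum(len(t) for t in self.spike_times.values())

    def to_frame(self) -> pd.DataFrame:
        """Long-format spike table sorted by time then neuron id."""
        rows = [
            (i, t)
            for i, train in self.spike_times.items()
            for t in train
        ]
        df = pd.DataFrame(rows, columns=["neuron_id", "time_ms"])
        return df.sort_values(["time_ms", "neuron_id"], kind="mergesort").reset_index(drop=True)

    def save(self, csv_path: str | Path) -> None:
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        meta = {
            "settings": {
                **asdict(self.settings),
                "record_voltage_ids": list(self.settings.record_voltage_ids),
            },
            "network_config": self.network_config,
            "cell_class": {str(i): c.value for i, c in self.cell_class.items()},
        }
        csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, csv_path: str | Path) -> "SimResult":
        csv_path = Path(csv_path)
        meta = json.loads(csv_path.with_suffix(".json").read_text())
        s = meta["settings"]
        s["record_voltage_ids"] = tuple(s["record_voltage_ids"])
        settings = SimSettings(**s)
        cell_class = {int(i): CellClass(v) for i, v in meta["cell_class"].items()}
        df = pd.read_csv(csv_path, float_precision="round_trip")
        trains: Dict[int, np.ndarray] = {i: np.empty(0) for i in cell_class}
        for i, grp in df.groupby("neuron_id"):
            t = grp["time_ms"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"spike times of neuron {i} are not strictly increasing")
            trains[int(i)] = t
        return cls(
            spike_times=trains,
            settings=settings,
            network_config=meta["network_config"],
            cell_class=cell_class,
        )


def _param_arrays(net: Network, params: Mapping[CellClass, NeuronParams]):
    n = net.n_neurons
    keys = (
        "g_leak", "e_leak", "c_m", "v_threshold", "g_ahp_peak", "e_ahp",
        "tau_ahp", "e_gaba", "tau_gaba", "g_gaba_peak", "kappa", "beta",
    )
    arrs = {k: np.empty(n) for k in keys}
    for neuron in net.neurons:
        p = params[neuron.cell_class]
        for k in keys:
            arrs[k][neuron.id] = getattr(p, k)
    return arrs


def run_simulation(
    net: Network,
    settings: SimSettings,
    params: Optional[Mapping[CellClass, NeuronParams]] = None,
    forced_spikes: Sequence[Tuple[int, float]] = (),
    clamped_ids: Iterable[int] = (),
    current_scale: float = 1.0,
) -> SimResult:
    """Simulate the network.  Deterministic given (wiring seed, sim_seed).

    Parameters
    ----------
    params
        Per-class neuron parameters; defaults to the standard PKJ/MLI sets.
    forced_spikes
        ``(neuron_id, t_ms)`` pairs: the neuron is made to spike at the step
        nearest ``t_ms`` (delivered with the usual one-step causality).
    clamped_ids
        Neurons excluded from spontaneous spiking.  Their current draws are
        still consumed, so clamping one neuron leaves every other neuron's
        random stream untouched.
    current_scale
        Multiplier on all spontaneous currents (1 = nominal; 0 silences the
        endogenous drive entirely).
    """
    from . import _kernel

    params = dict(params) if params is not None else dict(DEFAULT_PARAMS)
    n = net.n_neurons
    dt = settings.dt
    n_steps = settings.n_steps
    arrs = _param_arrays(net, params)
    gaba_decay = np.array([math.exp(-dt / tau) for tau in arrs["tau_gaba"]])

    # CSR adjacency by source id; delivered increment is weight * peak(target)
    order = sorted(range(len(net.synapses)), key=lambda i: (net.synapses[i].source, i))
    counts = np.zeros(n, dtype=np.int64)
    for s in net.synapses:
        counts[s.source] += 1
    syn_indptr = np.concatenate([[0], np.cumsum(counts)])
    syn_targets = np.array(
        [net.synapses[i].target for i in order], dtype=np.int64
    )
    syn_dg = np.array(
        [
            arrs["g_gaba_peak"][net.synapses[i].target] * net.synapses[i].weight
            for i in order
        ]
    )

    clamped = np.zeros(n, dtype=np.bool_)
    for i in clamped_ids:
        if not 0 <= i < n:
            raise ParameterError(f"neuron id {i} not in network")
        clamped[i] = True
    fs = sorted(
        ((int(round(t / dt)), nid) for nid, t in forced_spikes), key=lambda x: x[0]
    )
    for k, nid in fs:
        if not 0 <= nid < n:
            raise ParameterError(f"neuron id {nid} not in network")
        if not 0 <= k < n_steps:
            raise ParameterError(f"forced spike time outside the simulation window")
    forced_steps = np.array([k for k, _ in fs], dtype=np.int64)
    forced_ids = np.array([nid for _, nid in fs], dtype=np.int64)

    rec_ids = np.array(sorted(settings.record_voltage_ids), dtype=np.int64)
    stride = settings.voltage_sample_stride
    n_rec_rows = (n_steps + stride - 1) // stride if len(rec_ids) else 0
    rec_out = np.empty((n_rec_rows, len(rec_ids)))

    rng = np.random.default_rng(settings.sim_seed)
    v = arrs["e_leak"].copy()
    g = np.zeros(n)
    last_step = np.full(n, -1, dtype=np.int64)
    has_spiked = np.zeros(n, dtype=np.bool_)
    pending = np.zeros(n, dtype=np.bool_)

    all_steps: list = []
    all_ids: list = []
    forced_ptr = 0
    rec_row = 0
    for step0 in range(0, n_steps, _CHUNK_STEPS):
        m = min(_CHUNK_STEPS, n_steps - step0)
        i_pa = rng.gamma(arrs["kappa"], arrs["beta"], size=(m, n)) * NA_TO_PA
        if current_scale != 1.0:
            i_pa *= current_scale
        cap = m * n + len(forced_steps)
        spike_steps = np.empty(cap, dtype=np.int32)
        spike_ids = np.empty(cap, dtype=np.int32)
        nsp, forced_ptr, rec_row = _kernel.run_chunk(
            v, g, last_step, has_spiked, pending, i_pa,
            np.int64(step0), float(dt),
            arrs["g_leak"], arrs["e_leak"], arrs["c_m"], arrs["v_threshold"],
            arrs["g_ahp_peak"], arrs["e_ahp"], arrs["tau_ahp"], arrs["e_gaba"],
            gaba_decay,
            syn_indptr, syn_targets, syn_dg,
            clamped, forced_steps, forced_ids, np.int64(forced_ptr),
            rec_ids, np.int64(stride), rec_out, np.int64(rec_row),
            spike_steps, spike_ids,
        )
        if not np.all(np.isfinite(v)):
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise SimulationError(
                f"non-finite membrane potential for neuron {bad} "
                f"by step {step0 + m}"
            )
        all_steps.append(spike_steps[:nsp].copy())
        all_ids.append(spike_ids[:nsp].copy())

    steps = np.concatenate(all_steps) if all_steps else np.empty(0, dtype=np.int32)
    ids = np.concatenate(all_ids) if all_ids else np.empty(0, dtype=np.int32)
    trains: Dict[int, np.ndarray] = {}
    for neuron in net.neurons:
        trains[neuron.id] = np.sort(steps[ids == neuron.id]).astype(np.float64) * dt

    voltages = {int(nid): rec_out[:, r].copy() for r, nid in enumerate(rec_ids)}
    voltage_times = (
        np.arange(n_rec_rows) * stride * dt if len(rec_ids) else None
    )
    return SimResult(
        spike_times=trains,
        settings=settings,
        network_config=net.config.to_dict(),
        cell_class={nr.id: nr.cell_class for nr in net.neurons},
        voltages=voltages,
        voltage_times=voltage_times,
    )


def force_spike(
    net: Network,
    settings: SimSettings,
    neuron_id: int,
    t_fire_ms: float,
    params: Optional[Mapping[CellClass, NeuronParams]] = None,
) -> SimResult:
    """Run the network with one neuron clamped non-spontaneous and made to
    emit exactly one spike at ``t_fire_ms``."""
    return run_simulation(
        net,
        settings,
        params=params,
        forced_spikes=[(neuron_id, t_fire_ms)],
        clamped_ids=(neuron_id,),
    )
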