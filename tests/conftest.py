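"""Shared fixtures and the scalar reference integrator.

The reference integrator below advances a network with plain Python floats
through the public single-neuron operations, following the documented step
discipline (decay, deliver previous step's spikes in source-id order, draw
currents in id order, Euler update).  It is deliberately independent of the
compiled engine and serves as its oracle on small networks.
"""

from __future__ import annotations

import numpy as np
import pytest

from mzone.neuron import (
    CellClass,
    NeuronState,
    DEFAULT_PARAMS,
    draw_spont_current,
    step_neuron,
    decay_gaba_trace,
    receive_spike,
)


@pytest.fixture
def pkj_params():
    return DEFAULT_PARAMS[CellClass.PKJ]


@pytest.fixture
def mli_params():
    return DEFAULT_PARAMS[CellClass.MLI]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def reference_simulation(
    net,
    n_steps: int,
    dt: float,
    sim_seed: int,
    params=None,
    clamped=(),
    forced=(),
):
    """Scalar-arithmetic network integration via the single-neuron operations.

    ``forced`` is a sequence of ``(neuron_id, step_index)`` pairs.  Returns a
    dict of spike-time arrays (ms) keyed by neuron id.
    """
    params = dict(params) if params is not None else dict(DEFAULT_PARAMS)
    p_of = {nr.id: params[nr.cell_class] for nr in net.neurons}
    n = net.n_neurons
    rng = np.random.default_rng(sim_seed)
    states = {i: NeuronState.resting(p_of[i]) for i in range(n)}
    # synapses grouped by source in the engine's delivery order
    by_source = {i: [] for i in range(n)}
    for s in sorted(net.synapses, key=lambda s: s.source):
        by_source[s.source].append(s)
    forced_by_step = {}
    for nid, k in forced:
        forced_by_step.setdefault(k, []).append(nid)
    clamped = set(clamped)
    pending = []
    spikes = {i: [] for i in range(n)}
    for k in range(n_steps):
        for i in range(n):
            states[i] = decay_gaba_trace(states[i], p_of[i], dt)
        for src in sorted(pending):
            for syn in by_source[src]:
                states[syn.target] = receive_spike(states[syn.target], p_of[syn.target], syn.weight)
        pending = []
        draws = [draw_spont_current(p_of[i], rng) for i in range(n)]
        for i in range(n):
            new = step_neuron(states[i], p_of[i], draws[i], dt, now_ms=k * dt)
            if new.spiked_this_step and i in clamped:
                new = NeuronState(
                    v=new.v,
                    g_gaba_trace=new.g_gaba_trace,
                    t_last_spike=states[i].t_last_spike,
                    spiked_this_step=False,
                )
            states[i] = new
            if states[i].spiked_this_step:
                pending.append(i)
                spikes[i].append(k * dt)
        for nid in forced_by_step.get(k, []):
            if nid not in pending:
                states[nid] = NeuronState(
                    v=states[nid].v, g_gaba_trace=states[nid].g_gaba_trace,
                    t_last_spike=k * dt, spiked_this_step=True,
                )
                pending.append(nid)
                spikes[nid].append(k * dt)
    return {i: np.array(t) for i, t in spikes.items()}
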