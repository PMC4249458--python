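"""Compiled inner loop of the fixed-step network integrator.

The kernel advances all neurons over a chunk of steps.  Per step ``k`` (state
at time ``k*dt``):

1. every GABA trace is multiplied by its per-neuron decay factor
   ``exp(-dt/tau_gaba)``;
2. spikes emitted at step ``k-1`` are delivered (sources in ascending id
   order), incrementing target traces by ``weight * g_gaba_peak(target)`` —
   zero transmission delay, one-step causality: the increment first affects
   the membrane update of this step, undecayed;
3. forward-Euler membrane update with the pre-drawn spontaneous current;
   a neuron whose post-update potential reaches threshold spikes, its spike
   time recorded as ``k*dt`` and its AHP restarted from the peak;
4. forced spikes scheduled for step ``k`` are registered the same way.

Everything is scalar arithmetic in a fixed id order, so results are
bit-reproducible and independent of vectorization.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def run_chunk(
    v,  # float64[n]  membrane potentials, mV (updated in place)
    g,  # float64[n]  GABA conductance traces, nS (in place)
    last_step,  # int64[n]  step index of most recent spike (in place)
    has_spiked,  # bool[n]  whether the neuron ever spiked (in place)
    pending,  # bool[n]  spikes of the step before this chunk (in place)
    i_pa,  # float64[m, n]  spontaneous currents, pA
    step0,  # int64  absolute index of the chunk's first step
    dt,  # float64  ms
    g_leak, e_leak, c_m, v_th,  # float64[n]
    g_ahp, e_ahp, tau_ahp, e_gaba,  # float64[n]
    gaba_decay,  # float64[n]  exp(-dt/tau_gaba)
    syn_indptr,  # int64[n+1]  CSR over source ids
    syn_targets,  # int64[nsyn]
    syn_dg,  # float64[nsyn]  weight * g_gaba_peak(target), nS
    clamped,  # bool[n]  excluded from spontaneous spiking
    forced_steps,  # int64[nf]  ascending absolute step indices
    forced_ids,  # int64[nf]
    forced_ptr,  # int64  first not-yet-delivered forced spike
    rec_ids,  # int64[nrec]  neurons with voltage recording
    rec_stride,  # int64  record every rec_stride-th step
    rec_out,  # float64[rows, nrec]
    rec_row,  # int64  next row to write
    spike_steps,  # int32[cap]  output buffer
    spike_ids,  # int32[cap]
):
    n = v.shape[0]
    m = i_pa.shape[0]
    nsp = 0
    for j in range(m):
        k = step0 + j
        for i in range(n):
            g[i] *= gaba_decay[i]
        for s in range(n):
            if pending[s]:
                pending[s] = False
                for p in range(syn_indptr[s], syn_indptr[s + 1]):
                    g[syn_targets[p]] += syn_dg[p]
        for i in range(n):
            vi = v[i]
            if has_spiked[i]:
                gahp_term = g_ahp[i] * math.exp(-((k - last_step[i]) * dt) / tau_ahp[i])
            else:
                gahp_term = 0.0
            total = (
                -g_leak[i] * (vi - e_leak[i])
                - gahp_term * (vi - e_ahp[i])
                - g[i] * (vi - e_gaba[i])
                + i_pa[j, i]
            )
            vi = vi + dt * (total / c_m[i])
            v[i] = vi
            if vi >= v_th[i] and not clamped[i]:
                last_step[i] = k
                has_spiked[i] = True
                pending[i] = True
                spike_steps[nsp] = k
                spike_ids[nsp] = i
                nsp += 1
        while forced_ptr < forced_steps.shape[0] and forced_steps[forced_ptr] == k:
            fid = forced_ids[forced_ptr]
            if not pending[fid]:  # avoid double-count if it already spiked now
                last_step[fid] = k
                has_spiked[fid] = True
                pending[fid] = True
                spike_steps[nsp] = k
                spike_ids[nsp] = fid
                nsp += 1
            forced_ptr += 1
        if rec_ids.shape[0] > 0 and k % rec_stride == 0:
            for r in range(rec_ids.shape[0]):
                rec_out[rec_row, r] = v[rec_ids[r]]
            rec_row += 1
    return nsp, forced_ptr, rec_row
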