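# Methods

## Neuron model

Each cell is a conductance-based leaky integrate-and-fire neuron:

```
C dV/dt = −g_leak (V − E_leak)
          − ḡ_AHP exp(−(t − t_spike)/τ_AHP) (V − E_AHP)
          − g_GABA(t) (V − E_GABA)
          + I_spont(t)
```

* **Units.** V in mV, t in ms, conductances in nS, capacitance in pF,
  currents in pA.  `I_spont` is drawn in nA and converted (×1000) to pA, so
  every right-hand-side term is in pA and `dt/C · (pA)` is in mV.
* **Spiking.** A spike is registered when the post-update membrane
  potential reaches threshold (`V ≥ V_th`).  There is **no hard reset**:
  repolarization is produced entirely by the after-hyperpolarization (AHP)
  conductance, which restarts (does not summate) from the most recent
  spike.
* **Spontaneous drive.** `I_spont ~ Gamma(κ, β)` (shape κ, scale β in nA),
  drawn fresh on every time step for every neuron.  Because a new
  independent draw is applied each step, the effective noise bandwidth is
  tied to the step size: **dt = 0.25 ms is a model constant**, not a mere
  numerical parameter, and κ/β are calibrated at that dt (see
  Calibration).
* **Inhibition.** Each presynaptic spike increments the target's GABA
  conductance by `weight × ḡ_GABA(target)`; between spikes the conductance
  decays exactly as `g(t+dt) = g(t)·exp(−dt/τ_GABA)`, i.e. the trace equals
  the closed-form sum `ḡ_GABA Σ_i w_i exp(−(t−t_i)/τ_GABA)` over all past
  presynaptic spikes.

### Parameters

| parameter | PKJ | MLI | units |
|---|---|---|---|
| V_th | −55 | −53 | mV |
| C | 107 | 14.6 | pF |
| g_leak | 2.32 | 1.6 | nS |
| E_leak | −68 | −68 | mV |
| ḡ_GABA | 1.0 | 4.0 | nS |
| E_GABA | −75 | −82 | mV |
| τ_GABA | 10 | 4.6 | ms |
| ḡ_AHP | 100 | 50 | nS |
| E_AHP | −70 | −82 | mV |
| τ_AHP | 2.5 | 2.5 | ms |
| κ | 0.430303 | 3.966333 | — |
| β | 0.195962 | 0.006653 | nA |

## Network

The circuit is a 1-D parasagittal strip: 16 PKJs at 64 µm spacing, each
with a "territory" of 10 MLIs, of which the first 3 sit in the lower
molecular layer (the only cells eligible for Purkinje recurrent
collaterals).  Axons are strictly one-directional along the strip:

* an MLI's axon points left or right (equal probability) and reaches every
  PKJ and MLI within 8 territories on that side;
* a PKJ collateral points left or right and reaches the lower-ML MLIs of
  the 2 nearest territories on that side;
* no PKJ→PKJ synapses, no autapses, at most one synapse per ordered pair.

Synapse formation is Bernoulli per (source, candidate) pair.  The default
connection probabilities are **derived from the anatomical wiring targets**
— on average each MLI contacts 2 PKJs (so 20 MLIs converge on a PKJ), each
MLI receives 4 MLI inputs, and each PKJ contacts 3 lower-ML MLIs — by
dividing each target by the *mean realized candidate count on the finite
strip*:

```
p = target / E[candidates],   E[candidates] = mean over sources of
                              (min(span, left) + min(span, right)) / 2 × cells per territory
```

For the default geometry this gives p(MLI→PKJ) = 2/5.75 ≈ 0.348,
p(MLI→MLI) = 4/57.5 ≈ 0.070, p(PKJ→MLI) = 3/5.4375 ≈ 0.552.  The
truncation-blind ratios (0.25, 0.05, 0.5) — targets divided by the full
one-side candidate counts, as if the strip were unbounded — are available
via `derive_probabilities(cfg, boundary_correction=False)`; they
under-produce synapses on a finite strip because edge neurons have fewer
candidates.  With the corrected defaults the *population mean*
convergence/divergence matches 20/4/3 by construction (verified within
binomial standard error over 200 seeds in the test suite), although
individual edge neurons still receive fewer contacts than central ones.

Synaptic weights are uniform per connection type: MLI→MLI ~ U(0, 1),
MLI→PKJ ~ U(0, 1.25), PKJ→MLI ~ U(0, 1).

## Numerical integration

Forward Euler with dt = 0.25 ms.  Per step *k* (exact order, which the
compiled kernel and the scalar reference implementation in the test suite
both follow):

1. decay every GABA trace by `exp(−dt/τ_GABA)`;
2. deliver the spikes emitted at step *k−1*, iterating sources in id order
   (one-step transmission, zero modeled axonal delay beyond it);
3. draw each neuron's spontaneous current (id order) and apply the Euler
   update, with the AHP factor evaluated at the elapsed time
   `(k − k_last_spike)·dt`; test threshold after the update and record a
   spike at time `k·dt`.

Determinism: a wiring seed fixes the network (direction draws, Bernoulli
draws, weight draws consumed in one documented sequence from a single
`numpy` Generator) and a dynamics seed fixes the currents (drawn per step
in neuron-id order).  The engine pre-draws currents in chunks; chunking is
bit-invariant, and the compiled kernel is verified spike-for-spike against
the scalar reference integrator.

Experiment utilities: a neuron can be *clamped* (its threshold crossings
suppressed while its random draws are still consumed, so other neurons'
streams are untouched) and *forced* to spike at a chosen step — together
these implement the controlled single-IPSC protocol.

## Statistics

* **Mean rate**: spike count / duration.
* **ISI CV**: sample SD (N−1) over mean of the inter-spike intervals;
  undefined (NaN) below 3 spikes.
* **Rate–CV association**: Spearman rank correlation over neurons with a
  defined CV (scipy, average ranks on ties).
* **Distribution comparisons**: two-sided Mann–Whitney U.
* **Normality**: Shapiro–Wilk; samples above 5000 are subsampled with a
  fixed seed to stay inside the test's validated range.
* **Autocorrelogram**: counts of ordered spike-pair lags in (0, 100] ms,
  1 ms right-closed bins.

## Experiments

* **Isolated** (300 s): one neuron, no synapses.
* **Network** (300 s): default 176-neuron strip; per-class population
  statistics and the rate–CV correlation.
* **Feedforward inhibition**: two-neuron MLI→PKJ motif; per trial, the PKJ
  runs to its second spike once without and once with a single forced MLI
  spike 12 ms after the PKJ's first spike.  Control and inhibited runs of
  a trial share the same current stream (paired design); the MLI is
  clamped in both.  Peak IPSC conductances 0–8 nS.
* **Pruning**: one wiring realization; a random fraction (0–100%) of one
  connection type removed per condition with independent prune draws; the
  same dynamics seed across conditions, 60 s each.
* **Calibration**: exhaustive (κ, β) grid; loss = sum of relative errors of
  achieved isolated rate and CV against targets; ties break toward smaller
  κ then β.
* **Robustness**: spread of population statistics across independent
  re-instantiations, and a run with every neuron parameter and weight
  bound scaled by independent U(−10%, +10%) factors.

## Limitations and assumptions

* The endogenous drive is phenomenological: a memoryless gamma current
  stands in for intrinsic pacemaker conductances and background synaptic
  bombardment; its statistics are dt-bound (changing dt without
  recalibrating κ/β changes the firing statistics).
* No excitatory inputs (granule-cell/parallel-fiber and climbing-fiber
  pathways are outside scope); all interaction is GABAergic.
* 1-D geometry with hard territory boundaries; real sagittal axons have
  graded, distance-dependent contact probabilities.
* Single-compartment neurons: no dendritic processing, no gap junctions
  between interneurons, no short-term synaptic plasticity.
* Zero transmission delay beyond the one-step (0.25 ms) update latency.
* Forward Euler at fixed dt: spike times are quantized to the step grid;
  threshold crossings within a step are detected only at its end.
* Population means over the finite strip include under-connected edge
  neurons; the connection probabilities compensate on average but not per
  neuron.
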