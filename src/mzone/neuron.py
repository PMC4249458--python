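"""Single-neuron model: conductance-based leaky integrate-and-fire with
stochastic spontaneous drive.

Both cerebellar cell classes modeled here — Purkinje cells (PKJ) and
molecular layer interneurons (MLI, one homogeneous stellate/basket class) —
fire spontaneously without excitatory synaptic input.  The spontaneous drive
is an endogenous depolarizing current drawn independently every time step
from a gamma distribution ``I_spont ~ Gamma(kappa, beta)`` (shape, scale; in
nA), whose strictly non-negative support and flexible shape make it a
convenient stand-in for the TTX-sensitive sodium current underlying
spontaneous firing in these cells.

Membrane dynamics (forward Euler, fixed step):

    C dV/dt = -g_leak (V - E_leak)
              - g_ahp_peak * exp(-(t - t_spiked)/tau_ahp) * (V - E_ahp)
              - g_gaba(t) * (V - E_gaba)
              + I_spont(t)

There is no hard post-spike reset: when ``V`` crosses ``V_threshold`` a spike
is emitted and the after-hyperpolarization (AHP) conductance restarts from
its peak, pulling the membrane back toward ``E_ahp`` within a millisecond or
so.  The AHP depends only on the most recent spike.  Inhibitory (GABA-A)
input enters through a single exponentially decaying conductance trace that
is incremented by ``g_gaba_peak * w`` on each presynaptic spike.

Unit system: mV, ms, nS, pF.  Then conductance x voltage is in pA and
``C dV/dt`` is in pA, so the spontaneous current (specified in nA) is scaled
by 1000 inside the update.

Because a fresh current sample is drawn every step, the statistics of the
drive depend on the step size; ``dt`` = 0.25 ms is therefore a model
constant, not a free numerical knob.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace, asdict
from typing import Optional

import numpy as np

__all__ = [
    "CellClass",
    "NeuronParams",
    "NeuronState",
    "PKJ_PARAMS",
    "MLI_PARAMS",
    "DT_MS",
    "NA_TO_PA",
    "draw_spont_current",
    "ahp_factor",
    "membrane_derivative",
    "step_neuron",
    "decay_gaba_trace",
    "receive_spike",
]

#: Model integration step (ms).  Part of the model definition: the per-step
#: gamma current makes the effective noise level dt-dependent.
DT_MS: float = 0.25

NA_TO_PA: float = 1000.0


class CellClass(str, enum.Enum):
    """The two modeled cell classes of the molecular layer circuit."""

    PKJ = "PKJ"
    MLI = "MLI"


class ParameterError(ValueError):
    """Invalid neuron / network parameter."""


@dataclass(frozen=True)
class NeuronParams:
    """Electrical and stochastic-drive constants for one cell class.

    All voltages in mV, conductances in nS, capacitance in pF, time constants
    in ms.  ``kappa`` (shape, dimensionless) and ``beta`` (scale, nA)
    parameterize the per-step gamma-distributed spontaneous current.
    ``g_gaba_peak`` is the peak inhibitory conductance of a unit-weight
    synapse onto this cell class; ``g_ahp_peak`` the peak of the
    spike-triggered AHP conductance.
    """

    cell_class: CellClass
    v_threshold: float
    c_m: float
    g_leak: float
    e_leak: float
    g_gaba_peak: float
    e_gaba: float
    tau_gaba: float
    g_ahp_peak: float
    e_ahp: float
    tau_ahp: float
    kappa: float
    beta: float

    def __post_init__(self) -> None:
        if self.c_m <= 0:
            raise ParameterError("membrane capacitance must be positive")
        for name in ("g_leak", "g_gaba_peak", "g_ahp_peak"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        for name in ("tau_gaba", "tau_ahp"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not self.e_gaba < self.v_threshold:
            raise ParameterError("E_GABA must lie below V_threshold")
        if not self.e_ahp < self.v_threshold:
            raise ParameterError("E_AHP must lie below V_threshold")
        if self.kappa <= 0 or self.beta <= 0:
            raise ParameterError("gamma shape and scale must be positive")

    def with_updates(self, **kwargs) -> "NeuronParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cell_class"] = self.cell_class.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronParams":
        d = dict(d)
        d["cell_class"] = CellClass(d["cell_class"])
        return cls(**d)


#: Default Purkinje-cell parameters.
PKJ_PARAMS = NeuronParams(
    cell_class=CellClass.PKJ,
    v_threshold=-55.0,
    c_m=107.0,
    g_leak=2.32,
    e_leak=-68.0,
    g_gaba_peak=1.0,
    e_gaba=-75.0,
    tau_gaba=10.0,
    g_ahp_peak=100.0,
    e_ahp=-70.0,
    tau_ahp=2.5,
    kappa=0.430303,
    beta=0.195962,
)

#: Default molecular-layer-interneuron parameters.
MLI_PARAMS = NeuronParams(
    cell_class=CellClass.MLI,
    v_threshold=-53.0,
    c_m=14.6,
    g_leak=1.6,
    e_leak=-68.0,
    g_gaba_peak=4.0,
    e_gaba=-82.0,
    tau_gaba=4.6,
    g_ahp_peak=50.0,
    e_ahp=-82.0,
    tau_ahp=2.5,
    kappa=3.966333,
    beta=0.006653,
)

DEFAULT_PARAMS = {CellClass.PKJ: PKJ_PARAMS, CellClass.MLI: MLI_PARAMS}


@dataclass
class NeuronState:
    """Dynamic variables of one neuron.

    ``t_last_spike`` is ``None`` until the first spike; afterwards it holds
    the (non-decreasing) time of the most recent spike in ms.
    """

    v: float
    g_gaba_trace: float = 0.0
    t_last_spike: Optional[float] = None
    spiked_this_step: bool = field(default=False, compare=False)

    @classmethod
    def resting(cls, params: NeuronParams) -> "NeuronState":
        """Initial condition: membrane at leak reversal, no conductances."""
        return cls(v=params.e_leak)


def draw_spont_current(params: NeuronParams, rng: np.random.Generator) -> float:
    """Draw one spontaneous depolarizing current sample (nA).

    An i.i.d. ``Gamma(kappa, beta)`` draw; a fresh sample is taken every
    integration step of a simulation.
    """
    return float(rng.gamma(params.kappa, params.beta))


def ahp_factor(params: NeuronParams, elapsed_ms: float) -> float:
    """Dimensionless AHP kinetics ``exp(-elapsed/tau_ahp)``.

    At the spike itself (``elapsed_ms == 0``) the factor is 1, so the AHP
    conductance starts at its peak ``g_ahp_peak``.
    """
    return math.exp(-elapsed_ms / params.tau_ahp)


def membrane_derivative(
    state: NeuronState, params: NeuronParams, i_spont_na: float, now_ms: float
) -> float:
    """dV/dt in mV/ms at time ``now_ms`` given the current state."""
    if state.t_last_spike is None:
        g_ahp = 0.0
    else:
        g_ahp = params.g_ahp_peak * ahp_factor(params, now_ms - state.t_last_spike)
    i_total_pa = (
        -params.g_leak * (state.v - params.e_leak)
        - g_ahp * (state.v - params.e_ahp)
        - state.g_gaba_trace * (state.v - params.e_gaba)
        + i_spont_na * NA_TO_PA
    )
    return i_total_pa / params.c_m


def step_neuron(
    state: NeuronState,
    params: NeuronParams,
    i_spont_na: float,
    dt: float,
    now_ms: float,
) -> NeuronState:
    """One forward-Euler membrane update; threshold test after the update.

    ``now_ms`` is the time of the state at the start of the step; the AHP
    term uses the elapsed time since the most recent spike at ``now_ms``.
    If the updated potential reaches threshold the neuron spikes and the
    spike time is recorded as ``now_ms`` (restarting the AHP from its peak).
    The GABA trace is not advanced here; see :func:`decay_gaba_trace`.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    v_new = state.v + dt * membrane_derivative(state, params, i_spont_na, now_ms)
    if not math.isfinite(v_new):
        raise FloatingPointError(
            f"membrane potential diverged at t={now_ms} ms (V={v_new})"
        )
    spiked = v_new >= params.v_threshold
    return NeuronState(
        v=v_new,
        g_gaba_trace=state.g_gaba_trace,
        t_last_spike=now_ms if spiked else state.t_last_spike,
        spiked_this_step=spiked,
    )


def decay_gaba_trace(state: NeuronState, params: NeuronParams, dt: float) -> NeuronState:
    """Advance the synaptic conductance trace by ``dt``: exact exponential decay."""
    if dt <= 0:
        raise ParameterError("dt must be positive")
    return replace(state, g_gaba_trace=state.g_gaba_trace * math.exp(-dt / params.tau_gaba))


def receive_spike(state: NeuronState, params: NeuronParams, weight: float) -> NeuronState:
    """Register one presynaptic spike of the given weight.

    The trace is incremented by ``g_gaba_peak * weight``; simultaneous
    presynaptic spikes sum linearly.
    """
    if weight < 0:
        raise ParameterError("synaptic weight must be non-negative")
    return replace(state, g_gaba_trace=state.g_gaba_trace + params.g_gaba_peak * weight)
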