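"""Wiring of the 1-D parasagittal microzone.

The model circuit is a 1 mm x 32 um parasagittal strip containing ``n_pkj``
Purkinje cells (default 16) laid out on a line with 64 um spacing, each with
a "territory" of ``mli_per_pkj`` molecular layer interneurons (default 10,
the anatomical 10:1 MLI:PKJ ratio).  The first ``lower_mli_per_pkj``
(default 3) MLIs of every territory sit in the lower molecular layer and are
the only cells eligible to receive Purkinje recurrent collaterals.

Axons are strictly one-directional along the strip:

* each MLI axon branches left or right with equal probability and can reach
  every PKJ and MLI in the ``mli_axon_span_pkjs`` (default 8) territories on
  that side;
* each PKJ recurrent collateral extends left or right with equal probability
  and can reach the lower-ML MLIs of the 2 nearest territories on that side;
* PKJ-to-PKJ synapses are disallowed (adult circuit).

Synapse formation is Bernoulli per (source, candidate) pair — every
candidate within the span has the same probability, candidates outside have
none — with at most one synapse per ordered pair and no autapses.  Weights
are drawn uniformly per connection type: MLI->MLI ~ U(0, 1),
MLI->PKJ ~ U(0, 1.25), PKJ->MLI ~ U(0, 1).

Connection probabilities default to values derived so that the *average*
convergence/divergence over the finite strip matches the anatomical targets
(20 MLIs converging onto a PKJ, 4 MLIs onto an MLI, each PKJ diverging onto
3 MLIs, each eligible MLI receiving about one PKJ input); see
:func:`derive_probabilities`.

Draw sequence (fixed, so a seed fully determines the wiring):
one ``numpy`` Generator seeded with ``config.seed`` is consumed in order:

1. for each MLI in id order: one U(0,1) draw; < 0.5 means axon points left;
2. for each MLI in id order: one U(0,1) draw per candidate PKJ (ascending
   id), then one per candidate MLI (ascending id); a draw below the
   connection probability forms a synapse;
3. for each PKJ in id order: one U(0,1) direction draw, then one U(0,1)
   draw per candidate lower-ML MLI (ascending id);
4. for each synapse in formation order: one uniform weight draw over that
   connection type's bounds.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .neuron import CellClass, ParameterError

__all__ = [
    "ConnectionType",
    "NetworkConfig",
    "Neuron",
    "Synapse",
    "Network",
    "derive_probabilities",
    "mean_candidate_counts",
    "build_network",
    "prune_synapses",
]


class ConnectionType(str, enum.Enum):
    MLI_MLI = "MLI->MLI"
    MLI_PKJ = "MLI->PKJ"
    PKJ_MLI = "PKJ->MLI"


#: Anatomical wiring targets: average number of synapses formed, per source
#: (divergence) or per target (convergence), that the connection
#: probabilities are chosen to reproduce.
WIRING_TARGETS = {
    ConnectionType.MLI_PKJ: 2.0,  # PKJs contacted per MLI (=> 20 MLIs per PKJ)
    ConnectionType.MLI_MLI: 4.0,  # MLI inputs per MLI
    ConnectionType.PKJ_MLI: 3.0,  # lower-ML MLIs contacted per PKJ
}

DEFAULT_WEIGHT_BOUNDS: Dict[ConnectionType, Tuple[float, float]] = {
    ConnectionType.MLI_MLI: (0.0, 1.0),
    ConnectionType.MLI_PKJ: (0.0, 1.25),
    ConnectionType.PKJ_MLI: (0.0, 1.0),
}


@dataclass(frozen=True)
class NetworkConfig:
    """Geometry, eligibility, connection probabilities and weight bounds."""

    n_pkj: int = 16
    mli_per_pkj: int = 10
    lower_mli_per_pkj: int = 3
    pkj_spacing_um: float = 64.0
    mli_axon_span_pkjs: int = 8
    pkj_collateral_span_pkjs: int = 2
    #: None => derive from WIRING_TARGETS for this geometry (finite strip).
    p_mli_to_pkj: Optional[float] = None
    p_mli_to_mli: Optional[float] = None
    p_pkj_to_mli: Optional[float] = None
    weight_bounds: Dict[ConnectionType, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHT_BOUNDS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pkj < 1 or self.mli_per_pkj < 1:
            raise ParameterError("neuron counts must be >= 1")
        if not 0 <= self.lower_mli_per_pkj <= self.mli_per_pkj:
            raise ParameterError("lower_mli_per_pkj must be <= mli_per_pkj")
        if self.mli_axon_span_pkjs < 1 or self.pkj_collateral_span_pkjs < 1:
            raise ParameterError("axon spans must be >= 1")
        for name in ("p_mli_to_pkj", "p_mli_to_mli", "p_pkj_to_mli"):
            p = getattr(self, name)
            if p is not None and not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        for ct, (lo, hi) in self.weight_bounds.items():
            if lo < 0 or hi < lo:
                raise ParameterError(f"invalid weight bounds for {ct}")

    @property
    def n_mli(self) -> int:
        return self.n_pkj * self.mli_per_pkj

    @property
    def n_neurons(self) -> int:
        return self.n_pkj + self.n_mli

    def probabilities(self) -> Dict[ConnectionType, float]:
        """Connection probabilities, deriving unset ones for this geometry."""
        explicit = {
            ConnectionType.MLI_PKJ: self.p_mli_to_pkj,
            ConnectionType.MLI_MLI: self.p_mli_to_mli,
            ConnectionType.PKJ_MLI: self.p_pkj_to_mli,
        }
        if any(p is None for p in explicit.values()):
            derived = derive_probabilities(self)
            return {ct: (p if p is not None else derived[ct]) for ct, p in explicit.items()}
        return explicit

    def to_dict(self) -> dict:
        d = asdict(self)
        d["weight_bounds"] = {
            ct.value if isinstance(ct, ConnectionType) else str(ct): list(b)
            for ct, b in self.weight_bounds.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if "weight_bounds" in d:
            d["weight_bounds"] = {
                ConnectionType(k): tuple(v) for k, v in d["weight_bounds"].items()
            }
        return cls(**d)


@dataclass(frozen=True)
class Neuron:
    id: int
    cell_class: CellClass
    territory: int
    within_territory: int  # 0 for the PKJ, 0..mli_per_pkj-1 for MLIs
    lower_ml: bool
    position_um: float


@dataclass(frozen=True)
class Synapse:
    source: int
    target: int
    conn_type: ConnectionType
    weight: float


@dataclass
class Network:
    """Realized microzone: neurons, directed inhibitory synapses, directions."""

    config: NetworkConfig
    neurons: List[Neuron]
    synapses: List[Synapse]
    mli_direction: Dict[int, int]  # MLI id -> -1 (left) or +1 (right)
    pkj_direction: Dict[int, int]  # PKJ id -> -1 or +1

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def ids_of(self, cell_class: CellClass) -> List[int]:
        return [n.id for n in self.neurons if n.cell_class is cell_class]

    def synapses_of(self, conn_type: ConnectionType) -> List[Synapse]:
        return [s for s in self.synapses if s.conn_type is conn_type]

    def counts_by_type(self) -> Dict[ConnectionType, int]:
        out = {ct: 0 for ct in ConnectionType}
        for s in self.synapses:
            out[s.conn_type] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.source, s.target, s.conn_type.value, s.weight) for s in self.synapses],
            columns=["source_id", "target_id", "type", "weight"],
        )

    def save(self, csv_path: str | Path) -> None:
        """Edge-list CSV plus a JSON sidecar with config, seed and directions."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        sidecar = {
            "config": self.config.to_dict(),
            "mli_direction": {str(k): v for k, v in self.mli_direction.items()},
            "pkj_direction": {str(k): v for k, v in self.pkj_direction.items()},
        }
        csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, csv_path: str | Path) -> "Network":
        csv_path = Path(csv_path)
        sidecar = json.loads(csv_path.with_suffix(".json").read_text())
        config = NetworkConfig.from_dict(sidecar["config"])
        net = cls(
            config=config,
            neurons=_layout_neurons(config),
            synapses=[],
            mli_direction={int(k): v for k, v in sidecar["mli_direction"].items()},
            pkj_direction={int(k): v for k, v in sidecar["pkj_direction"].items()},
        )
        df = pd.read_csv(csv_path, float_precision="round_trip")
        net.synapses = [
            Synapse(int(r.source_id), int(r.target_id), ConnectionType(r.type), float(r.weight))
            for r in df.itertuples()
        ]
        return net


def mean_candidate_counts(config: NetworkConfig) -> Dict[ConnectionType, float]:
    """Average candidate-target count per source, over positions and the
    equiprobable left/right axon direction, with spans truncated at the strip
    boundaries."""
    n, span = config.n_pkj, config.mli_axon_span_pkjs
    cspan = config.pkj_collateral_span_pkjs
    # territories reachable on one side, averaged over both directions
    mli_side = np.array([0.5 * (min(span, t) + min(span, n - 1 - t)) for t in range(n)])
    pkj_side = np.array([0.5 * (min(cspan, t) + min(cspan, n - 1 - t)) for t in range(n)])
    return {
        ConnectionType.MLI_PKJ: float(mli_side.mean()),
        ConnectionType.MLI_MLI: float(mli_side.mean() * config.mli_per_pkj),
        ConnectionType.PKJ_MLI: float(pkj_side.mean() * config.lower_mli_per_pkj),
    }


def derive_probabilities(
    config: NetworkConfig, boundary_correction: bool = True
) -> Dict[ConnectionType, float]:
    """Connection probabilities reproducing the anatomical wiring targets.

    With ``boundary_correction`` (default) the probability for each type is
    target divergence divided by the *average* candidate count on the finite
    strip, so the population-mean convergence/divergence matches the targets
    (20 MLI inputs per PKJ, 4 per MLI, 3 MLI targets per PKJ, about one PKJ
    input per eligible MLI).  Without it, candidate counts are taken as if
    the strip were unbounded, giving the simple ratios (e.g. 2 target PKJs /
    8 candidate PKJs = 0.25 for MLI->PKJ).
    """
    if boundary_correction:
        cand = mean_candidate_counts(config)
    else:
        # unbounded strip: every source sees the full span on its chosen side
        cand = {
            ConnectionType.MLI_PKJ: float(config.mli_axon_span_pkjs),
            ConnectionType.MLI_MLI: float(config.mli_axon_span_pkjs * config.mli_per_pkj),
            ConnectionType.PKJ_MLI: float(
                config.pkj_collateral_span_pkjs * config.lower_mli_per_pkj
            ),
        }
    probs = {}
    for ct, target in WIRING_TARGETS.items():
        if cand[ct] <= 0:
            raise ParameterError(f"no candidate targets for {ct.value}")
        p = target / cand[ct]
        if p > 1.0:
            raise ParameterError(
                f"wiring target for {ct.value} infeasible: requires p={p:.3f} > 1"
            )
        probs[ct] = p
    return probs


def _layout_neurons(config: NetworkConfig) -> List[Neuron]:
    """PKJs get ids 0..n_pkj-1, MLIs n_pkj..; MLI id encodes (territory, rank)."""
    neurons = []
    for t in range(config.n_pkj):
        neurons.append(
            Neuron(
                id=t,
                cell_class=CellClass.PKJ,
                territory=t,
                within_territory=0,
                lower_ml=False,
                position_um=t * config.pkj_spacing_um,
            )
        )
    for t in range(config.n_pkj):
        for w in range(config.mli_per_pkj):
            neurons.append(
                Neuron(
                    id=config.n_pkj + t * config.mli_per_pkj + w,
                    cell_class=CellClass.MLI,
                    territory=t,
                    within_territory=w,
                    lower_ml=w < config.lower_mli_per_pkj,
                    position_um=t * config.pkj_spacing_um
                    + (w + 0.5) / config.mli_per_pkj * config.pkj_spacing_um
                    - 0.5 * config.pkj_spacing_um,
                )
            )
    return neurons


def _side_territories(t: int, direction: int, span: int, n_pkj: int) -> range:
    """Territories reachable from territory ``t`` on the given side,
    truncated at the strip boundaries (the source's own territory excluded)."""
    if direction > 0:
        return range(t + 1, min(t + span, n_pkj - 1) + 1)
    return range(max(t - span, 0), t)


def build_network(config: NetworkConfig) -> Network:
    """Instantiate the wiring.  Deterministic given ``config.seed``.

    See the module docstring for the exact draw sequence.
    """
    rng = np.random.default_rng(config.seed)
    neurons = _layout_neurons(config)
    probs = config.probabilities()
    n_pkj, mpp = config.n_pkj, config.mli_per_pkj

    mli_ids = list(range(n_pkj, n_pkj + config.n_mli))
    mli_direction = {
        mid: (-1 if rng.random() < 0.5 else 1) for mid in mli_ids
    }

    raw: List[Tuple[int, int, ConnectionType]] = []
    for mid in mli_ids:
        terr = (mid - n_pkj) // mpp
        terrs = _side_territories(terr, mli_direction[mid], config.mli_axon_span_pkjs, n_pkj)
        for t in terrs:  # candidate PKJs, ascending id
            if rng.random() < probs[ConnectionType.MLI_PKJ]:
                raw.append((mid, t, ConnectionType.MLI_PKJ))
        for t in terrs:  # candidate MLIs, ascending id
            for w in range(mpp):
                if rng.random() < probs[ConnectionType.MLI_MLI]:
                    raw.append((mid, n_pkj + t * mpp + w, ConnectionType.MLI_MLI))

    pkj_direction = {}
    for pid in range(n_pkj):
        pkj_direction[pid] = -1 if rng.random() < 0.5 else 1
        terrs = _side_territories(
            pid, pkj_direction[pid], config.pkj_collateral_span_pkjs, n_pkj
        )
        for t in terrs:
            for w in range(config.lower_mli_per_pkj):
                if rng.random() < probs[ConnectionType.PKJ_MLI]:
                    raw.append((pid, n_pkj + t * mpp + w, ConnectionType.PKJ_MLI))

    synapses = [
        Synapse(s, t, ct, float(rng.uniform(*config.weight_bounds[ct])))
        for s, t, ct in raw
    ]
    return Network(
        config=config,
        neurons=neurons,
        synapses=synapses,
        mli_direction=mli_direction,
        pkj_direction=pkj_direction,
    )


def prune_synapses(
    net: Network,
    conn_type: ConnectionType,
    fraction: float,
    rng: np.random.Generator,
) -> Network:
    """Remove ``round(fraction * N_type)`` synapses of one connection type,
    uniformly at random without replacement; other synapses untouched."""
    if not isinstance(conn_type, ConnectionType):
        raise ParameterError(f"unknown connection type: {conn_type!r}")
    if not 0.0 <= fraction <= 1.0:
        raise ParameterError("prune fraction must lie in [0, 1]")
    idx_of_type = [i for i, s in enumerate(net.synapses) if s.conn_type is conn_type]
    n_remove = int(round(fraction * len(idx_of_type)))
    removed = set(rng.choice(idx_of_type, size=n_remove, replace=False).tolist()) if n_remove else set()
    kept = [s for i, s in enumerate(net.synapses) if i not in removed]
    return Network(
        config=net.config,
        neurons=list(net.neurons),
        synapses=kept,
        mli_direction=dict(net.mli_direction),
        pkj_direction=dict(net.pkj_direction),
    )
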