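"""Wiring generator: geometry, eligibility, probabilities, pruning."""

import numpy as np
import pytest
from scipy import stats as sps

from mzone.neuron import CellClass, ParameterError
from mzone.network import (
    ConnectionType,
    NetworkConfig,
    Network,
    WIRING_TARGETS,
    build_network,
    derive_probabilities,
    mean_candidate_counts,
    prune_synapses,
)


def replay_build(config):
    """Independent re-enactment of the documented draw sequence, returning
    (synapse triples, weights) for comparison with build_network."""
    rng = np.random.default_rng(config.seed)
    probs = config.probabilities()
    n_pkj, mpp, low = config.n_pkj, config.mli_per_pkj, config.lower_mli_per_pkj
    span, cspan = config.mli_axon_span_pkjs, config.pkj_collateral_span_pkjs
    mli_ids = range(n_pkj, n_pkj + n_pkj * mpp)
    directions = {m: (-1 if rng.random() < 0.5 else 1) for m in mli_ids}
    triples = []
    for m in mli_ids:
        terr = (m - n_pkj) // mpp
        if directions[m] > 0:
            terrs = [t for t in range(terr + 1, terr + span + 1) if t < n_pkj]
        else:
            terrs = [t for t in range(terr - span, terr) if t >= 0]
        for t in terrs:
            if rng.random() < probs[ConnectionType.MLI_PKJ]:
                triples.append((m, t, ConnectionType.MLI_PKJ))
        for t in terrs:
            for w in range(mpp):
                if rng.random() < probs[ConnectionType.MLI_MLI]:
                    triples.append((m, n_pkj + t * mpp + w, ConnectionType.MLI_MLI))
    for p in range(n_pkj):
        d = -1 if rng.random() < 0.5 else 1
        if d > 0:
            terrs = [t for t in range(p + 1, p + cspan + 1) if t < n_pkj]
        else:
            terrs = [t for t in range(p - cspan, p) if t >= 0]
        for t in terrs:
            for w in range(low):
                if rng.random() < probs[ConnectionType.PKJ_MLI]:
                    triples.append((p, n_pkj + t * mpp + w, ConnectionType.PKJ_MLI))
    weights = [rng.uniform(*config.weight_bounds[ct]) for _, _, ct in triples]
    return triples, weights


class TestDerivedProbabilities:
    def test_unbounded_strip_ratios(self):
        # 2 target PKJs / 8 candidates, 4 MLIs / 80, 3 MLIs / 6
        p = derive_probabilities(NetworkConfig(), boundary_correction=False)
        assert p[ConnectionType.MLI_PKJ] == pytest.approx(0.25)
        assert p[ConnectionType.MLI_MLI] == pytest.approx(0.05)
        assert p[ConnectionType.PKJ_MLI] == pytest.approx(0.5)

    def test_doubled_span_halves_mli_pkj_probability(self):
        p = derive_probabilities(
            NetworkConfig(n_pkj=32, mli_axon_span_pkjs=16), boundary_correction=False
        )
        assert p[ConnectionType.MLI_PKJ] == pytest.approx(0.125)

    def test_finite_strip_correction_hand_computed(self):
        # default 16-territory strip, span 8: mean one-side territory count
        # = (1/16) sum_t (min(8,t)+min(8,15-t))/2 = 5.75
        cfg = NetworkConfig()
        cand = mean_candidate_counts(cfg)
        assert cand[ConnectionType.MLI_PKJ] == pytest.approx(5.75)
        assert cand[ConnectionType.MLI_MLI] == pytest.approx(57.5)
        # collateral side: (1/16) sum_t (min(2,t)+min(2,15-t))/2 = 1.8125
        assert cand[ConnectionType.PKJ_MLI] == pytest.approx(1.8125 * 3)
        p = derive_probabilities(cfg)
        assert p[ConnectionType.MLI_PKJ] == pytest.approx(2 / 5.75)
        assert p[ConnectionType.MLI_MLI] == pytest.approx(4 / 57.5)
        assert p[ConnectionType.PKJ_MLI] == pytest.approx(3 / 5.4375)

    def test_infeasible_target_raises(self):
        with pytest.raises(ParameterError):
            derive_probabilities(NetworkConfig(n_pkj=2, mli_axon_span_pkjs=1))


class TestBuildNetwork:
    def test_zero_probabilities_yield_empty_wiring(self):
        cfg = NetworkConfig(p_mli_to_pkj=0.0, p_mli_to_mli=0.0, p_pkj_to_mli=0.0, seed=3)
        net = build_network(cfg)
        assert net.n_neurons == 176 and len(net.synapses) == 0

    @pytest.mark.parametrize("seed", [0, 11])
    def test_anatomical_invariants(self, seed):
        net = build_network(NetworkConfig(seed=seed))
        cfg = net.config
        by_id = {n.id: n for n in net.neurons}
        pairs = set()
        for s in net.synapses:
            src, tgt = by_id[s.source], by_id[s.target]
            assert s.source != s.target, "no autapses"
            assert (s.source, s.target) not in pairs, "one synapse per ordered pair"
            pairs.add((s.source, s.target))
            assert not (src.cell_class is CellClass.PKJ and tgt.cell_class is CellClass.PKJ)
            lo, hi = cfg.weight_bounds[s.conn_type]
            assert lo <= s.weight <= hi
            if s.conn_type is ConnectionType.PKJ_MLI:
                assert tgt.lower_ml, "collaterals only reach lower-ML interneurons"
                d = net.pkj_direction[s.source]
                offset = (tgt.territory - src.territory) * d
                assert 1 <= offset <= cfg.pkj_collateral_span_pkjs
            else:
                d = net.mli_direction[s.source]
                offset = (tgt.territory - src.territory) * d
                assert 1 <= offset <= cfg.mli_axon_span_pkjs

    def test_matches_independent_replay_of_draw_sequence(self):
        cfg = NetworkConfig(seed=99)
        net = build_network(cfg)
        triples, weights = replay_build(cfg)
        assert [(s.source, s.target, s.conn_type) for s in net.synapses] == triples
        assert [s.weight for s in net.synapses] == pytest.approx(weights)

    def test_convergence_matches_analytic_expectation_over_seeds(self):
        """Mean per-neuron in/out-degree over 200 seeds matches the exact
        truncation-aware expectation within 4 binomial standard errors, and
        the population means land on the anatomical targets (20/4/3)."""
        n_seeds = 200
        cfg = NetworkConfig()
        probs = cfg.probabilities()
        n_pkj, mpp = cfg.n_pkj, cfg.mli_per_pkj
        span = cfg.mli_axon_span_pkjs

        conv_mp = np.zeros(n_pkj)  # MLI->PKJ in-degree per PKJ
        div_pm = np.zeros(n_pkj)  # PKJ->MLI out-degree per PKJ
        n_mm = 0
        for seed in range(n_seeds):
            net = build_network(NetworkConfig(seed=seed))
            for s in net.synapses:
                if s.conn_type is ConnectionType.MLI_PKJ:
                    conv_mp[s.target] += 1
                elif s.conn_type is ConnectionType.PKJ_MLI:
                    div_pm[s.source] += 1
                else:
                    n_mm += 1
        conv_mp /= n_seeds
        div_pm /= n_seeds

        # exact expectation for PKJ t: MLIs in reach on either side x 1/2 x p
        p = probs[ConnectionType.MLI_PKJ]
        for t in range(n_pkj):
            n_cand = (min(span, t) + min(span, n_pkj - 1 - t)) * mpp
            expect = n_cand * 0.5 * p
            se = np.sqrt(n_cand * 0.5 * p * (1 - 0.5 * p) / n_seeds)
            assert abs(conv_mp[t] - expect) < 4 * se
        # population means hit the anatomical targets by construction
        assert conv_mp.mean() == pytest.approx(
            WIRING_TARGETS[ConnectionType.MLI_PKJ] * cfg.n_mli / n_pkj, rel=0.05
        )
        assert n_mm / n_seeds / cfg.n_mli == pytest.approx(4.0, rel=0.05)
        assert div_pm.mean() == pytest.approx(3.0, rel=0.05)
        # boundary neurons see no more synapses than the best-connected ones
        assert conv_mp[0] <= conv_mp.max() and conv_mp[-1] <= conv_mp.max()

    def test_weights_are_uniform_within_bounds(self):
        """KS test of pooled weights against U(bounds) at alpha=0.01."""
        weights = {ct: [] for ct in ConnectionType}
        seed = 0
        while len(weights[ConnectionType.MLI_MLI]) < 10_000:
            net = build_network(NetworkConfig(seed=seed))
            for s in net.synapses:
                weights[s.conn_type].append(s.weight)
            seed += 1
        for ct, (lo, hi) in NetworkConfig().weight_bounds.items():
            x = (np.array(weights[ct]) - lo) / (hi - lo)
            assert sps.kstest(x, "uniform").pvalue > 0.01

    def test_save_load_round_trip(self, tmp_path):
        net = build_network(NetworkConfig(seed=5))
        net.save(tmp_path / "edges.csv")
        back = Network.load(tmp_path / "edges.csv")
        assert back.config == net.config
        assert [(s.source, s.target, s.conn_type, s.weight) for s in back.synapses] == [
            (s.source, s.target, s.conn_type, s.weight) for s in net.synapses
        ]


@pytest.fixture(scope="module")
def pruning_net():
    return build_network(NetworkConfig(seed=7))


class TestPruning:

    def test_fraction_zero_is_identity(self, pruning_net):
        net = pruning_net
        out = prune_synapses(net, ConnectionType.MLI_MLI, 0.0, np.random.default_rng(0))
        assert [(s.source, s.target) for s in out.synapses] == [
            (s.source, s.target) for s in net.synapses
        ]

    def test_fraction_one_removes_all_of_type_only(self, pruning_net):
        net = pruning_net
        out = prune_synapses(net, ConnectionType.PKJ_MLI, 1.0, np.random.default_rng(0))
        counts, base = out.counts_by_type(), net.counts_by_type()
        assert counts[ConnectionType.PKJ_MLI] == 0
        assert counts[ConnectionType.MLI_MLI] == base[ConnectionType.MLI_MLI]
        assert counts[ConnectionType.MLI_PKJ] == base[ConnectionType.MLI_PKJ]

    def test_half_removes_rounded_count(self, pruning_net):
        net = pruning_net
        n0 = net.counts_by_type()[ConnectionType.MLI_MLI]
        out = prune_synapses(net, ConnectionType.MLI_MLI, 0.5, np.random.default_rng(1))
        assert out.counts_by_type()[ConnectionType.MLI_MLI] == n0 - round(0.5 * n0)

    def test_invalid_arguments(self, pruning_net):
        net = pruning_net
        with pytest.raises(ParameterError):
            prune_synapses(net, "GRC->PKJ", 0.5, np.random.default_rng(0))
        with pytest.raises(ParameterError):
            prune_synapses(net, ConnectionType.MLI_MLI, 1.5, np.random.default_rng(0))
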