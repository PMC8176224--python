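import math
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cernapipe as cp
from cernapipe.cerna import (CernaConfig, CernaNetwork, TargetMap,
                             build_cerna_network, extract_subnetwork,
                             negative_target_pairs, pearson_r, spearman_rho,
                             sponge_test)
from cernapipe.ortholog import CoDESet

from conftest import make_matrix


class TestCorrelations:
    def test_perfect_monotone(self):
        x = np.array([1, 2, 3, 4, 5.0])
        assert spearman_rho(x, -x) == pytest.approx(-1.0)
        assert spearman_rho([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_pearson_affine_invariance(self):
        x = np.array([3, 1, 4, 1, 5, 9.0])
        assert pearson_r(x, 2 * x + 3) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_constant_vector_gives_nan(self):
        assert math.isnan(pearson_r([1, 1, 1], [1, 2, 3]))
        assert math.isnan(spearman_rho([2, 2, 2, 2], [1, 2, 3, 4]))

    def test_tied_ranks_match_bruteforce(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.integers(0, 4, size=9).astype(float)
            y = rng.integers(0, 4, size=9).astype(float)

            def ranks(v):
                order = np.argsort(v, kind="mergesort")
                r = np.empty(len(v))
                i = 0
                while i < len(v):
                    j = i
                    while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                        j += 1
                    r[order[i:j + 1]] = (i + j) / 2 + 1
                    i = j + 1
                return r

            rx, ry = ranks(x), ranks(y)
            if np.ptp(rx) == 0 or np.ptp(ry) == 0:
                continue
            expected = np.corrcoef(rx, ry)[0, 1]
            assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)


class TestSpongeTest:
    def test_x_zero_gives_one(self):
        assert sponge_test(0, 10, 4, 5) == 1.0

    def test_fully_shared_triples_in_universe_six(self):
        # all C(6,3)=20 draws; only one contains all three marked
        assert sponge_test(3, 6, 3, 3) == pytest.approx(1 / 20)

    def test_four_shared_of_five_drawn(self):
        assert sponge_test(4, 10, 4, 5) == pytest.approx(6 / 252)

    @pytest.mark.parametrize("kwargs", [
        dict(x=4, U=10, M=3, N=5),   # x > min(M, N)
        dict(x=1, U=5, M=6, N=2),    # M > U
        dict(x=-1, U=5, M=2, N=2),
        dict(x=0, U=0, M=0, N=0),
    ])
    def test_precondition_violations_raise(self, kwargs):
        with pytest.raises(ValueError):
            sponge_test(**kwargs)

    def test_exclusive_tail_variant(self):
        assert sponge_test(0, 10, 4, 5, tail="above") < 1.0
        assert sponge_test(0, 10, 4, 5, tail="above") == pytest.approx(
            1 - math.comb(6, 5) / math.comb(10, 5))

    @settings(deadline=None, max_examples=100)
    @given(st.data())
    def test_monotone_nonincreasing_in_x(self, data):
        U = data.draw(st.integers(1, 12))
        M = data.draw(st.integers(0, U))
        N = data.draw(st.integers(0, U))
        ps = [sponge_test(x, U, M, N) for x in range(min(M, N) + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


def _retained(rows):
    return pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_class", "scc"])


class TestNegativeTargetPairs:
    def test_strictness_at_threshold(self):
        """A pair with Spearman rho exactly at the cut is dropped (strict <)."""
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([3, 4, 5, 1, 2.0])  # rho = exactly -0.5 vs x
        assert spearman_rho(x, -y) == pytest.approx(0.5)
        mirna = make_matrix(x[None, :2 * 3 - 1] if False else np.tile(x, (1, 1)),
                            transcript_ids=["M1"], groups=("A",), reps=5,
                            rna_class="miRNA")
        target = make_matrix(np.tile(y, (1, 1)), transcript_ids=["G1"],
                             groups=("A",), reps=5)
        tmap = TargetMap({"M1": {"G1": "mRNA"}})
        cfg_at = CernaConfig(scc_max=-0.5)
        out = negative_target_pairs(tmap, mirna, {"mRNA": target}, config=cfg_at)
        assert len(out) == 0  # rho == scc_max, not < scc_max
        cfg_below = CernaConfig(scc_max=-0.49)
        out2 = negative_target_pairs(tmap, mirna, {"mRNA": target}, config=cfg_below)
        assert len(out2) == 1 and out2.iloc[0]["scc"] == pytest.approx(-0.5)

    def test_positive_correlation_dropped(self):
        v = np.array([[1, 2, 3, 4, 5, 6.0]])
        mirna = make_matrix(v, transcript_ids=["M1"], rna_class="miRNA")
        target = make_matrix(v, transcript_ids=["G1"])
        tmap = TargetMap({"M1": {"G1": "mRNA"}})
        assert len(negative_target_pairs(tmap, mirna, {"mRNA": target})) == 0

    def test_non_de_pairs_excluded(self):
        v = np.array([[1, 2, 3, 4, 5, 6.0]])
        mirna = make_matrix(v, transcript_ids=["M1"], rna_class="miRNA")
        target = make_matrix(v[:, ::-1].copy(), transcript_ids=["G1"])
        tmap = TargetMap({"M1": {"G1": "mRNA"}})
        assert len(negative_target_pairs(tmap, mirna, {"mRNA": target},
                                         de_ids={"M1"})) == 0
        assert len(negative_target_pairs(tmap, mirna, {"mRNA": target},
                                         de_ids={"M1", "G1"})) == 1


class TestBuildNetwork:
    def test_planted_triplets_recovered(self, default_run):
        net, truth = default_run.network, default_run.truth
        predicted = {frozenset(e) for e in net.cerna_edges}
        recovered = [t for t in truth.triplets if frozenset(t[:2]) in predicted]
        assert len(recovered) >= 0.8 * len(truth.triplets)
        for a, b, shared in recovered:
            # the supporting miRNA-target edges are present
            n_support = sum(1 for m in shared
                            if net.graph.has_edge(m, a) and net.graph.has_edge(m, b))
            assert n_support >= 1

    def test_mirna_direction_opposes_partners(self, default_run):
        g = default_run.network.graph
        for u, v, d in g.edges(data=True):
            if d["kind"] != "mirna_target":
                continue
            dirs = {g.nodes[u]["direction"], g.nodes[v]["direction"]}
            assert dirs == {"up", "down"}

    def test_empty_co_de_gives_empty_network(self, default_sim):
        bundle, _ = default_sim
        empty = {c: CoDESet() for c in ("mRNA", "lncRNA", "miRNA", "circRNA")}
        net = cp.run_cerna(bundle, empty)
        assert net.graph.number_of_nodes() == 0
        assert len(net.sponge) == 0

    def test_pcc_knockout_removes_pairs(self, default_run, default_sim):
        bundle, _ = default_sim
        res = cp.run_all(cp.SimulationConfig(seed=3), with_associations=False,
                         cerna_config=CernaConfig(pcc_min=1.0))
        assert len(res.network.cerna_edges) == 0

    def test_universe_smaller_than_regulator_set_raises(self):
        v = np.array([[1, 2, 3, 8, 9, 10.0]])
        expr = {
            "mRNA": make_matrix(v, transcript_ids=["G1"]),
            "lncRNA": make_matrix(v, transcript_ids=["L1"], rna_class="lncRNA"),
            "miRNA": make_matrix(np.vstack([v[:, ::-1]] * 2),
                                 transcript_ids=["m1", "m2"], rna_class="miRNA"),
        }
        targets = TargetMap({"m1": {"G1": "mRNA", "L1": "lncRNA"},
                             "m2": {"G1": "mRNA", "L1": "lncRNA"}})
        co = {"mRNA": CoDESet(ids={"G1"}, direction_of={"G1": "up"}),
              "lncRNA": CoDESet(ids={"L1"}, direction_of={"L1": "up"}),
              "miRNA": CoDESet(ids={"m1"}, direction_of={"m1": "down"})}
        retained = _retained([("m1", "G1", "mRNA", -0.95), ("m1", "L1", "lncRNA", -0.95)])
        with pytest.raises(ValueError, match="universe"):
            build_cerna_network(co, retained, expr, targets,
                                CernaConfig(universe_size=1))


class TestSubnetwork:
    @staticmethod
    def _star():
        net = CernaNetwork()
        net.graph.add_node("hub", **{"class": "mRNA", "direction": "up"})
        for i in range(5):
            net.graph.add_node(f"leaf{i}", **{"class": "miRNA", "direction": "down"})
            net.graph.add_edge("hub", f"leaf{i}", kind="mirna_target", weight=-0.9)
        return net

    def test_star_from_hub_radius_one(self):
        sub = extract_subnetwork(self._star(), ["hub"], radius=1)
        assert sub.graph.number_of_nodes() == 6

    def test_isolated_seed_returns_itself(self):
        net = self._star()
        net.graph.add_node("lone", **{"class": "circRNA", "direction": "up"})
        sub = extract_subnetwork(net, ["lone"], radius=2)
        assert set(sub.graph.nodes) == {"lone"}

    def test_absent_seed_gives_empty_with_warning(self, caplog):
        sub = extract_subnetwork(self._star(), ["nope"], radius=1)
        assert sub.graph.number_of_nodes() == 0

    def test_matches_bfs_oracle_on_pipeline_network(self, default_run):
        net = default_run.network
        seeds = [n for n, d in net.graph.nodes(data=True) if d["class"] == "mRNA"][:3]
        if not seeds:
            pytest.skip("no mRNA nodes in this network")
        sub = extract_subnetwork(net, seeds, radius=2)
        expected = set()
        for s in seeds:
            frontier, seen = {s}, {s}
            for _ in range(2):
                frontier = {v for u in frontier for v in net.graph.neighbors(u)} - seen
                seen |= frontier
            expected |= seen
        assert set(sub.graph.nodes) == expected

    def test_radius_zero_rejected(self):
        with pytest.raises(ValueError):
            extract_subnetwork(self._star(), ["hub"], radius=0)


class TestExport:
    def test_sif_round_trippable_lines(self, default_run, tmp_path):
        sif = tmp_path / "net.sif"
        nodes = tmp_path / "nodes.tsv"
        cp.cerna.write_sif(default_run.network, sif, nodes)
        lines = sif.read_text().strip().splitlines()
        assert len(lines) == default_run.network.graph.number_of_edges()
        assert all(len(l.split("\t")) == 3 for l in lines)
        header = nodes.read_text().splitlines()[0]
        assert header == "id\tclass\tdirection"
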