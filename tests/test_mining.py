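import itertools
from collections import Counter

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import cranesig as cs
from hypothesis import given, settings, strategies as st

from tests.oracles import oracle_best_mi


class TestEntropy:
    @pytest.mark.parametrize(
        "p,expected",
        [((0.5, 0.5), 1.0), ((1.0, 0.0), 0.0), ((0.25, 0.75), 0.811278)],
    )
    def test_values(self, p, expected):
        assert cs.entropy(p) == pytest.approx(expected, abs=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cs.entropy([-0.1, 1.1])
        with pytest.raises(ValueError):
            cs.entropy([0.6, 0.6])

    def test_permutation_invariant(self, rng):
        p = rng.dirichlet(np.ones(6))
        assert cs.entropy(p) == pytest.approx(cs.entropy(p[::-1]), abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=8))
    def test_bounds_and_symmetry(self, weights):
        p = np.array(weights) / np.sum(weights)
        h = cs.entropy(p)
        assert -1e-12 <= h <= np.log2(len(p)) + 1e-12
        assert h == pytest.approx(cs.entropy(sorted(p)), abs=1e-9)


class TestStateString:
    def test_order_sensitivity(self, tiny_binarized):
        assert cs.state_string(tiny_binarized, ["A", "B"], "s5") == "HL"
        assert cs.state_string(tiny_binarized, ["B", "A"], "s5") == "LH"

    def test_all_low(self, tiny_binarized):
        assert cs.state_string(tiny_binarized, list("ABCD"), "s7") == "LLLL"

    def test_missing_gene(self, tiny_binarized):
        with pytest.raises(KeyError):
            cs.state_string(tiny_binarized, ["Z"], "s1")


class TestStateTable:
    def test_hand_enumerated_joint(self):
        states = pd.DataFrame(
            {"a": [1, 1], "b": [1, 1], "c": [0, 0], "d": [0, 0]},
            index=["g1", "g2"],
            dtype=bool,
        )
        binarized = cs.BinarizedMatrix(states)
        labels = cs.PhenotypeLabels(
            pd.Series(["LTS", "LTS", "STS", "STS"], index=list("abcd")), 225, 635
        )
        records = {r.state: r for r in cs.state_table(binarized, ["g1", "g2"], labels)}
        assert records["HH"].support == 0.5
        assert records["HH"].confidence == 1.0
        assert records["HH"].anti_confidence == 0.0
        assert records["HH"].j_value == pytest.approx(0.5)
        assert records["LL"].j_value == pytest.approx(0.5)

    def test_uninformative_single_state(self):
        states = pd.DataFrame(
            {"a": [1, 0], "b": [1, 0], "c": [1, 0], "d": [1, 0]},
            index=["g1", "g2"],
            dtype=bool,
        )
        binarized = cs.BinarizedMatrix(states)
        labels = cs.PhenotypeLabels(
            pd.Series(["LTS", "STS", "LTS", "STS"], index=list("abcd")), 225, 635
        )
        records = cs.state_table(binarized, ["g1", "g2"], labels)
        assert len(records) == 1
        assert records[0].j_value == pytest.approx(0.0, abs=1e-12)

    def test_lts_only_state_positive_j(self, tiny_binarized, tiny_labels):
        records = cs.state_table(tiny_binarized, ["A", "B", "C", "D"], tiny_labels)
        lts_only = [r for r in records if r.anti_confidence == 0 and r.confidence > 0]
        assert lts_only and all(r.j_value > 0 for r in lts_only)

    def test_supports_sum_to_one_and_count_identity(self, tiny_binarized, tiny_labels):
        records = cs.state_table(tiny_binarized, ["A", "C"], tiny_labels)
        n, n_lts, n_sts = 8, tiny_labels.n_lts, tiny_labels.n_sts
        assert sum(r.support for r in records) == pytest.approx(1.0)
        for r in records:
            lhs = n_lts * r.confidence + n_sts * r.anti_confidence
            assert lhs == pytest.approx(n * r.support, abs=1e-9)


class TestMutualInformation:
    def test_perfect_separation_one_bit(self):
        states = pd.DataFrame(
            {"a": [1], "b": [1], "c": [0], "d": [0]}, index=["g"], dtype=bool
        )
        labels = cs.PhenotypeLabels(
            pd.Series(["LTS", "LTS", "STS", "STS"], index=list("abcd")), 225, 635
        )
        records = cs.state_table(cs.BinarizedMatrix(states), ["g"], labels)
        assert cs.subnetwork_mutual_information(records, labels) == pytest.approx(1.0)

    def test_xor_pair_informative_singles_not(self):
        # class = parity of two genes' states, all four states uniform
        g1 = [1, 1, 0, 0] * 5
        g2 = [1, 0, 1, 0] * 5
        cls = ["LTS" if a == b else "STS" for a, b in zip(g1, g2)]
        samples = [f"s{i}" for i in range(20)]
        binarized = cs.BinarizedMatrix(
            pd.DataFrame([g1, g2], index=["g1", "g2"], columns=samples, dtype=bool)
        )
        labels = cs.PhenotypeLabels(pd.Series(cls, index=samples), 225, 635)
        pair = cs.state_table(binarized, ["g1", "g2"], labels)
        assert cs.subnetwork_mutual_information(pair, labels) == pytest.approx(1.0)
        for g in ("g1", "g2"):
            single = cs.state_table(binarized, [g], labels)
            assert cs.subnetwork_mutual_information(single, labels) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_decomposition_identity_random_fixtures(self, rng):
        """sum_f J(f) equals I(C;F) = H(C) - H(C|F) on random data."""
        for _ in range(25):
            k = int(rng.integers(1, 5))
            n = int(rng.integers(6, 40))
            states = pd.DataFrame(
                rng.random((k, n)) < 0.3,
                index=[f"g{i}" for i in range(k)],
                columns=[f"s{i}" for i in range(n)],
            )
            y = rng.permutation([True] * (n // 2) + [False] * (n - n // 2))
            labels = cs.PhenotypeLabels(
                pd.Series(np.where(y, "LTS", "STS"), index=states.columns), 225, 635
            )
            records = cs.state_table(cs.BinarizedMatrix(states), states.index, labels)
            mi = cs.subnetwork_mutual_information(records, labels)
            assert abs(mi - sum(r.j_value for r in records)) < 1e-10


class TestMineSubnetworks:
    def test_exhaustive_matches_independent_oracle(self, rng):
        """On small graphs the search attains the enumeration maximum."""
        for _ in range(5):
            g = nx.gnp_random_graph(10, 0.3, seed=int(rng.integers(1 << 16)))
            g = nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes})
            states = pd.DataFrame(
                rng.random((10, 30)) < 0.25,
                index=[f"G{i}" for i in range(10)],
                columns=[f"s{i}" for i in range(30)],
            )
            labels = cs.PhenotypeLabels(
                pd.Series(["LTS"] * 15 + ["STS"] * 15, index=states.columns), 225, 635
            )
            binarized = cs.BinarizedMatrix(states)
            cands = cs.mine_subnetworks(
                cs.PPINetwork(g), binarized, labels, d_max=3, method="auto"
            )
            oracle = oracle_best_mi(g, binarized, labels, 3)
            assert cands[0].mutual_information == pytest.approx(oracle, abs=1e-9)

    def test_dmax_one_is_single_gene_ranking(self, cohort_sim):
        b = cs.binarize_expression(cohort_sim.expression)
        labels = cohort_sim.labels_true
        cands = cs.mine_subnetworks(
            cohort_sim.network, b, labels, d_max=1, method="exhaustive", top_n=300
        )
        assert all(c.size == 1 for c in cands)
        mis = [c.mutual_information for c in cands]
        assert mis == sorted(mis, reverse=True)

    def test_xor_pair_found_on_path_graph(self):
        # 6-node path; adjacent pair (G2, G3) carries an XOR rule
        g = nx.path_graph(6)
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes})
        rng = np.random.default_rng(0)
        n = 60
        g2 = rng.random(n) < 0.5
        g3 = rng.random(n) < 0.5
        cls = np.where(g2 == g3, "LTS", "STS")
        rows = {f"G{i}": rng.random(n) < 0.25 for i in range(6)}
        rows["G2"], rows["G3"] = g2, g3
        states = pd.DataFrame(rows, index=[f"s{i}" for i in range(n)]).T
        labels = cs.PhenotypeLabels(pd.Series(cls, index=states.columns), 225, 635)
        cands = cs.mine_subnetworks(
            cs.PPINetwork(g), cs.BinarizedMatrix(states), labels, d_max=2, method="auto"
        )
        assert set(cands[0].genes) == {"G2", "G3"}

    def test_beam_deterministic(self, cohort_sim):
        b = cs.binarize_expression(cohort_sim.expression)
        kw = dict(d_max=4, beam_width=3, method="beam", seed=5)
        a = cs.mine_subnetworks(cohort_sim.network, b, cohort_sim.labels_true, **kw)
        c = cs.mine_subnetworks(cohort_sim.network, b, cohort_sim.labels_true, **kw)
        assert [x.genes for x in a] == [x.genes for x in c]
        assert [x.mutual_information for x in a] == [x.mutual_information for x in c]

    def test_permutation_null_mi_decreases_with_n(self):
        """Top-candidate MI under shuffled labels shrinks as n grows."""
        g = nx.relabel_nodes(nx.path_graph(8), {i: f"G{i}" for i in range(8)})
        tops = {}
        for n in (50, 500):
            vals = []
            for seed in range(10):
                rng = np.random.default_rng(seed)
                states = pd.DataFrame(
                    rng.random((8, n)) < 0.25,
                    index=[f"G{i}" for i in range(8)],
                    columns=[f"s{i}" for i in range(n)],
                )
                labels = cs.PhenotypeLabels(
                    pd.Series(
                        rng.permutation(["LTS"] * (n // 2) + ["STS"] * (n // 2)),
                        index=states.columns,
                    ),
                    225,
                    635,
                )
                cands = cs.mine_subnetworks(
                    cs.PPINetwork(g),
                    cs.BinarizedMatrix(states),
                    labels,
                    d_max=3,
                    method="exhaustive",
                )
                vals.append(cands[0].mutual_information)
            tops[n] = np.mean(vals)
        assert tops[500] < tops[50]

    def test_insufficient_overlap_raises(self, tiny_binarized, tiny_labels):
        g = nx.Graph([("X", "Y")])
        with pytest.raises(ValueError, match="overlap"):
            cs.mine_subnetworks(
                cs.PPINetwork(g), tiny_binarized, tiny_labels, d_max=5
            )


class TestComposeSignature:
    def _sub(self, genes, mi):
        return cs.Subnetwork(genes=tuple(genes), state_table=[], mutual_information=mi)

    def test_disjointness_rule(self):
        cands = [
            self._sub("AB", 0.9),
            self._sub("BC", 0.8),
            self._sub("DE", 0.7),
        ]
        sig = cs.compose_signature(cands, k=2)
        assert [s.genes for s in sig.subnetworks] == [("A", "B"), ("D", "E")]

    def test_k_one(self):
        cands = [self._sub("AB", 0.9), self._sub("CD", 0.5)]
        sig = cs.compose_signature(cands, k=1)
        assert len(sig) == 1 and sig.subnetworks[0].genes == ("A", "B")

    def test_fifty_gene_union(self):
        cands = [
            self._sub([f"G{i}_{j}" for j in range(10)], 1.0 - 0.1 * i)
            for i in range(5)
        ]
        sig = cs.compose_signature(cands, k=5)
        assert len(sig.genes) == 50
        assert len(set(sig.genes)) == 50

    def test_too_few_disjoint_warns(self):
        cands = [self._sub("AB", 0.9), self._sub("BC", 0.8), self._sub("CA", 0.7)]
        with pytest.warns(UserWarning, match="disjoint"):
            sig = cs.compose_signature(cands, k=3)
        assert len(sig) == 1
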