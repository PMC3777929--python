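import networkx as nx
import numpy as np
import pandas as pd
import pytest

import cranesig as cs
from cranesig.simulate import ConfigError, balanced_design


class TestNetworkGeneration:
    def test_planted_sets_connected_and_disjoint(self):
        cfg = cs.CohortSimConfig(
            n_genes=100, planted=[cs.two_state_design(10), cs.two_state_design(6)], seed=2
        )
        net, sets = cs.generate_ppi_network(cfg)
        assert len(sets[0]) == 10 and len(sets[1]) == 6
        assert not set(sets[0]) & set(sets[1])
        for s in sets:
            assert nx.is_connected(net.graph.subgraph(s))

    def test_seed_reproducible(self):
        cfg = cs.CohortSimConfig(n_genes=80, planted=[cs.two_state_design(4)], seed=9)
        n1, s1 = cs.generate_ppi_network(cfg)
        n2, s2 = cs.generate_ppi_network(cfg)
        assert sorted(n1.graph.edges) == sorted(n2.graph.edges)
        assert s1 == s2

    def test_infeasible_planting_rejected(self):
        with pytest.raises(ConfigError):
            cs.CohortSimConfig(n_genes=12, planted=[cs.two_state_design(20)], seed=0)


class TestPlantedSpecs:
    def test_inconsistent_confidences_rejected(self):
        with pytest.raises(ConfigError):
            cs.PlantedSubnetworkSpec(
                size=2,
                states=[cs.PlantedState("HH", 0.7, 0.0), cs.PlantedState("LL", 0.6, 0.0)],
            )

    def test_state_length_checked(self):
        with pytest.raises(ConfigError):
            cs.PlantedSubnetworkSpec(size=3, states=[cs.PlantedState("HH", 0.2, 0.0)])

    def test_balanced_design_class_balanced_marginals(self):
        spec = balanced_design(6, confidence=0.4, cross=0.04)
        for gi in range(6):
            lts = sum(s.confidence for s in spec.states if s.state[gi] == "H")
            sts = sum(s.anti_confidence for s in spec.states if s.state[gi] == "H")
            assert lts == pytest.approx(sts)


class TestExpressionCohort:
    @pytest.fixture(scope="class")
    def sim(self):
        cfg = cs.CohortSimConfig(
            n_genes=150,
            n_sts=60,
            n_lts=60,
            n_middle=0,
            planted=[cs.two_state_design(6, 0.44, 0.0)],
            seed=4,
        )
        return cs.simulate_cohort(cfg)

    def test_byte_reproducible(self, sim):
        sim2 = cs.simulate_cohort(sim.config)
        pd.testing.assert_frame_equal(sim.expression.values, sim2.expression.values)
        pd.testing.assert_frame_equal(sim.clinical.table, sim2.clinical.table)

    def test_survival_split_recovers_classes(self, sim):
        labels = cs.define_survival_groups(sim.clinical, 0.5, 0.5)
        truth = sim.labels_true.labels
        assert labels.labels.sort_index().equals(truth.sort_index())

    def test_binarization_recovers_planted_cells(self, sim):
        """>= 95% of planted (gene, sample) cells keep their designed state
        after quartile binarization at noise sd 0.2."""
        b = cs.binarize_expression(sim.expression)
        genes = sim.planted_sets[0]
        truth = sim.true_states[0]
        obs = np.array(
            [list(cs.state_string(b, genes, s)) for s in truth.index]
        )
        designed = np.array([list(t) for t in truth])
        assert (obs == designed).mean() >= 0.95

    def test_planted_state_fractions_near_targets(self, sim):
        spec = sim.config.planted[0]
        truth = sim.true_states[0]
        lts = sim.labels_true.lts_samples
        n = len(lts)
        for st in spec.states:
            emp = np.mean([truth[s] == st.state for s in lts])
            se = np.sqrt(st.confidence * (1 - st.confidence) / n)
            assert abs(emp - st.confidence) <= 3 * se + 1e-9

    def test_xor_pair_mi_matches_design(self):
        """Plug-in MI of a planted XOR-style pair approaches the design
        value at n = 400."""
        spec = balanced_design(2, confidence=0.48, cross=0.02)
        cfg = cs.CohortSimConfig(
            n_genes=30, n_sts=200, n_lts=200, n_middle=0, planted=[spec], seed=11
        )
        sim = cs.simulate_cohort(cfg)
        b = cs.binarize_expression(sim.expression)
        records = cs.state_table(b, sim.planted_sets[0], sim.labels_true)
        mi = cs.subnetwork_mutual_information(records, sim.labels_true)
        # design MI by exact enumeration of the generative distribution
        design = _design_pair_mi(spec)
        assert abs(mi - design) < 0.1

    def test_null_cohort_top_mi_near_permutation_null(self):
        cfg = cs.CohortSimConfig(n_genes=40, n_sts=40, n_lts=40, n_middle=0, seed=13)
        sim = cs.simulate_cohort(cfg)
        b = cs.binarize_expression(sim.expression)
        cands = cs.mine_subnetworks(
            sim.network, b, sim.labels_true, d_max=2, method="exhaustive"
        )
        null_tops = []
        for pseed in range(5):
            r = np.random.default_rng(pseed)
            perm = cs.PhenotypeLabels(
                pd.Series(
                    r.permutation(sim.labels_true.labels.to_numpy()),
                    index=sim.labels_true.labels.index,
                ),
                225,
                635,
            )
            c = cs.mine_subnetworks(sim.network, b, perm, d_max=2, method="exhaustive")
            null_tops.append(c[0].mutual_information)
        assert cands[0].mutual_information <= max(null_tops) + 0.05


def _design_pair_mi(spec):
    probs = {}
    for cls, attr in (("STS", "anti_confidence"), ("LTS", "confidence")):
        p = {s.state: getattr(s, attr) for s in spec.states}
        p["LL"] = p.get("LL", 0.0) + (1.0 - sum(getattr(s, attr) for s in spec.states))
        probs[cls] = p
    states = sorted({st for p in probs.values() for st in p})
    joint = np.array([[0.5 * probs[c].get(st, 0.0) for c in ("STS", "LTS")] for st in states])
    pf = joint.sum(axis=1)
    h_c = 1.0
    h_cond = sum(
        pf[i] * cs.entropy(joint[i] / pf[i]) for i in range(len(states)) if pf[i] > 0
    )
    return h_c - h_cond


class TestPeptideGenerator:
    def test_reproducible_and_positive(self):
        cfg = cs.ProteomicsSimConfig(n_proteins=10, seed=5)
        t1, tr1 = cs.generate_peptide_data(cfg)
        t2, tr2 = cs.generate_peptide_data(cfg)
        pd.testing.assert_frame_equal(t1.intensities, t2.intensities)
        assert (t1.intensities.fillna(1.0) > 0).all().all()

    def test_zero_missingness_impute_identity(self):
        cfg = cs.ProteomicsSimConfig(n_proteins=10, missing_rate=0.0, seed=6)
        table, _ = cs.generate_peptide_data(cfg)
        out = cs.impute_missing_by_group_median(table)
        pd.testing.assert_frame_equal(out.intensities, table.intensities)

    def test_group_dependent_missingness(self):
        cfg = cs.ProteomicsSimConfig(
            n_proteins=60, missing_rate={"STS": 0.3, "LTS": 0.05}, seed=7
        )
        table, _ = cs.generate_peptide_data(cfg)
        miss_sts = table.intensities[table.samples_in("STS")].isna().to_numpy().mean()
        miss_lts = table.intensities[table.samples_in("LTS")].isna().to_numpy().mean()
        assert miss_sts > miss_lts

    def test_planted_effect_power(self):
        """A 1.5-sd planted effect is flagged significant in >= 90% of
        simulated proteins."""
        cfg = cs.ProteomicsSimConfig(
            n_proteins=100,
            effects={f"P{i:04d}": 1.5 for i in range(100)},
            seed=8,
        )
        table, _ = cs.generate_peptide_data(cfg)
        de = cs.run_de_analysis(table)
        assert de["significant"].mean() >= 0.9

    def test_invalid_rate_rejected(self):
        with pytest.raises(ConfigError):
            cs.ProteomicsSimConfig(missing_rate=1.2)


class TestCentroidGenerator:
    def test_zero_noise_perfect_assignment(self):
        cents, expr, labels = cs.generate_centroid_data(
            n_genes=100, n_samples=12, noise_sd=0.0, seed=1
        )
        pre = cs.preprocess_for_centroids(expr)
        out = cs.assign_subtypes(pre, cents)
        assert (out["subtype"] == labels).all()

    def test_moderate_noise_high_accuracy_at_panel_scale(self):
        cents, expr, labels = cs.generate_centroid_data(
            n_genes=840, n_samples=30, noise_sd=0.5, seed=2
        )
        pre = cs.preprocess_for_centroids(expr)
        out = cs.assign_subtypes(pre, cents)
        assert (out["subtype"] == labels).mean() > 0.9

    def test_large_noise_near_chance(self):
        accs = []
        for seed in range(5):
            cents, expr, labels = cs.generate_centroid_data(
                n_genes=60, n_samples=40, noise_sd=50.0, seed=seed
            )
            pre = cs.preprocess_for_centroids(expr)
            out = cs.assign_subtypes(pre, cents)
            accs.append((out["subtype"] == labels).mean())
        assert abs(np.mean(accs) - 0.25) < 0.15
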