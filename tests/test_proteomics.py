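import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

import cranesig as cs


def _table(values, groups=None, protein_map=None):
    """values: dict peptide -> list over samples."""
    df = pd.DataFrame(values).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    n = df.shape[1]
    if groups is None:
        groups = pd.Series(["STS"] * (n // 2) + ["LTS"] * (n - n // 2), index=df.columns)
    if protein_map is None:
        protein_map = pd.Series({p: "PROT" for p in df.index})
    return cs.PeptideTable(df, protein_map, groups)


class TestImputation:
    def test_group_median_fill(self):
        t = _table({"p": [1, 2, np.nan, 4, 7, 8, 9, 10]})
        out = cs.impute_missing_by_group_median(t)
        assert out.intensities.at["p", "s2"] == 2.0  # median of 1,2,4

    def test_fully_missing_group_dropped(self):
        t = _table({"p": [1, 2, 3, 4, np.nan, np.nan, np.nan, np.nan],
                    "q": [1, 2, 3, 4, 5, 6, 7, 8]})
        out = cs.impute_missing_by_group_median(t)
        assert list(out.intensities.index) == ["q"]
        assert out.n_dropped_peptides == 1

    def test_complete_table_identity(self, rng):
        t = _table({"p": rng.random(8), "q": rng.random(8)})
        out = cs.impute_missing_by_group_median(t)
        pd.testing.assert_frame_equal(out.intensities, t.intensities)


class TestNormalization:
    def test_mean_zero_sd_one(self, rng):
        t = _table({f"p{i}": rng.random(16) * 10 for i in range(5)})
        out = cs.standard_normalize_peptides(t)
        assert np.allclose(out.intensities.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(out.intensities.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_zero_sum_group_mean_law(self, rng):
        """10 STS + 6 LTS: normalized group means satisfy
        10*m_STS + 6*m_LTS = 0 for every protein."""
        groups = pd.Series(["STS"] * 10 + ["LTS"] * 6, index=[f"s{i}" for i in range(16)])
        t = _table({f"p{i}": rng.random(16) * 5 + 10 for i in range(8)}, groups=groups)
        out = cs.standard_normalize_peptides(t)
        sts = out.intensities[out.samples_in("STS")].to_numpy().mean()
        lts = out.intensities[out.samples_in("LTS")].to_numpy().mean()
        assert 10 * sts + 6 * lts == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_dropped(self, rng):
        t = _table({"flat": [3.0] * 8, "ok": rng.random(8)})
        with pytest.warns(UserWarning, match="zero-variance"):
            out = cs.standard_normalize_peptides(t)
        assert list(out.intensities.index) == ["ok"]

    def test_missing_values_rejected(self):
        t = _table({"p": [1, 2, np.nan, 4, 5, 6, 7, 8]})
        with pytest.raises(ValueError, match="imputation"):
            cs.standard_normalize_peptides(t)


class TestMixedModel:
    def test_single_peptide_equals_ols_lrt(self, rng):
        """For one peptide the LRT must match the closed-form Gaussian
        likelihood-ratio of the two-group linear model."""
        y = rng.normal(size=16) + np.r_[np.zeros(10), np.full(6, 0.8)]
        groups = pd.Series(["STS"] * 10 + ["LTS"] * 6, index=[f"s{i}" for i in range(16)])
        Y = pd.DataFrame([y], index=["pep"], columns=groups.index)
        eff, p, conv = cs.fit_protein_mixed_model(Y, groups)
        rss1 = (
            ((y[:10] - y[:10].mean()) ** 2).sum() + ((y[10:] - y[10:].mean()) ** 2).sum()
        )
        rss0 = ((y - y.mean()) ** 2).sum()
        lr = 16 * np.log(rss0 / rss1)
        assert p == pytest.approx(chi2.sf(lr, 1), rel=1e-9)
        assert eff == pytest.approx(y[10:].mean() - y[:10].mean(), rel=1e-9)

    def test_balanced_effect_estimate_is_group_mean_difference(self, rng):
        groups = pd.Series(["STS"] * 8 + ["LTS"] * 8, index=[f"s{i}" for i in range(16)])
        Y = pd.DataFrame(rng.normal(size=(4, 16)), columns=groups.index,
                         index=[f"pep{i}" for i in range(4)])
        eff, _, _ = cs.fit_protein_mixed_model(Y, groups)
        diff = Y[groups.index[8:]].to_numpy().mean() - Y[groups.index[:8]].to_numpy().mean()
        assert eff == pytest.approx(diff, abs=1e-6)

    def test_null_calibration_small(self, rng):
        """Type-I error of the LRT near alpha on null data (scaled run; the
        acceptance suite repeats this at 1000 proteins)."""
        cfg = cs.ProteomicsSimConfig(
            n_proteins=150, peptides_per_protein_mean=6, missing_rate=0.0, seed=77
        )
        table, _ = cs.generate_peptide_data(cfg)
        logint = np.log(table.intensities)
        ps = [
            cs.fit_protein_mixed_model(logint.loc[peps], table.groups)[1]
            for _, peps in table.protein_map.groupby(table.protein_map).groups.items()
        ]
        assert 0.01 <= np.mean(np.array(ps) <= 0.05) <= 0.11


class TestRunDE:
    def test_power_and_false_positives(self):
        ok = 0
        for seed in range(8):
            cfg = cs.ProteomicsSimConfig(
                n_proteins=25,
                effects={f"P{i:04d}": 1.5 for i in range(5)},
                missing_rate=0.1,
                seed=seed,
            )
            table, _ = cs.generate_peptide_data(cfg)
            de = cs.run_de_analysis(table)
            flagged = set(de.loc[de.significant, "protein"])
            planted = {f"P{i:04d}" for i in range(5)}
            if planted <= flagged and len(flagged - planted) <= 3:
                ok += 1
        assert ok >= 6

    def test_alpha_zero_no_flags(self):
        cfg = cs.ProteomicsSimConfig(n_proteins=10, seed=3)
        table, _ = cs.generate_peptide_data(cfg)
        de = cs.run_de_analysis(table, alpha=0.0)
        assert not de["significant"].any()

    def test_ratio_uses_raw_scale(self):
        cfg = cs.ProteomicsSimConfig(n_proteins=5, effects={"P0000": 1.0},
                                     missing_rate=0.0, seed=9)
        table, _ = cs.generate_peptide_data(cfg)
        de = cs.run_de_analysis(table).set_index("protein")
        assert de.loc["P0000", "ratio_lts_sts"] > 1.0
        assert (de["ratio_lts_sts"] > 0).all()

    def test_group_mean_zero_sum_in_results(self):
        cfg = cs.ProteomicsSimConfig(n_proteins=8, seed=21)
        table, _ = cs.generate_peptide_data(cfg)
        de = cs.run_de_analysis(table)
        z = cfg.n_sts * de["sts_mean"] + cfg.n_lts * de["lts_mean"]
        assert np.allclose(z, 0, atol=1e-9)


class TestCART:
    def test_perfectly_separable_single_split(self):
        X = pd.DataFrame({"PROT": [-1.0] * 6 + [1.0] * 6}, index=[f"s{i}" for i in range(12)])
        y = pd.Series(["STS"] * 6 + ["LTS"] * 6, index=X.index)
        tree = cs.fit_cart_classifier(X, y)
        assert len(tree.splits) == 1
        assert tree.performance(X, y)["accuracy"] == 1.0

    def test_depth_zero_majority_stump(self):
        X = pd.DataFrame({"PROT": range(10)}, index=[f"s{i}" for i in range(10)])
        y = pd.Series(["STS"] * 7 + ["LTS"] * 3, index=X.index)
        tree = cs.fit_cart_classifier(X, y, max_depth=0)
        assert (tree.predict(X) == "STS").all()

    def test_and_rule_threshold_recovery(self):
        """Two-protein AND rule on a 10/6 cohort: recovered thresholds near
        the planted ones."""
        recovered = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            t1, t2 = -1.05, 0.50
            # STS: x1 > t1 and x2 < t2; LTS: violate one clause
            x1 = np.r_[t1 + 0.3 + r.random(10), t1 - 0.3 - r.random(6)]
            x2 = np.r_[t2 - 0.3 - r.random(10), t2 + 0.3 + r.random(6)]
            X = pd.DataFrame({"CANX": x1, "MAPK1": x2},
                             index=[f"s{i}" for i in range(16)])
            y = pd.Series(["STS"] * 10 + ["LTS"] * 6, index=X.index)
            tree = cs.fit_cart_classifier(X, y, max_depth=2)
            ths = {s["protein"]: s["threshold"] for s in tree.splits}
            err = min(
                abs(th - (t1 if prot == "CANX" else t2)) for prot, th in ths.items()
            )
            recovered.append(err)
        assert np.median(recovered) < 0.35

    def test_single_class_single_leaf(self):
        X = pd.DataFrame({"PROT": range(6)}, index=[f"s{i}" for i in range(6)])
        y = pd.Series(["STS"] * 6, index=X.index)
        tree = cs.fit_cart_classifier(X, y)
        assert tree.tree is None and tree.majority_class == "STS"


class TestPeptideTableIO:
    def test_long_round_trip(self, rng):
        t = _table({"p1": rng.random(8), "p2": rng.random(8)},
                   protein_map=pd.Series({"p1": "A", "p2": "B"}))
        long = t.to_long()
        t2 = cs.PeptideTable.from_long(long, t.groups)
        pd.testing.assert_frame_equal(
            t.intensities.sort_index(), t2.intensities.sort_index(), check_names=False
        )

    def test_multi_protein_peptide_rejected(self):
        df = pd.DataFrame(
            {
                "peptide": ["p", "p"],
                "protein": ["A", "B"],
                "sample": ["s0", "s1"],
                "intensity": [1.0, 2.0],
            }
        )
        groups = pd.Series({"s0": "STS", "s1": "LTS"})
        with pytest.raises(ValueError, match="multiple proteins"):
            cs.PeptideTable.from_long(df, groups)
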