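"""Differential abundance, odds ratios and random-forest prediction."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from anxmediate import microassoc, synthdata


def _labels(n_ha=60, n_la=60, seed=None):
    idx = [f"m{i}" for i in range(n_ha + n_la)]
    return pd.Series(["HA"] * n_ha + ["LA"] * n_la, index=idx)


class TestFamilyAggregation:
    def test_mass_conserved(self, small_cohort):
        fam = microassoc.family_abundance(small_cohort.abundance, small_cohort.taxonomy)
        assert np.allclose(
            fam.sum(axis=1), small_cohort.abundance.sum(axis=1), atol=1e-12
        )

    def test_unmapped_otu_rejected(self, small_cohort):
        tax = small_cohort.taxonomy.iloc[:-1]
        with pytest.raises(ValueError, match="family"):
            microassoc.family_abundance(small_cohort.abundance, tax)


class TestDifferentialAbundance:
    def test_planted_family_power(self):
        flagged = 0
        for seed in range(20):
            labels = _labels()
            table, tax = synthdata.gen_labeled_abundance(
                labels, {"Ruminococcaceae": 2.0}, n_families=30, n_otus=200, seed=seed
            )
            out = microassoc.differential_abundance(table, labels, "family", tax, fdr=0.1)
            row = out.set_index("taxon").loc["Ruminococcaceae"]
            flagged += int(row["significant"] and row["direction"] == 1)
        assert flagged >= 18  # >= 90% of seeded cohorts

    def test_permuted_labels_control_false_discoveries(self):
        n_false = n_disc = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            labels = _labels()
            table, tax = synthdata.gen_labeled_abundance(
                labels, {"Ruminococcaceae": 2.0}, n_families=30, n_otus=200, seed=seed
            )
            perm = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
            out = microassoc.differential_abundance(table, perm, "family", tax, fdr=0.1)
            n_disc += int(out["significant"].sum())
            n_false += int(out["significant"].sum())  # every discovery is false here
        assert n_false <= max(2, 0.1 * 20 * 30)  # false positives are rare on average

    def test_identical_groups_flag_nothing(self):
        labels = _labels(30, 30)
        base, tax = synthdata.gen_labeled_abundance(
            _labels(30, 0), {}, n_families=10, n_otus=50, seed=0
        )
        table = pd.concat([base, base.set_index(pd.Index([f"m{i}" for i in range(30, 60)]))])
        out = microassoc.differential_abundance(table, labels, "family", tax)
        assert not out["significant"].any()

    def test_unknown_level_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            microassoc.differential_abundance(
                small_cohort.abundance, _labels(), level="genus"
            )


class TestTaxonLogistic:
    def test_planted_direction_gives_or_above_one(self):
        labels = _labels(100, 100)
        table, tax = synthdata.gen_labeled_abundance(
            labels, {"Ruminococcaceae": 1.5, "Bacteroidaceae": -1.5}, seed=5
        )
        out = microassoc.taxon_logistic(
            table, labels, ["Ruminococcaceae", "Bacteroidaceae"], taxonomy=tax
        ).set_index("taxon")
        assert out.loc["Ruminococcaceae", "odds_ratio"] > 1
        assert out.loc["Bacteroidaceae", "odds_ratio"] < 1
        assert (out["q"] < 0.05).all()

    def test_null_confidence_intervals_cover_one(self):
        covered = 0
        for seed in range(30):
            labels = _labels(80, 80)
            table, tax = synthdata.gen_labeled_abundance(
                labels, {}, n_families=5, n_otus=30, seed=seed
            )
            out = microassoc.taxon_logistic(table, labels, ["Family01"], taxonomy=tax)
            covered += int(out["or_lo"].iloc[0] <= 1.0 <= out["or_hi"].iloc[0])
        assert covered >= 25  # nominal 95% coverage

    def test_constant_abundance_rejected(self):
        labels = _labels(10, 10)
        table = pd.DataFrame({"t1": np.full(20, 0.5), "t2": np.linspace(0.1, 0.9, 20)}, index=labels.index)
        with pytest.raises(ValueError, match="constant"):
            microassoc.taxon_logistic(table, labels, ["t1"])


class TestRandomForest:
    def _planted(self, seed=3):
        labels = _labels(100, 100)
        table, tax = synthdata.gen_labeled_abundance(
            labels,
            {"Ruminococcaceae": 2.0, "Bacteroidaceae": -1.5, "Clostridiaceae": 1.0},
            seed=seed,
        )
        return labels, table, tax

    def test_planted_signal_predicts_well(self):
        labels, table, tax = self._planted()
        res = microassoc.rf_predict(
            table, labels, ["Ruminococcaceae", "Bacteroidaceae", "Clostridiaceae"],
            taxonomy=tax, n_trees=200, n_iterations=20, seed=0,
        )
        assert res.auc >= 0.8
        assert res.mean_accuracy >= 0.7

    def test_largest_effect_family_ranks_first(self):
        first = 0
        for seed in range(10):
            labels, table, tax = self._planted(seed)
            res = microassoc.rf_predict(
                table, labels, ["Ruminococcaceae", "Bacteroidaceae", "Clostridiaceae"],
                taxonomy=tax, n_trees=100, n_iterations=10, seed=seed,
            )
            first += int(res.importances.index[0] == "Ruminococcaceae")
        assert first >= 8

    def test_duplicated_feature_leaves_auc_stable(self):
        labels, table, tax = self._planted()
        fam = microassoc.family_abundance(table, tax)
        fam["copy"] = fam["Ruminococcaceae"]
        base = microassoc.rf_predict(
            fam, labels, ["Ruminococcaceae", "Bacteroidaceae"], n_trees=200,
            n_iterations=15, seed=1,
        )
        dup = microassoc.rf_predict(
            fam, labels, ["Ruminococcaceae", "Bacteroidaceae", "copy"], n_trees=200,
            n_iterations=15, seed=1,
        )
        assert abs(base.auc - dup.auc) < 0.05

    def test_too_few_samples_per_class_rejected(self):
        labels = _labels(3, 40)
        table, tax = synthdata.gen_labeled_abundance(labels, {}, n_families=5, n_otus=20, seed=0)
        with pytest.raises(ValueError):
            microassoc.rf_predict(table, labels, ["Family01"], taxonomy=tax)


def test_auc_invariant_under_monotone_transform(rng):
    y = rng.integers(0, 2, 300)
    s = rng.normal(size=300) + y
    a1 = roc_auc_score(y, s)
    for f in (np.exp, np.tanh, lambda v: v**3):
        assert roc_auc_score(y, f(s)) == pytest.approx(a1, abs=1e-12)
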