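"""Consensus clustering, HA/LA assignment and group characterization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from anxmediate import anxclass
from anxmediate.behavior import PHENOTYPE_NAMES
from anxmediate.stats import bh_adjust, mann_whitney


def _pheno_frame(X, cols=("time_light", "n_full_transitions")):
    return pd.DataFrame(X, columns=list(cols))


class TestConsensus:
    def test_perfectly_separable_pairs(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        res = anxclass.consensus_cluster(X, k_max=2, n_resamples=20, seed=0)
        M = res.consensus[2]
        assert M[0, 1] == 1.0 and M[2, 3] == 1.0
        assert M[0, 2] == 0.0 and M[1, 3] == 0.0

    def test_seeded_determinism(self, rng):
        X = rng.normal(size=(40, 3))
        r1 = anxclass.consensus_cluster(X, k_max=3, n_resamples=15, seed=9)
        r2 = anxclass.consensus_cluster(X, k_max=3, n_resamples=15, seed=9)
        for k in r1.ks:
            assert np.array_equal(r1.consensus[k], r2.consensus[k])
            assert np.array_equal(r1.labels[k], r2.labels[k])

    def test_planted_two_cluster_recovery(self, rng):
        truth = np.repeat([0, 1], 50)
        X = rng.normal(size=(100, 4)) + 5.0 * truth[:, None]
        res = anxclass.consensus_cluster(X, k_max=3, n_resamples=40, seed=2)
        assert adjusted_rand_score(truth, res.labels[2]) >= 0.95

    def test_constant_column_rejected(self):
        X = np.column_stack([np.ones(30), np.arange(30.0)])
        with pytest.raises(ValueError, match="constant"):
            anxclass.consensus_cluster(X, k_max=2)

    def test_kmax_below_two_rejected(self, rng):
        with pytest.raises(ValueError):
            anxclass.consensus_cluster(rng.normal(size=(30, 2)), k_max=1)

    def test_permuting_mice_permutes_labels(self, rng):
        truth = np.repeat([0, 1], 25)
        X = rng.normal(size=(50, 3)) + 6.0 * truth[:, None]
        perm = rng.permutation(50)
        r1 = anxclass.consensus_cluster(X, k_max=2, n_resamples=30, seed=4)
        r2 = anxclass.consensus_cluster(X[perm], k_max=2, n_resamples=30, seed=4)
        # partitions agree as partitions (cluster ids may swap)
        assert adjusted_rand_score(r1.labels[2][perm], r2.labels[2]) == 1.0


class TestCdfDeltaArea:
    def _result_with(self, matrices):
        ks = list(range(2, 2 + len(matrices)))
        return anxclass.ConsensusResult(
            ks=ks, consensus=dict(zip(ks, matrices)), labels={}
        )

    def test_binary_consensus_area_is_zero_fraction(self):
        M = np.ones((4, 4))
        M[0, 2] = M[2, 0] = M[0, 3] = M[3, 0] = 0.0
        res = self._result_with([M])
        out = anxclass.cdf_delta_area(res)
        # 2 zero entries of 6 upper-triangle values
        assert out[2][0] == pytest.approx(2 / 6)

    def test_all_ones_consensus_has_zero_area(self):
        res = self._result_with([np.ones((5, 5))])
        assert anxclass.cdf_delta_area(res)[2][0] == 0.0

    def test_identical_matrices_give_zero_delta(self, rng):
        M = rng.uniform(size=(6, 6))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        res = self._result_with([M, M.copy()])
        out = anxclass.cdf_delta_area(res)
        assert out[3][1] == pytest.approx(0.0)


class TestAssignAnxiety:
    def _result(self, labels):
        return anxclass.ConsensusResult(ks=[2], consensus={}, labels={2: np.asarray(labels)})

    def test_low_time_in_light_is_high_anxiety(self):
        pheno = _pheno_frame([[40.0, 3], [42.0, 3], [120.0, 9], [118.0, 9]])
        out = anxclass.assign_anxiety(self._result([0, 0, 1, 1]), pheno)
        assert out.tolist() == ["HA", "HA", "LA", "LA"]

    def test_tie_broken_on_full_transitions(self):
        pheno = _pheno_frame([[80.0, 2], [80.0, 2], [80.0, 10], [80.0, 10]])
        out = anxclass.assign_anxiety(self._result([0, 0, 1, 1]), pheno)
        assert out.tolist() == ["HA", "HA", "LA", "LA"]

    def test_empty_cluster_rejected(self):
        pheno = _pheno_frame([[1.0, 1], [2.0, 2]])
        with pytest.raises(ValueError):
            anxclass.assign_anxiety(self._result([0, 0]), pheno)

    def test_moving_one_mouse_changes_only_its_label(self, rng):
        truth = np.repeat([0, 1], 20)
        X = rng.normal(size=(40, 4)) + 6.0 * truth[:, None]
        r1 = anxclass.consensus_cluster(X, k_max=2, n_resamples=30, seed=1)
        X2 = X.copy()
        X2[0] = X[-1] + rng.normal(scale=0.1, size=4)  # move mouse 0 across
        r2 = anxclass.consensus_cluster(X2, k_max=2, n_resamples=30, seed=1)
        a = pd.Series(r1.labels[2]).map({r1.labels[2][1]: "A"}).fillna("B")
        b = pd.Series(r2.labels[2]).map({r2.labels[2][1]: "A"}).fillna("B")
        assert (a[1:] == b[1:]).all()
        assert a[0] != b[0]


class TestGroupTests:
    def test_exact_small_sample_p(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_groups_are_null(self):
        vals = np.tile(np.arange(10.0), 2)
        pheno = pd.DataFrame({c: vals for c in PHENOTYPE_NAMES})
        labels = pd.Series(["HA"] * 10 + ["LA"] * 10, index=pheno.index)
        out = anxclass.group_tests(pheno, labels)
        assert (out["p"] > 0.9).all()
        assert not (out["q"] < 0.5).any()

    def test_tiny_group_rejected(self):
        pheno = pd.DataFrame({c: np.arange(5.0) for c in PHENOTYPE_NAMES})
        labels = pd.Series(["HA"] + ["LA"] * 4, index=pheno.index)
        with pytest.raises(ValueError):
            anxclass.group_tests(pheno, labels)

    def test_bh_worked_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.5])


def _brute_force_bh(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        q[i] = running_min
    return q


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=15))
def test_bh_matches_brute_force_definition(pvals):
    assert np.allclose(bh_adjust(pvals), _brute_force_bh(pvals), atol=1e-12)


class TestMultivariateLogit:
    def _cohort(self, rng, informative=True, n=400):
        X = rng.normal(size=(n, 7))
        eta = 1.6 * X[:, 2] if informative else np.zeros(n)
        y = np.where(rng.random(n) < 1 / (1 + np.exp(-eta)), "HA", "LA")
        pheno = pd.DataFrame(X, columns=list(PHENOTYPE_NAMES))
        return pheno, pd.Series(y, index=pheno.index)

    def test_single_informative_phenotype_detected(self):
        rng = np.random.default_rng(11)
        wins = 0
        for _ in range(30):
            pheno, labels = self._cohort(rng)
            out = anxclass.multivariate_logit(pheno, labels).set_index("phenotype")
            others = out.drop(index=["intercept", "time_light"])
            if out.loc["time_light", "p"] < 0.01 and (others["p"] < 0.01).sum() == 0:
                wins += 1
        assert wins >= 24  # >= 80% of replicates isolate the planted signal

    def test_null_phenotypes_hold_type_one_error(self):
        rng = np.random.default_rng(13)
        rejections, total = 0, 0
        for _ in range(100):
            pheno, labels = self._cohort(rng, informative=False, n=200)
            out = anxclass.multivariate_logit(pheno, labels)
            rejections += int((out["p"].iloc[1:] < 0.05).sum())
            total += 7
        rate = rejections / total
        assert 0.02 <= rate <= 0.09

    def test_duplicated_column_is_rank_deficient(self, rng):
        pheno, labels = self._cohort(rng)
        pheno["n_full_transitions"] = pheno["time_light"]
        with pytest.raises(ValueError, match="rank"):
            anxclass.multivariate_logit(pheno, labels)
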