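"""Mediation estimator: probit fit, effect composition, screening, scan."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from anxmediate import mediation, microassoc
from anxmediate.genassoc import ALLELE_A, ALLELE_B, GenotypeMatrix
from anxmediate.mediation import (
    assign_loci,
    closed_form_acme,
    fit_mediation,
    probit_fit,
    screen_pairs,
)


def _simulate_triple(n, alpha1=1.0, beta1=0.0, beta2=1.0, sigma=1.0, seed=0):
    rng = np.random.default_rng(seed)
    t = rng.integers(0, 2, n).astype(float)
    m = alpha1 * t + sigma * rng.standard_normal(n)
    y = (rng.standard_normal(n) < beta1 * t + beta2 * m).astype(float)
    return t, m, y


class TestProbitFit:
    def test_matches_statsmodels(self, rng):
        for _ in range(5):
            X = np.column_stack([np.ones(300), rng.normal(size=(300, 2))])
            beta = rng.normal(size=3)
            y = (rng.standard_normal(300) < X @ beta).astype(float)
            mine = probit_fit(X, y)
            ref = sm.Probit(y, X).fit(disp=0)
            assert mine.converged
            assert np.allclose(mine.params, ref.params, atol=1e-5)

    def test_separation_flagged(self):
        x = np.linspace(-1, 1, 50)
        X = np.column_stack([np.ones(50), x])
        y = (x > 0).astype(float)
        assert not probit_fit(X, y).converged


class TestClosedForm:
    def test_worked_value(self):
        from scipy.special import ndtr

        expected = float(ndtr(1 / np.sqrt(2)) - ndtr(0.0))
        assert closed_form_acme(0, 1, 1, 0, 0, 1) == pytest.approx(expected)
        assert expected == pytest.approx(0.2602, abs=1e-4)

    def test_no_mediator_effect_means_zero(self):
        assert closed_form_acme(0, 1, 1, 0, 0.5, 0) == 0.0


class TestFitMediation:
    def test_decomposition_is_exact(self):
        t, m, y = _simulate_triple(500, seed=1)
        res = fit_mediation(t, m, y, n_boot=50, seed=2)
        assert abs(res.total - (res.acme + res.ade)) < 1e-12

    def test_point_estimate_near_closed_form(self):
        t, m, y = _simulate_triple(4000, seed=3)
        res = fit_mediation(t, m, y, n_boot=50, seed=4)
        assert res.acme == pytest.approx(closed_form_acme(0, 1, 1, 0, 0, 1), abs=0.04)

    def test_no_direct_path_centers_ade_at_zero(self):
        t, m, y = _simulate_triple(3000, beta1=0.0, seed=5)
        res = fit_mediation(t, m, y, n_boot=100, seed=6)
        assert abs(res.ade) < 0.05
        assert res.ade_ci[0] <= 0.0 <= res.ade_ci[1]

    def test_deterministic_given_seed(self):
        t, m, y = _simulate_triple(400, seed=7)
        r1 = fit_mediation(t, m, y, n_boot=80, seed=8)
        r2 = fit_mediation(t, m, y, n_boot=80, seed=8)
        assert r1.acme == r2.acme and r1.acme_ci == r2.acme_ci and r1.p_acme == r2.p_acme

    def test_p_value_floor(self):
        t, m, y = _simulate_triple(2000, beta2=1.5, seed=9)
        res = fit_mediation(t, m, y, n_boot=99, seed=10)
        assert res.p_acme >= 1.0 / (res.n_boot + 1)

    def test_cage_bootstrap_runs(self):
        t, m, y = _simulate_triple(200, seed=11)
        cage = np.repeat(np.arange(50), 4)
        res = fit_mediation(t, m, y, n_boot=60, seed=12, cage=cage, cage_bootstrap=True)
        assert np.isfinite(res.acme)

    @pytest.mark.parametrize(
        "t, y, msg",
        [
            (np.array([0.0, 2.0, 1.0, 0.0]), np.array([0.0, 1.0, 0.0, 1.0]), "0/1"),
            (np.zeros(4), np.array([0.0, 1.0, 0.0, 1.0]), "treatment"),
            (np.array([0.0, 1.0, 0.0, 1.0]), np.ones(4), "outcome"),
        ],
    )
    def test_invalid_inputs_rejected(self, t, y, msg):
        with pytest.raises(ValueError, match=msg):
            fit_mediation(t, np.arange(len(t), dtype=float), y, n_boot=10, seed=0)


class TestScreenPairs:
    def _toy(self):
        # 4 strains x 2 snps; snp0 tracks the mediator family, snp1 does not
        alleles = np.array(
            [[ALLELE_B, ALLELE_A], [ALLELE_B, ALLELE_A], [ALLELE_A, ALLELE_B], [ALLELE_A, ALLELE_B]],
            dtype=np.int8,
        )
        G = GenotypeMatrix(
            alleles=alleles,
            strains=["S0", "S1", "S2", "S3"],
            snp_ids=np.array(["snp0", "snp1"]),
            chrom=np.array(["chr1", "chr2"]),
            pos=np.array([100, 200]),
        )
        rng = np.random.default_rng(0)
        mice = [f"m{i}" for i in range(200)]
        strain = pd.Series([f"S{i % 4}" for i in range(200)], index=mice)
        t0 = (strain.map({"S0": 1, "S1": 1, "S2": 0, "S3": 0})).to_numpy()
        fam = pd.DataFrame(
            {"famX": 3.0 * t0 + rng.standard_normal(200) * 0.3,
             "famNull": rng.standard_normal(200)},
            index=mice,
        )
        return G, fam, strain

    def test_intersection_and_null_exclusion(self):
        G, fam, strain = self._toy()
        pairs = screen_pairs(G, fam, ["snp0", "snp1"], ["famX", "famNull"], strain)
        kept = set(zip(pairs["snp_id"], pairs["taxon"]))
        assert ("snp0", "famX") in kept
        assert ("snp0", "famNull") not in kept
        # snp1 is anti-correlated with famX, so it may associate, but a SNP
        # not in the anxiety hit list must never appear
        pairs2 = screen_pairs(G, fam, ["snp1"], ["famX", "famNull"], strain)
        assert "snp0" not in set(pairs2["snp_id"])


class TestLoci:
    def test_windowing(self):
        snps = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr1", "chr2"], "pos": [100_000, 110_000, 2_000_000, 100_000]}
        )
        loci = assign_loci(snps, window_bp=1_000_000)
        assert loci.iloc[0] == loci.iloc[1]
        assert loci.iloc[2] != loci.iloc[0]
        assert loci.iloc[3] != loci.iloc[2]


class TestScanOnPlantedCohort:
    def test_planted_pairs_recovered(self, small_cohort):
        coh = small_cohort
        labels = coh.truth.true_label
        som = coh.mice.set_index("mouse_id")["strain"]
        fam_table = microassoc.family_abundance(coh.abundance, coh.taxonomy)
        causal_snps = [b["snp_ids"][0] for b in coh.truth.causal_blocks]
        fams = sorted(coh.truth.mediator_families())
        pairs = screen_pairs(coh.genotypes, fam_table, causal_snps, fams, som)
        assert len(pairs) > 0
        med = mediation.mediation_scan(
            pairs, coh.genotypes, fam_table, labels, som, n_boot=400, seed=0
        )
        sig = med[med["significant"]]
        assert set(sig["taxon"]) == set(fams)

    def test_empty_pairs_give_empty_frame(self, small_cohort):
        coh = small_cohort
        som = coh.mice.set_index("mouse_id")["strain"]
        fam_table = microassoc.family_abundance(coh.abundance, coh.taxonomy)
        out = mediation.mediation_scan(
            pd.DataFrame(columns=["snp_id", "taxon", "screen_p"]),
            coh.genotypes, fam_table, coh.truth.true_label, som,
        )
        assert len(out) == 0
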