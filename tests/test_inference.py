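"""Model assembly, eigen-designs, Gibbs sampler behavior, prediction."""

import numpy as np
import pytest

from hybridgp import (
    ChainConfig,
    MODEL_CODES,
    assemble_model,
    eigen_design,
    gibbs_fit,
    predict_hybrids,
    summarize_fit,
)
from hybridgp.data import PhenotypeTable
from hybridgp.kinship import KinshipMatrix
from hybridgp.simulate import SimConfig, simulate_study


def _study(**kw):
    base = dict(
        n1=25, n2=20, nsnp=300, design="incomplete", n_hybrids=350, seed=1,
        var_A1=0.0, var_A2=0.0, var_D=0.0, var_AA11=0.0, var_AA22=0.0,
        var_AA12=0.0, var_r1=0.0, var_r2=0.0, var_e=1.0, mu=0.0,
    )
    base.update(kw)
    return simulate_study(SimConfig(**base))


class TestEigenDesign:
    def test_identity_reproduces_itself(self):
        K = KinshipMatrix("D", "hybrids", np.eye(6), 1.0, [f"h{i}" for i in range(6)])
        B = eigen_design(K, ridge=0.0, tol=0.0)
        np.testing.assert_allclose(B @ B.T, np.eye(6), atol=1e-12)

    def test_rank_one_keeps_single_column(self):
        v = np.array([1.0, 2.0, -1.0])
        K = KinshipMatrix("D", "hybrids", np.outer(v, v), 1.0, list("abc"))
        B = eigen_design(K, ridge=0.0)
        assert B.shape[1] == 1
        np.testing.assert_allclose(np.abs(B[:, 0] / np.linalg.norm(B)), np.abs(v) / np.linalg.norm(v))

    def test_reconstruction_of_random_psd(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 30))
        K = KinshipMatrix("D", "hybrids", X @ X.T, 1.0, [f"h{i}" for i in range(20)])
        B = eigen_design(K, tol=0.0)
        assert np.max(np.abs(B @ B.T - K.values)) < 2e-8  # ridge-order only

    def test_mapped_design_covers_line_structure(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((5, 9))
        K = X @ X.T
        T = np.zeros((8, 5))
        T[np.arange(8), rng.integers(0, 5, 8)] = 1.0
        B = eigen_design(K, T)
        np.testing.assert_allclose(B @ B.T, T @ K @ T.T, atol=2e-7)


class TestModelAssembly:
    @pytest.mark.parametrize("code,expected", [
        ("GCA:A", ["A1", "A2", "r1", "r2"]),
        ("GCA:ADAA11AA22AA12", ["A1", "A2", "D", "AA11", "AA22", "AA12", "r1", "r2"]),
        ("G:ADHAAH", ["AH", "DH", "AAH"]),
    ])
    def test_term_menus(self, small_study, code, expected):
        with_r = code.startswith("GCA:")
        M = assemble_model(
            small_study["g1"], small_study["g2"], small_study["pedigree"],
            code, with_r=with_r,
        )
        assert [t.name for t in M.terms] == expected

    def test_r_terms_rejected_for_g_models(self, small_study):
        with pytest.raises(ValueError, match="GCA"):
            assemble_model(small_study["g1"], small_study["g2"],
                           small_study["pedigree"], "G:A", with_r=True)

    def test_unknown_code_rejected(self, small_study):
        with pytest.raises(KeyError):
            assemble_model(small_study["g1"], small_study["g2"],
                           small_study["pedigree"], "GCA:X", with_r=False)


class TestGibbs:
    def test_same_seed_reproduces_samples_exactly(self, small_study):
        M = assemble_model(small_study["g1"], small_study["g2"],
                           small_study["pedigree"], "GCA:AD", with_r=True)
        chain = ChainConfig(n_iter=400, burn_in=200, thin=2, seed=9)
        y = small_study["phenotypes"]
        S1 = gibbs_fit(y, M, chain)
        S2 = gibbs_fit(y, M, chain)
        for k in S1.variance_samples:
            np.testing.assert_array_equal(S1.variance_samples[k], S2.variance_samples[k])
        np.testing.assert_array_equal(S1.mu_samples, S2.mu_samples)

    def test_pure_noise_leaves_genetic_variances_small(self):
        s = _study(n_hybrids=500)
        M = assemble_model(s["g1"], s["g2"], s["pedigree"], "GCA:AD", with_r=True)
        chain = ChainConfig(n_iter=2500, burn_in=1000, thin=3, seed=5)
        summ = summarize_fit(gibbs_fit(s["phenotypes"], M, chain), M, s["phenotypes"])
        for t in ("A1", "A2", "D", "r1", "r2"):
            assert summ.variances[t][0] < 0.15
        assert 0.85 <= summ.variances["residual"][0] <= 1.15
        assert 0.0 <= summ.H2_mean <= 1.0

    def test_nonfinite_phenotypes_rejected(self, small_study):
        M = assemble_model(small_study["g1"], small_study["g2"],
                           small_study["pedigree"], "GCA:A", with_r=False)
        y = small_study["phenotypes"]
        bad = PhenotypeTable(list(y.hybrid_ids), np.full(y.n, np.nan))
        with pytest.raises(ValueError, match="non-finite"):
            gibbs_fit(bad, M, ChainConfig(200, 100, 1, 0))

    def test_unmapped_hybrid_rejected(self, small_study):
        M = assemble_model(small_study["g1"], small_study["g2"],
                           small_study["pedigree"], "GCA:A", with_r=False)
        bad = PhenotypeTable(["nope"], np.array([1.0]))
        with pytest.raises(KeyError, match="nope"):
            gibbs_fit(bad, M, ChainConfig(200, 100, 1, 0))

    def test_clamped_variances_have_zero_posterior_sd(self, small_study):
        M = assemble_model(small_study["g1"], small_study["g2"],
                           small_study["pedigree"], "GCA:A", with_r=False)
        fixed = {"A1": 2.0, "A2": 1.0, "residual": 5.0}
        S = gibbs_fit(small_study["phenotypes"], M, ChainConfig(400, 200, 2, 3),
                      fixed_variances=fixed)
        summ = summarize_fit(S, M, small_study["phenotypes"])
        for name, value in fixed.items():
            mean, sd = summ.variances[name]
            assert mean == value and sd == 0.0


class TestBlupEquivalence:
    def test_posterior_mean_matches_henderson_solution(self):
        """At clamped variances the Gibbs posterior mean of genetic values is
        the GLS/mixed-model-equations BLUP."""
        s = _study(n1=30, n2=25, nsnp=400, n_hybrids=300, seed=5,
                   var_A1=20.0, var_A2=10.0, var_D=3.0, var_r1=2.0, var_r2=2.0,
                   var_e=10.0, mu=50.0)
        M = assemble_model(s["g1"], s["g2"], s["pedigree"], "GCA:AD", with_r=True)
        fixed = {"A1": 20.0, "A2": 10.0, "D": 3.0, "r1": 2.0, "r2": 2.0, "residual": 10.0}
        chain = ChainConfig(n_iter=6000, burn_in=2000, thin=2, seed=11)
        S = gibbs_fit(s["phenotypes"], M, chain, fixed_variances=fixed)
        g_gibbs = sum(S.effect_means[t.name] for t in M.terms)

        n = M.n_hybrids
        V = fixed["residual"] * np.eye(n)
        C = np.zeros((n, n))
        for t in M.terms:
            K = t.design @ t.design.T * fixed[t.name]
            V += K
            C += K
        yv = s["phenotypes"].values
        ones = np.ones(n)
        Vi = np.linalg.inv(V)
        mu_gls = (ones @ Vi @ yv) / (ones @ Vi @ ones)
        g_blup = C @ Vi @ (yv - mu_gls * ones)
        assert np.corrcoef(g_gibbs, g_blup)[0, 1] > 0.999


class TestPrediction:
    def test_duplicate_design_rows_predict_identically(self):
        """Two hybrids from the same parents share every design row, hence
        the same prediction."""
        from hybridgp.data import HybridPedigree

        s = _study(n1=10, n2=8, nsnp=150, n_hybrids=60, seed=8, var_A1=5.0, var_e=1.0)
        ped = s["pedigree"]
        dup = HybridPedigree(
            ped.hybrid_ids + ["HDUP"],
            {**ped.parent1, "HDUP": ped.parent1[ped.hybrid_ids[0]]},
            {**ped.parent2, "HDUP": ped.parent2[ped.hybrid_ids[0]]},
        )
        M = assemble_model(s["g1"], s["g2"], dup, "GCA:A", with_r=True)
        S = gibbs_fit(s["phenotypes"], M, ChainConfig(800, 400, 2, 1))
        pred = predict_hybrids(S, M, [ped.hybrid_ids[0], "HDUP"])
        assert pred.iloc[0] == pytest.approx(pred.iloc[1], abs=1e-10)

    def test_near_interpolation_with_saturated_additive_model(self):
        """Strong additive signal and tiny noise: training predictions track
        the observations."""
        s = _study(n1=20, n2=15, nsnp=400, design="complete", seed=4,
                   var_A1=20.0, var_A2=10.0, var_e=0.01, mu=10.0)
        M = assemble_model(s["g1"], s["g2"], s["pedigree"], "GCA:A", with_r=True)
        S = gibbs_fit(s["phenotypes"], M, ChainConfig(2000, 1000, 2, 2))
        pred = predict_hybrids(S, M, s["pedigree"].hybrid_ids)
        r = np.corrcoef(pred.to_numpy(), s["phenotypes"].values)[0, 1]
        assert r > 0.99

    def test_absent_hybrid_rejected(self, small_study):
        M = assemble_model(small_study["g1"], small_study["g2"],
                           small_study["pedigree"], "GCA:A", with_r=False)
        S = gibbs_fit(small_study["phenotypes"], M, ChainConfig(200, 100, 2, 0))
        with pytest.raises(KeyError):
            predict_hybrids(S, M, ["missing-hybrid"])


class TestSummaries:
    def test_gca_sca_aggregates_from_posterior_means(self, small_study):
        M = assemble_model(small_study["g1"], small_study["g2"],
                           small_study["pedigree"], "GCA:ADAA11AA22AA12", with_r=True)
        S = gibbs_fit(small_study["phenotypes"], M, ChainConfig(600, 300, 3, 4))
        summ = summarize_fit(S, M, small_study["phenotypes"])
        want_gca1 = (summ.variances["A1"][0] + summ.variances["AA11"][0]
                     + summ.variances["r1"][0])
        assert summ.aggregates["GCA1"] == pytest.approx(want_gca1)
        want_sca = summ.variances["D"][0] + summ.variances["AA12"][0]
        assert summ.aggregates["SCA"] == pytest.approx(want_sca)
        assert 0.0 <= summ.H2_mean <= 1.0
        assert np.isfinite(summ.dic)

    def test_all_model_codes_assemble(self, small_study):
        for code in MODEL_CODES:
            M = assemble_model(small_study["g1"], small_study["g2"],
                               small_study["pedigree"], code,
                               with_r=code.startswith("GCA:"))
            assert len(M.terms) >= 1
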