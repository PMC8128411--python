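"""Relationship matrices: printed scalings, Hadamard identities, PSD structure."""

import numpy as np
import pytest

from hybridgp import (
    LineGenotypes,
    compute_allele_freqs,
    center_line_genotypes,
    build_parent_incidence,
    build_dominance_incidence,
    derive_hybrid_genotypes,
    noia_codings,
    additive_kinship,
    vanraden1_kinship,
    dominance_kinship,
    epistatic_within,
    epistatic_across,
    epistatic_with_dominance,
    gmodel_kinships,
    kinship_summary,
)
from hybridgp.encoding import AdditiveCoding


def _random_group(rng, n, m, label="g"):
    calls = (rng.random((n, m)) < rng.uniform(0.1, 0.9, m)).astype(float)
    return LineGenotypes(label, [f"{label}{i}" for i in range(n)], [f"m{j}" for j in range(m)], calls)


class TestAdditive:
    def test_two_line_hand_example(self, tiny_two_line):
        g, f, z = tiny_two_line
        GA = additive_kinship(z, f)
        # Z = (0.5, -0.5), sum pq = 0.25
        np.testing.assert_allclose(GA.values, [[1, -1], [-1, 1]])
        assert GA.scale_constant == pytest.approx(0.25)

    def test_mean_diag_one_and_mean_zero(self):
        rng = np.random.default_rng(2)
        g = _random_group(rng, 30, 200)
        f = compute_allele_freqs(g)
        GA = additive_kinship(center_line_genotypes(g, f), f)
        assert np.mean(np.diag(GA.values)) == pytest.approx(1.0, abs=1e-12)
        assert np.mean(GA.values) == pytest.approx(0.0, abs=1e-12)

    def test_all_fixed_markers_rejected(self):
        g = LineGenotypes("g", ["a", "b"], ["m1"], np.ones((2, 1)))
        f = compute_allele_freqs(g)
        with pytest.raises(ValueError, match="fixed"):
            additive_kinship(center_line_genotypes(g, f), f)


class TestVanRaden:
    def test_equals_twice_additive(self, tiny_two_line):
        g, f, z = tiny_two_line
        GVR = vanraden1_kinship(g, f)
        np.testing.assert_allclose(GVR.values, [[2, -2], [-2, 2]])

    def test_factor_two_on_random_panel(self):
        rng = np.random.default_rng(7)
        g = _random_group(rng, 30, 200)
        f = compute_allele_freqs(g)
        GA = additive_kinship(center_line_genotypes(g, f), f)
        GVR = vanraden1_kinship(g, f)
        assert np.max(np.abs(GVR.values - 2 * GA.values)) < 1e-12
        # halved, it is the coancestry-scaled matrix: equal to G_A
        np.testing.assert_allclose(GVR.values / 2, GA.values, atol=1e-12)


class TestDominance:
    def test_2x2_factorial_hand_example(self, factorial_2x2):
        g1, g2, ped = factorial_2x2
        f1, f2 = compute_allele_freqs(g1), compute_allele_freqs(g2)
        W = build_dominance_incidence(
            center_line_genotypes(g1, f1), center_line_genotypes(g2, f2), ped
        )
        np.testing.assert_allclose(W.W[:, 0], [-0.5, 0.5, 0.5, -0.5])
        D = dominance_kinship(W, f1, f2)
        sign = np.array([[1, -1, -1, 1], [-1, 1, 1, -1], [-1, 1, 1, -1], [1, -1, -1, 1]])
        np.testing.assert_allclose(D.values, sign)
        assert D.scale_constant == pytest.approx(0.25)

    def test_complete_factorial_mean_diag_exactly_one(self, small_study):
        g1, g2, ped = small_study["g1"], small_study["g2"], small_study["pedigree"]
        f1, f2 = compute_allele_freqs(g1), compute_allele_freqs(g2)
        W = build_dominance_incidence(
            center_line_genotypes(g1, f1), center_line_genotypes(g2, f2), ped
        )
        D = dominance_kinship(W, f1, f2)
        assert np.mean(np.diag(D.values)) == pytest.approx(1.0, abs=1e-10)
        assert np.mean(D.values) == pytest.approx(0.0, abs=1e-10)

    def test_incomplete_factorial_still_psd_symmetric(self):
        rng = np.random.default_rng(12)
        g1 = _random_group(rng, 10, 60, "d")
        g2 = _random_group(rng, 8, 60, "f")
        from hybridgp import HybridPedigree

        pairs = [(i, j) for i in range(10) for j in range(8)]
        rng.shuffle(pairs)
        pairs = pairs[:40]
        hybrids = [f"H{k}" for k in range(40)]
        ped = HybridPedigree(
            hybrids,
            {h: f"d{i}" for h, (i, j) in zip(hybrids, pairs)},
            {h: f"f{j}" for h, (i, j) in zip(hybrids, pairs)},
        )
        f1, f2 = compute_allele_freqs(g1), compute_allele_freqs(g2)
        W = build_dominance_incidence(
            center_line_genotypes(g1, f1), center_line_genotypes(g2, f2), ped
        )
        D = dominance_kinship(W, f1, f2)
        np.testing.assert_allclose(D.values, D.values.T)
        s = kinship_summary(D)
        assert s["min_eigenvalue"] >= -1e-8 * s["max_eigenvalue"]


class TestEpistatic:
    def test_within_hand_example(self):
        from hybridgp.kinship import KinshipMatrix

        GA = KinshipMatrix("GA1", "lines1", np.array([[1.0, -1.0], [-1.0, 1.0]]), 1.0, ["a", "b"])
        GAA = epistatic_within(GA)
        np.testing.assert_allclose(GAA.values, np.ones((2, 2)))

    def test_kronecker_coding_identity(self):
        """Z11 Z11' equals (Z Z') . (Z Z') with Z11 built explicitly."""
        rng = np.random.default_rng(4)
        g = _random_group(rng, 5, 4)
        f = compute_allele_freqs(g)
        Z = center_line_genotypes(g, f).Z
        Z11 = np.stack([np.kron(Z[i], Z[i]) for i in range(5)])
        lhs = Z11 @ Z11.T
        rhs = (Z @ Z.T) * (Z @ Z.T)
        np.testing.assert_allclose(lhs, rhs, atol=1e-13)

    def test_across_matches_loop_oracle(self, small_study):
        g1, g2, ped = small_study["g1"], small_study["g2"], small_study["pedigree"]
        f1, f2 = compute_allele_freqs(g1), compute_allele_freqs(g2)
        GA1 = additive_kinship(center_line_genotypes(g1, f1), f1, 1)
        GA2 = additive_kinship(center_line_genotypes(g2, f2), f2, 2)
        T1 = build_parent_incidence(ped, g1, 1)
        T2 = build_parent_incidence(ped, g2, 2)
        GAA12 = epistatic_across(GA1, GA2, T1, T2, ped.hybrid_ids)
        assert np.mean(np.diag(GAA12.values)) == pytest.approx(1.0, abs=1e-12)
        # loop oracle on a random subset of hybrid pairs
        rng = np.random.default_rng(0)
        i1 = {h: g1.line_ids.index(ped.parent1[h]) for h in ped.hybrid_ids}
        i2 = {h: g2.line_ids.index(ped.parent2[h]) for h in ped.hybrid_ids}
        for _ in range(50):
            a, b = rng.integers(0, ped.n_hybrids, 2)
            ha, hb = ped.hybrid_ids[a], ped.hybrid_ids[b]
            raw = GA1.values[i1[ha], i1[hb]] * GA2.values[i2[ha], i2[hb]]
            assert GAA12.values[a, b] == pytest.approx(raw / GAA12.scale_constant, rel=1e-12)

    def test_dominance_interactions_loop_oracle(self, small_study):
        g1, g2, ped = small_study["g1"], small_study["g2"], small_study["pedigree"]
        f1, f2 = compute_allele_freqs(g1), compute_allele_freqs(g2)
        Z1, Z2 = center_line_genotypes(g1, f1), center_line_genotypes(g2, f2)
        GA1 = additive_kinship(Z1, f1, 1)
        T1 = build_parent_incidence(ped, g1, 1)
        D = dominance_kinship(build_dominance_incidence(Z1, Z2, ped), f1, f2)
        GA1D = epistatic_with_dominance(D, GA1, T1, "A1D")
        GDD = epistatic_with_dominance(D, kind="DD")
        hyb = T1 @ GA1.values @ T1.T
        np.testing.assert_allclose(
            GA1D.values * GA1D.scale_constant, hyb * D.values, atol=1e-12
        )
        np.testing.assert_allclose(
            GDD.values * GDD.scale_constant, D.values * D.values, atol=1e-12
        )
        for K in (GA1D, GDD):
            assert np.mean(np.diag(K.values)) == pytest.approx(1.0, abs=1e-12)

    def test_gdd_of_sign_factorial_is_all_ones(self, factorial_2x2):
        g1, g2, ped = factorial_2x2
        f1, f2 = compute_allele_freqs(g1), compute_allele_freqs(g2)
        W = build_dominance_incidence(
            center_line_genotypes(g1, f1), center_line_genotypes(g2, f2), ped
        )
        D = dominance_kinship(W, f1, f2)
        GDD = epistatic_with_dominance(D, kind="DD")
        np.testing.assert_allclose(GDD.values, np.ones((4, 4)))


class TestGModel:
    def test_unit_mean_diagonals(self, small_study):
        g1, g2, ped = small_study["g1"], small_study["g2"], small_study["pedigree"]
        gm = gmodel_kinships(noia_codings(derive_hybrid_genotypes(g1, g2, ped)))
        for K in gm.values():
            assert np.mean(np.diag(K.values)) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(
            gm["GAAH"].values * gm["GAAH"].scale_constant,
            gm["GAH"].values * gm["GAH"].values, atol=1e-12,
        )


def test_kinship_summary_of_identity():
    from hybridgp.kinship import KinshipMatrix

    K = KinshipMatrix("GA1", "lines1", np.eye(4), 1.0, list("abcd"))
    s = kinship_summary(K)
    assert s["mean_diag"] == 1.0
    assert s["mean_all"] == pytest.approx(1 / 4)


def test_marker_duplication_leaves_kinships_unchanged():
    """Doubling the panel by duplicating every marker rescales numerator and
    denominator identically, so every kinship matrix is invariant."""
    rng = np.random.default_rng(21)
    g = _random_group(rng, 15, 40)
    gd = LineGenotypes("g", list(g.line_ids), g.marker_ids + [m + "x" for m in g.marker_ids],
                       np.hstack([g.calls, g.calls]))
    for panel in (g,):
        f = compute_allele_freqs(panel)
        fd = compute_allele_freqs(gd)
        GA = additive_kinship(center_line_genotypes(panel, f), f)
        GAd = additive_kinship(center_line_genotypes(gd, fd), fd)
        np.testing.assert_allclose(GA.values, GAd.values, atol=1e-12)
        np.testing.assert_allclose(
            epistatic_within(GA).values, epistatic_within(GAd).values, atol=1e-12
        )
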