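"""Relationship machinery: A, A⁻¹, G, blending/tuning, H⁻¹ vs oracles."""

import numpy as np
import pandas as pd
import pytest

from qtnprofile import (a_inverse, blend_and_tune, h_inverse, h_matrix,
                        numerator_relationship, vanraden_g)
from qtnprofile.relmat import inbreeding

from conftest import random_pedigree


def ibd_sharing_oracle(ped: pd.DataFrame, n_rep: int, seed: int):
    """Monte-Carlo additive-relationship estimate by allele dropping.

    Founders get unique allele labels; alleles drop through the pedigree
    with fair coin picks.  A_ij is estimated as twice the coancestry, the
    probability that random alleles from i and j are identical by descent.
    Returns (estimate, standard error) matrices.
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    sire = ped["sire"].to_numpy() - 1
    dam = ped["dam"].to_numpy() - 1
    alleles = np.zeros((n, 2, n_rep), dtype=np.int32)
    label = 1
    for i in range(n):
        for j, p in enumerate((sire[i], dam[i])):
            if p < 0:
                alleles[i, j] = label
                label += 1
            else:
                pick = rng.integers(0, 2, n_rep)
                alleles[i, j] = alleles[p, pick, np.arange(n_rep)]
    est = np.empty((n, n))
    se = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            share = np.zeros(n_rep)
            for x in range(2):
                for y in range(2):
                    if i == j and x == y:
                        continue
                    share += alleles[i, x] == alleles[j, y]
            if i == j:
                stat = 1.0 + share / 2.0   # 1 + F from the two cross pairs
            else:
                stat = share / 2.0         # 2 * mean IBD over 4 pairs
            est[i, j] = est[j, i] = stat.mean()
            se[i, j] = se[j, i] = stat.std(ddof=1) / np.sqrt(n_rep)
    return est, se


class TestNumeratorRelationship:
    def test_textbook_identities(self, trio_pedigree):
        a = numerator_relationship(trio_pedigree)
        assert a[0, 0] == a[1, 1] == 1.0
        assert a[0, 1] == 0.0
        assert a[0, 2] == a[1, 2] == 0.5
        assert a[2, 2] == 1.0

    def test_full_sibs_and_inbred_offspring(self):
        # 1,2 founders; 3,4 full sibs; 5 offspring of the full sibs
        ped = pd.DataFrame({
            "id": [1, 2, 3, 4, 5],
            "sire": [0, 0, 1, 1, 3],
            "dam": [0, 0, 2, 2, 4],
        })
        a = numerator_relationship(ped)
        assert a[2, 3] == 0.5
        assert a[4, 4] == 1.25          # F = 0.25
        np.testing.assert_allclose(a, a.T)

    def test_own_ancestor_rejected(self):
        ped = pd.DataFrame({"id": [1, 2], "sire": [2, 0], "dam": [0, 0]})
        with pytest.raises(ValueError):
            numerator_relationship(ped)

    def test_matches_monte_carlo_ibd_oracle(self):
        """A equals twice the mean IBD sharing from allele-drop replicates
        (30 individuals, 100k gene drops, 3 SE with a small floor)."""
        ped = random_pedigree(30, 8, seed=42)
        a = numerator_relationship(ped)
        est, se = ibd_sharing_oracle(ped, n_rep=100_000, seed=43)
        tol = 3 * se + 1e-12
        frac_in = (np.abs(a - est) <= tol).mean()
        assert frac_in >= 0.99
        assert (np.abs(a - est) <= 4.5 * se + 1e-12).all()


class TestAInverse:
    def test_founders_only_identity(self):
        ped = pd.DataFrame({"id": [1, 2, 3], "sire": 0, "dam": 0})
        np.testing.assert_allclose(a_inverse(ped), np.eye(3))

    def test_trio_pattern(self, trio_pedigree):
        ainv = a_inverse(trio_pedigree)
        expected = np.array([[1.5, 0.5, -1.0],
                             [0.5, 1.5, -1.0],
                             [-1.0, -1.0, 2.0]])
        np.testing.assert_allclose(ainv, expected)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_inverts_tabular_a_with_inbreeding(self, seed):
        ped = random_pedigree(60, 10, seed=seed)
        a = numerator_relationship(ped)
        assert inbreeding(ped).max() > 0  # pedigree actually inbred
        ainv = a_inverse(ped)
        np.testing.assert_allclose(ainv @ a, np.eye(60), atol=1e-8)

    def test_a_positive_definite(self):
        ped = random_pedigree(80, 12, seed=9)
        w = np.linalg.eigvalsh(numerator_relationship(ped))
        assert w.min() > 0


class TestVanRadenG:
    def test_single_snp_hand_calculation(self):
        g, p = vanraden_g(np.array([[0], [1], [2]]), p=np.array([0.5]))
        # Z = (-1, 0, 1), denominator 2*0.25 = 0.5
        np.testing.assert_allclose(np.diag(g), [2.0, 0.0, 2.0])
        np.testing.assert_allclose(g[0, 2], -2.0)

    def test_linear_in_weights(self):
        rng = np.random.default_rng(0)
        m = rng.integers(0, 3, (10, 30))
        g1, _ = vanraden_g(m)
        g2, _ = vanraden_g(m, weights=np.full(30, 2.0))
        # doubling D doubles numerator and denominator alike
        np.testing.assert_allclose(g1, g2)
        g3, _ = vanraden_g(m, p=np.full(30, 0.5), weights=np.full(30, 2.0))
        g4, _ = vanraden_g(m, p=np.full(30, 0.5))
        np.testing.assert_allclose(g3, g4)

    def test_mean_diagonal_near_one_in_hwe(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.9, 400)
        m = rng.binomial(2, p, (200, 400))
        g, _ = vanraden_g(m)
        assert np.diag(g).mean() == pytest.approx(1.0, abs=0.05)

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            vanraden_g(np.ones((4, 3), dtype=int) * 2)

    def test_monomorphic_columns_do_not_shift_indexing(self):
        rng = np.random.default_rng(2)
        m = rng.integers(0, 3, (12, 20))
        m[:, 5] = 2
        g, p = vanraden_g(m)
        assert p.size == 20 and p[5] == 1.0
        assert np.isfinite(g).all()


class TestBlendAndTune:
    def test_g_equals_a22_is_neutral(self):
        a22 = np.array([[1.0, 0.25], [0.25, 1.0]])
        gb, rho, delta = blend_and_tune(a22, a22)
        np.testing.assert_allclose(gb, a22)
        assert rho == 0.0 and delta == 1.0

    def test_constant_shift(self):
        a22 = np.eye(3)
        g = a22 + 0.1
        gb, rho, delta = blend_and_tune(g, a22, alpha=0.95)
        assert rho == pytest.approx(0.1)
        assert delta == pytest.approx(0.95)
        np.testing.assert_allclose(gb, 0.95 * g + 0.05 * a22)

    def test_alpha_one_no_blending(self):
        a22 = np.eye(2)
        g = np.array([[1.1, 0.2], [0.2, 0.9]])
        gb, _, _ = blend_and_tune(g, a22, alpha=1.0)
        np.testing.assert_allclose(gb, g)

    def test_off_diagonal_variant(self):
        a22 = np.eye(2)
        g = a22 + np.array([[0.4, 0.1], [0.1, 0.4]])
        _, rho_all, _ = blend_and_tune(g, a22)
        _, rho_off, _ = blend_and_tune(g, a22, include_diagonal=False)
        assert rho_all == pytest.approx(0.25)
        assert rho_off == pytest.approx(0.1)


class TestHInverse:
    def _setup(self, seed, n=40, n_gen=15, n_snp=200):
        ped = random_pedigree(n, 10, seed=seed)
        a = numerator_relationship(ped)
        ainv = a_inverse(ped)
        g_idx = np.arange(n - n_gen, n)
        rng = np.random.default_rng(seed + 100)
        m = rng.binomial(2, rng.uniform(0.2, 0.8, n_snp), (n_gen, n_snp))
        g, _ = vanraden_g(m)
        a22 = a[np.ix_(g_idx, g_idx)]
        gb, _, _ = blend_and_tune(g, a22, alpha=0.95)
        return a, ainv, a22, gb, g_idx

    def test_no_genotyped_animals(self):
        ped = random_pedigree(20, 5, seed=3)
        ainv = a_inverse(ped)
        hinv = h_inverse(ainv, np.empty((0, 0)), np.empty((0, 0)),
                         np.array([], dtype=int))
        np.testing.assert_array_equal(hinv, ainv)

    def test_gb_equal_a22_recovers_ainv(self):
        ped = random_pedigree(20, 5, seed=4)
        a = numerator_relationship(ped)
        ainv = a_inverse(ped)
        g_idx = np.arange(12, 20)
        a22 = a[np.ix_(g_idx, g_idx)]
        hinv = h_inverse(ainv, a22, a22.copy(), g_idx)
        np.testing.assert_allclose(hinv, ainv, atol=1e-10)

    @pytest.mark.parametrize("seed", [5, 6])
    def test_matches_dense_h_inversion(self, seed):
        """Aguilar-form H⁻¹ equals the direct inverse of the joint
        (Legarra) H on ≤50 animals to 1e-6."""
        a, ainv, a22, gb, g_idx = self._setup(seed)
        hinv = h_inverse(ainv, a22, gb, g_idx)
        h = h_matrix(a, gb, g_idx)
        np.testing.assert_allclose(hinv, np.linalg.inv(h), atol=1e-6)

    def test_singular_gb_message(self):
        ped = random_pedigree(10, 4, seed=7)
        a = numerator_relationship(ped)
        ainv = a_inverse(ped)
        g_idx = np.arange(6, 10)
        bad = np.zeros((4, 4))
        with pytest.raises(np.linalg.LinAlgError, match="blending"):
            h_inverse(ainv, a[np.ix_(g_idx, g_idx)], bad, g_idx)
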