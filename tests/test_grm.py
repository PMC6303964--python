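import numpy as np
import pytest

import epiblup as eb

from conftest import small_simulation


def brute_force_gram(values):
    """Explicit-loop X X' as an independent oracle."""
    n, m = values.shape
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            for k in range(m):
                out[i, j] += values[i, k] * values[j, k]
    return out


def brute_force_hadamard_of_gram(x):
    """((XX') . (XX'))[i,j] = sum_k sum_l x_ik x_jk x_il x_jl by quadruple loop."""
    n, m = x.shape
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            for k in range(m):
                for l in range(m):
                    out[i, j] += x[i, k] * x[j, k] * x[i, l] * x[j, l]
    return out


class TestIncidence:
    def test_additive_coding_and_zero_column_sums(self, toy_genotypes):
        p = eb.allele_frequencies(toy_genotypes)
        m = eb.additive_incidence(toy_genotypes, p)
        np.testing.assert_allclose(m.values[:, 0], [1.0, 0.0, -1.0])
        np.testing.assert_allclose(m.values.sum(axis=0), 0.0, atol=1e-12)

    def test_additive_entry_at_p02(self):
        g = eb.GenotypeMatrix([[2], [0], [0], [0], [0]],
                              [f"i{k}" for k in range(5)], ["s"])
        m = eb.additive_incidence(g, np.array([0.2]))
        assert m.values[0, 0] == pytest.approx(1.6)

    def test_monomorphic_column_is_zero(self):
        g = eb.GenotypeMatrix([[2], [2], [2]], ["a", "b", "c"], ["s"])
        with pytest.warns(UserWarning, match="monomorphic"):
            m = eb.additive_incidence(g, np.array([1.0]))
        np.testing.assert_allclose(m.values, 0.0)

    @pytest.mark.parametrize("code,p,expected", [
        (2, 0.5, -0.5), (1, 0.5, 0.5), (0, 0.5, -0.5),
        (1, 0.9, 0.18), (2, 1.0, 0.0),
    ])
    def test_dominance_coding(self, code, p, expected):
        g = eb.GenotypeMatrix([[code]], ["a"], ["s"])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = eb.dominance_incidence(g, np.array([p]))
        assert w.values[0, 0] == pytest.approx(expected)

    def test_missing_contributes_zero_to_dominance(self):
        g = eb.GenotypeMatrix([[np.nan], [1], [0]], ["a", "b", "c"], ["s"])
        w = eb.dominance_incidence(g, np.array([0.25]))
        assert w.values[0, 0] == 0.0

    def test_hw_proportions_make_w_orthogonal_to_m(self):
        # genotype counts exactly (p^2, 2pq, q^2)*n at p = 0.5
        codes = np.array([2] * 5 + [1] * 10 + [0] * 5, dtype=float)
        g = eb.GenotypeMatrix(codes[:, None], [f"i{k}" for k in range(20)], ["s"])
        p = eb.allele_frequencies(g)
        m = eb.additive_incidence(g, p).values[:, 0]
        w = eb.dominance_incidence(g, p).values[:, 0]
        assert w.sum() == pytest.approx(0.0, abs=1e-10)
        assert m @ w == pytest.approx(0.0, abs=1e-10)


class TestRelationshipMatrices:
    def test_toy_additive(self, toy_genotypes):
        p = eb.allele_frequencies(toy_genotypes)
        ga = eb.grm_additive(eb.additive_incidence(toy_genotypes, p))
        np.testing.assert_allclose(ga.values, [[2, 0, -2], [0, 0, 0], [-2, 0, 2]])
        assert ga.norm_constant == pytest.approx(1.0)

    def test_toy_dominance(self, toy_genotypes):
        p = eb.allele_frequencies(toy_genotypes)
        gd = eb.grm_dominance(eb.dominance_incidence(toy_genotypes, p))
        np.testing.assert_allclose(gd.values, [[1, -1, 1], [-1, 1, -1], [1, -1, 1]])

    def test_toy_epistatic_aa(self, toy_genotypes):
        p = eb.allele_frequencies(toy_genotypes)
        ga = eb.grm_additive(eb.additive_incidence(toy_genotypes, p))
        gaa = eb.epistatic_grm(ga, ga)
        np.testing.assert_allclose(gaa.values, [[1.5, 0, 1.5], [0, 0, 0], [1.5, 0, 1.5]])
        assert np.trace(gaa.values) == pytest.approx(3.0)

    def test_identity_inputs_stay_identity(self):
        ident = eb.RelationshipMatrix(np.eye(4), "A", list("abcd"), 1.0)
        out = eb.epistatic_grm(ident, ident)
        np.testing.assert_allclose(out.values, np.eye(4))

    def test_epistatic_component_tags(self, small_dataset):
        grms = small_dataset["grms"]
        assert grms["AA"].component == "AA"
        assert grms["AD"].component == "AD"
        assert grms["DD"].component == "DD"

    def test_grm_oracle_random_matrices(self):
        """MM', WW' and Hadamard entries match explicit loops exactly."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            n, m = rng.integers(2, 7), rng.integers(2, 5)
            codes = rng.integers(0, 3, size=(n, m)).astype(float)
            # keep loci polymorphic
            codes[0] = 1.0
            g = eb.GenotypeMatrix(codes, [f"i{k}" for k in range(n)],
                                  [f"s{k}" for k in range(m)])
            p = eb.allele_frequencies(g)
            M = eb.additive_incidence(g, p)
            W = eb.dominance_incidence(g, p)
            ga = eb.grm_additive(M)
            gd = eb.grm_dominance(W)
            np.testing.assert_allclose(
                ga.values, brute_force_gram(M.values) / ga.norm_constant, atol=1e-12)
            np.testing.assert_allclose(
                gd.values, brute_force_gram(W.values) / gd.norm_constant, atol=1e-12)
            had = brute_force_hadamard_of_gram(M.values) / ga.norm_constant**2
            gaa = eb.epistatic_grm(ga, ga)
            np.testing.assert_allclose(gaa.values, had / (np.trace(had) / n), atol=1e-12)

    def test_trace_normalization_exact(self, small_dataset):
        for comp in ("AA", "AD", "DD"):
            g = small_dataset["grms"][comp]
            # regularization adds epsilon to the diagonal on top of trace 1
            assert np.trace(g.values) / g.n == pytest.approx(1.0 + 1e-6, abs=1e-12)

    def test_psd_and_symmetry(self, small_dataset):
        for g in small_dataset["grms"].values():
            np.testing.assert_allclose(g.values, g.values.T, atol=1e-12)
            evals = np.linalg.eigvalsh(g.values)
            assert evals.min() >= -1e-8 * evals.max()

    def test_mean_diagonal_near_one_under_hwe(self):
        _, geno, _, _, _ = small_simulation(5, n=500, m=5000)
        p = eb.allele_frequencies(geno)
        ga = eb.grm_additive(eb.additive_incidence(geno, p))
        gd = eb.grm_dominance(eb.dominance_incidence(geno, p))
        assert np.mean(np.diag(ga.values)) == pytest.approx(1.0, abs=0.05)
        assert np.mean(np.diag(gd.values)) == pytest.approx(1.0, abs=0.05)

    def test_degenerate_hadamard_trace_rejected(self):
        zero = eb.RelationshipMatrix(np.zeros((3, 3)), "A", list("abc"), 1.0)
        with pytest.raises(ValueError, match="trace"):
            eb.epistatic_grm(zero, zero)

    def test_all_monomorphic_rejected(self):
        g = eb.GenotypeMatrix([[2, 2], [2, 2]], ["a", "b"], ["s1", "s2"])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = eb.additive_incidence(g, np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="monomorphic"):
            eb.grm_additive(m)


class TestRegularize:
    def test_shifts_diagonal(self):
        ident = eb.RelationshipMatrix(np.eye(3), "A", list("abc"), 1.0)
        out = eb.regularize(ident, 0.01)
        np.testing.assert_allclose(out.values, 1.01 * np.eye(3))

    def test_min_eigenvalue_floor(self, toy_genotypes):
        p = eb.allele_frequencies(toy_genotypes)
        gd = eb.grm_dominance(eb.dominance_incidence(toy_genotypes, p))
        out = eb.regularize(gd, 1e-6)
        assert np.linalg.eigvalsh(out.values).min() >= 1e-6 - 1e-12


class TestIO:
    def test_tsv_roundtrip(self, tmp_path, toy_genotypes):
        p = eb.allele_frequencies(toy_genotypes)
        ga = eb.grm_additive(eb.additive_incidence(toy_genotypes, p))
        from epiblup.grm import read_grm_tsv, write_grm_tsv
        write_grm_tsv(ga, tmp_path / "ga.tsv")
        back = read_grm_tsv(tmp_path / "ga.tsv")
        np.testing.assert_allclose(back.values, ga.values)
        assert back.component == "A"
        assert back.norm_constant == pytest.approx(ga.norm_constant)

    def test_container_roundtrip(self, tmp_path, toy_genotypes):
        from epiblup.grm import load_grm, save_grm
        p = eb.allele_frequencies(toy_genotypes)
        gd = eb.grm_dominance(eb.dominance_incidence(toy_genotypes, p))
        save_grm(gd, tmp_path / "gd.npz")
        back = load_grm(tmp_path / "gd.npz")
        np.testing.assert_allclose(back.values, gd.values)
        assert back.component == "D"
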