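"""Kernel constructors and filters against independent brute-force oracles."""

import numpy as np
import pytest

from holopred.kernels import (
    GenotypeMatrix,
    Kernel,
    OTUTable,
    compute_grm,
    compute_mrm,
    core_greml_kernel,
    filter_otus_prevalence,
    filter_snps_maf,
    hadamard_kernel,
    normalise_kernel,
)

from conftest import random_psd_kernel


# ---------------------------------------------------------------------------
# brute-force oracles (deliberately naive; never share code with holopred)
# ---------------------------------------------------------------------------

def grm_oracle(Z):
    """VanRaden GRM by explicit double loops."""
    n, p = Z.shape
    freqs = [sum(Z[i, m] for i in range(n)) / (2 * n) for m in range(p)]
    denom = sum(2 * f * (1 - f) for f in freqs)
    G = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            G[i, j] = sum(
                (Z[i, m] - 2 * freqs[m]) * (Z[j, m] - 2 * freqs[m])
                for m in range(p)
            ) / denom
    return G


def mrm_oracle(counts):
    """Step-by-step MRM: relative abundance -> log -> standardise -> RR'/q."""
    n, q = counts.shape
    rel = counts / counts.sum(axis=1, keepdims=True)
    pseudo = 0.5 * rel[rel > 0].min()
    R = np.log(np.where(rel > 0, rel, pseudo))
    for j in range(q):
        col = R[:, j]
        R[:, j] = (col - col.mean()) / col.std(ddof=1)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            M[i, j] = sum(R[i, m] * R[j, m] for m in range(q)) / q
    return M


def core_oracle(G, M):
    Lg = np.linalg.cholesky(G)
    Lm = np.linalg.cholesky(M)
    return 0.5 * (Lg @ Lm.T + Lm @ Lg.T)


def _geno(Z, **kw):
    n, p = np.asarray(Z).shape
    return GenotypeMatrix(Z, [f"S{i}" for i in range(n)],
                          [f"snp{j}" for j in range(p)], **kw)


def _otus(counts, **kw):
    n, q = np.asarray(counts).shape
    return OTUTable(counts, [f"S{i}" for i in range(n)],
                    [f"OTU{j}" for j in range(q)], **kw)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

class TestMafFilter:
    def test_hand_computed_frequencies(self):
        # 6 samples, 3 SNPs with allele freqs 0.5, 1/12, 0.0
        Z = np.array([
            [1, 1, 0],
            [1, 0, 0],
            [1, 0, 0],
            [1, 0, 0],
            [1, 0, 0],
            [1, 0, 0],
        ], dtype=float)
        g = _geno(Z)
        assert np.allclose(g.allele_freqs, [0.5, 1 / 12, 0.0])
        kept = filter_snps_maf(g, 0.01)
        assert kept.snp_ids == ["snp0", "snp1"]

    def test_monomorphic_removed(self):
        g = _geno(np.array([[0.0, 1.0], [0.0, 1.0], [0.0, 2.0]]))
        kept = filter_snps_maf(g, 0.01)
        assert kept.snp_ids == ["snp1"]

    def test_threshold_zero_is_identity(self):
        g = _geno(np.array([[0.0, 2.0], [0.0, 1.0]]))
        kept = filter_snps_maf(g, 0.0)
        assert kept.snp_ids == g.snp_ids
        np.testing.assert_array_equal(kept.dosages, g.dosages)

    def test_all_removed_raises(self):
        g = _geno(np.zeros((4, 2)))
        with pytest.raises(ValueError, match="removed all"):
            filter_snps_maf(g, 0.01)

    def test_frequencies_use_nonmissing_only(self):
        Z = np.array([[2.0, np.nan], [np.nan, 1.0], [0.0, 1.0]])
        g = _geno(Z)
        assert np.allclose(g.allele_freqs, [0.5, 0.5])


class TestPrevalenceFilter:
    def test_hand_counted_prevalence(self):
        counts = np.zeros((10, 2))
        counts[:2, 0] = 5   # OTU A in 2/10 samples
        counts[0, 1] = 3    # OTU B in 1/10
        counts[:, :] += 0   # everything else zero
        # pad a third always-present OTU so rows have nonzero totals
        counts = np.column_stack([counts, np.ones(10)])
        t = _otus(counts)
        kept = filter_otus_prevalence(t, 0.2)
        assert kept.otu_ids == ["OTU0", "OTU2"]

    def test_always_present_retained(self):
        t = _otus(np.ones((5, 1)))
        assert filter_otus_prevalence(t, 0.2).otu_ids == ["OTU0"]

    def test_zero_fraction_is_identity(self):
        t = _otus(np.array([[0.0, 1.0], [0.0, 2.0]]))
        kept = filter_otus_prevalence(t, 0.0)
        np.testing.assert_array_equal(kept.counts, t.counts)

    def test_all_removed_raises(self):
        t = _otus(np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="removed all"):
            filter_otus_prevalence(t, 0.9)


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

class TestGrm:
    def test_three_sample_hand_example(self):
        Z = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
        G = compute_grm(_geno(Z))
        np.testing.assert_allclose(G.matrix, grm_oracle(Z), atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("n,p", [(4, 3), (6, 5), (8, 10)])
    def test_matches_bruteforce_oracle(self, seed, n, p):
        rng = np.random.default_rng(seed)
        Z = rng.integers(0, 3, size=(n, p)).astype(float)
        # ensure polymorphic
        Z[0] = 1.0
        G = compute_grm(_geno(Z))
        np.testing.assert_allclose(G.matrix, grm_oracle(Z), atol=1e-10)

    def test_row_sums_zero_with_sample_frequencies(self, rng):
        Z = rng.integers(0, 3, size=(12, 30)).astype(float)
        Z[0] = 1.0
        G = compute_grm(_geno(Z))
        np.testing.assert_allclose(G.matrix.sum(axis=1), 0.0, atol=1e-10)

    def test_psd(self, rng):
        Z = rng.integers(0, 3, size=(10, 40)).astype(float)
        Z[0] = 1.0
        G = compute_grm(_geno(Z))
        assert G.min_eigenvalue() >= -1e-8 * abs(np.linalg.eigvalsh(G.matrix)[-1])

    def test_monomorphic_raises_with_snp_name(self):
        Z = np.array([[0.0, 1.0], [0.0, 1.0], [0.0, 2.0]])
        with pytest.raises(ValueError, match="snp0"):
            compute_grm(_geno(Z))

    def test_missing_imputed_to_mean(self):
        Z = np.array([[0.0, 1.0], [1.0, np.nan], [2.0, 1.0]])
        G = compute_grm(_geno(Z))
        Zi = Z.copy()
        Zi[1, 1] = 2 * np.nanmean(Z[:, 1]) / 2
        # oracle on the imputed matrix, frequencies from non-missing values
        p = np.nanmean(Z, axis=0) / 2
        Zc = Zi - 2 * p
        expected = Zc @ Zc.T / np.sum(2 * p * (1 - p))
        np.testing.assert_allclose(G.matrix, expected, atol=1e-12)

    def test_missing_without_imputation_raises(self):
        Z = np.array([[0.0, 1.0], [1.0, np.nan], [2.0, 1.0]])
        with pytest.raises(ValueError, match="imputation disabled"):
            compute_grm(_geno(Z), impute_missing=False)


# ---------------------------------------------------------------------------
# MRM
# ---------------------------------------------------------------------------

class TestMrm:
    def test_three_by_two_oracle(self):
        counts = np.array([[10.0, 5.0, 1.0], [3.0, 9.0, 2.0], [6.0, 2.0, 8.0]])
        M = compute_mrm(_otus(counts))
        np.testing.assert_allclose(M.matrix, mrm_oracle(counts), atol=1e-10)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_oracle_with_zeros(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(2.0, size=(8, 12)).astype(float)
        counts[:, 0] += 1  # keep every row nonzero in total
        M = compute_mrm(_otus(counts))
        np.testing.assert_allclose(M.matrix, mrm_oracle(counts), atol=1e-10)

    def test_identical_profiles_exchangeable(self):
        counts = np.array([[4.0, 2.0, 6.0], [8.0, 4.0, 12.0], [1.0, 7.0, 2.0]])
        # samples 0 and 1 have identical relative abundances
        M = compute_mrm(_otus(counts)).matrix
        assert M[0, 0] == pytest.approx(M[1, 1], abs=1e-10)
        assert M[0, 1] == pytest.approx(M[0, 0], abs=1e-10)

    def test_zero_variance_column_dropped(self, caplog):
        rel = np.array([[0.5, 0.2, 0.3], [0.5, 0.3, 0.2], [0.5, 0.25, 0.25]])
        t = _otus(rel, is_relative=True)
        with caplog.at_level("WARNING", logger="holopred.kernels"):
            M = compute_mrm(t)
        assert "zero-variance" in caplog.text
        # constant first column cannot contribute; M built from remaining 2
        assert M.n_samples == 3

    def test_mean_diagonal_near_one(self, rng):
        counts = rng.poisson(5.0, size=(20, 30)).astype(float) + 1
        M = compute_mrm(_otus(counts))
        assert M.diag_mean == pytest.approx((20 - 1) / 20, rel=1e-10)


# ---------------------------------------------------------------------------
# Hadamard, CORE, normalisation
# ---------------------------------------------------------------------------

class TestHadamard:
    def test_identity_inputs(self):
        ids = [f"S{i}" for i in range(4)]
        I = Kernel(np.eye(4), ids, "GRM")
        J = Kernel(np.eye(4), ids, "MRM")
        K = hadamard_kernel(I, J)
        np.testing.assert_array_equal(K.matrix, np.eye(4))
        assert K.kind == "HADAMARD"

    def test_commutative(self, rng):
        G = random_psd_kernel(rng, 5, "GRM")
        M = Kernel(random_psd_kernel(rng, 5).matrix, G.sample_ids, "MRM")
        np.testing.assert_array_equal(
            hadamard_kernel(G, M).matrix, hadamard_kernel(M, G).matrix
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_schur_product_psd(self, seed):
        rng = np.random.default_rng(seed)
        G = random_psd_kernel(rng, 6, "GRM")
        M = Kernel(random_psd_kernel(rng, 6).matrix, G.sample_ids, "MRM")
        K = hadamard_kernel(G, M)
        evals = np.linalg.eigvalsh(K.matrix)
        assert evals[0] >= -1e-10 * max(evals[-1], 1.0)

    def test_sample_id_mismatch(self, rng):
        G = random_psd_kernel(rng, 4, "GRM")
        M = random_psd_kernel(rng, 4, "MRM")
        M.sample_ids = ["X0", "S1", "S2", "S3"]
        with pytest.raises(ValueError, match="position 0.*'S0'.*'X0'"):
            hadamard_kernel(G, M)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="shape mismatch"):
            hadamard_kernel(random_psd_kernel(rng, 4), random_psd_kernel(rng, 5))


class TestCore:
    def test_self_covariance_identity(self, rng):
        G = random_psd_kernel(rng, 6, "GRM")
        K = core_greml_kernel(G, G)
        np.testing.assert_allclose(K.matrix, G.matrix, atol=1e-8)

    def test_identity_inputs(self):
        ids = [f"S{i}" for i in range(3)]
        I = Kernel(np.eye(3), ids, "GRM")
        K = core_greml_kernel(I, Kernel(np.eye(3), ids, "MRM"))
        np.testing.assert_allclose(K.matrix, np.eye(3), atol=1e-12)

    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_matches_cholesky_oracle(self, seed):
        rng = np.random.default_rng(seed)
        G = random_psd_kernel(rng, 4, "GRM")
        M = Kernel(random_psd_kernel(rng, 4).matrix, G.sample_ids, "MRM")
        K = core_greml_kernel(G, M)
        np.testing.assert_allclose(K.matrix, core_oracle(G.matrix, M.matrix),
                                   atol=1e-10)
        assert K.kind == "CORE"

    def test_ridge_recovers_near_singular(self, rng):
        A = rng.standard_normal((6, 3))
        G = Kernel(A @ A.T, [f"S{i}" for i in range(6)], "GRM")  # rank 3
        M = Kernel(random_psd_kernel(rng, 6).matrix, G.sample_ids, "MRM")
        K = core_greml_kernel(G, M)  # must not raise
        assert np.isfinite(K.matrix).all()


class TestNormalise:
    def test_halves_diag_two(self):
        ids = ["a", "b"]
        k = Kernel(2 * np.eye(2), ids, "GRM")
        out = normalise_kernel(k)
        np.testing.assert_allclose(out.matrix, np.eye(2))

    def test_idempotent(self, rng):
        k = random_psd_kernel(rng, 5)
        once = normalise_kernel(k)
        twice = normalise_kernel(once)
        np.testing.assert_allclose(once.matrix, twice.matrix, atol=1e-12)
        assert once.diag_mean == pytest.approx(1.0, abs=1e-10)

    def test_eigenvectors_preserved_eigenvalues_scaled(self, rng):
        k = random_psd_kernel(rng, 6)
        d0, U0 = np.linalg.eigh(k.matrix)
        out = normalise_kernel(k)
        d1, U1 = np.linalg.eigh(out.matrix)
        np.testing.assert_allclose(d1, d0 / k.diag_mean, atol=1e-10)
        np.testing.assert_allclose(np.abs(U0), np.abs(U1), atol=1e-8)

    def test_zero_diag_raises(self):
        k = Kernel(np.zeros((2, 2)), ["a", "b"], "CORE")
        with pytest.raises(ValueError, match="zero mean diagonal"):
            normalise_kernel(k)


def test_kernels_carry_sample_ids_through(rng):
    """Every constructor propagates sample IDs in content and order."""
    Z = rng.integers(0, 3, size=(7, 20)).astype(float)
    Z[0] = 1.0
    ids = [f"animal{i}" for i in range(7)]
    g = GenotypeMatrix(Z, ids, [f"s{j}" for j in range(20)])
    counts = rng.poisson(4.0, size=(7, 15)).astype(float) + 1
    t = OTUTable(counts, ids, [f"o{j}" for j in range(15)])
    G = compute_grm(g)
    M = compute_mrm(t)
    for K in (G, M, hadamard_kernel(G, M), core_greml_kernel(G, M),
              normalise_kernel(G)):
        assert K.sample_ids == ids


def test_asymmetric_matrix_rejected():
    mat = np.array([[1.0, 0.5], [0.2, 1.0]])
    with pytest.raises(ValueError, match="asymmetric"):
        Kernel(mat, ["a", "b"], "GRM")
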