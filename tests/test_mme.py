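"""Design matrices and Henderson mixed-model equations vs dense GLS/BLUP."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from forageblup import pedigree as pg
from forageblup.design import ModelSpec, build_design_matrices, validate_phenotypes
from forageblup.mme import InvalidVarianceError, assemble_mme, solve_mme
from forageblup.pedigree import PedigreeRecord as R

from conftest import random_pedigree


def small_ped():
    return pg.validate_and_order([R("g1"), R("g2"), R("g3"), R("g4", "g1", "g2")])


def small_pheno():
    rows = []
    for g in ("g1", "g2", "g3"):
        for year in (2017, 2018):
            rows.append({"genotype": g, "replicate": 1, "year": year, "harvest": "spring",
                         "DFY": 10.0 + hash((g, year)) % 7})
    return pd.DataFrame(rows)


def dense_gls_blup(y, X, Z, G, Rm):
    """Oracle: GLS fixed effects and BLUP via the dense V = ZGZ' + R."""
    V = Z @ G @ Z.T + Rm
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    beta = np.linalg.solve(XVX, X.T @ Vi @ y)
    u = G @ Z.T @ Vi @ (y - X @ beta)
    return beta, u


class TestDesignMatrices:
    def test_dimensions(self):
        ped = small_ped()
        dm = build_design_matrices(small_pheno(), ModelSpec("DFY", fixed=("year",)), ped)
        assert dm.X.shape == (6, 2)  # intercept + one year contrast
        assert dm.Z.shape == (6, ped.n)

    def test_recordless_genotype_still_gets_blup(self):
        ped = small_ped()  # g4 = g1 x g2 has no records
        dm = build_design_matrices(small_pheno(), ModelSpec("DFY"), ped)
        col = dm.Z[:, ped.index_of["g4"]]
        assert col.nnz == 0
        sys = assemble_mme(dm.X, dm.Z, None, pg.relationship_inverse(ped), dm.y, 2.0, 1.0)
        _, u, _, _ = solve_mme(sys)
        # BLUP flows through A: mid-parent value for a progeny of evaluated parents
        i = ped.index_of["g4"]
        assert u[i] == pytest.approx(0.5 * (u[ped.index_of["g1"]] + u[ped.index_of["g2"]]))

    def test_row_permutation_consistency(self):
        ped = small_ped()
        df = small_pheno()
        perm = np.random.default_rng(0).permutation(len(df))
        dm1 = build_design_matrices(df, ModelSpec("DFY"), ped)
        dm2 = build_design_matrices(df.iloc[perm].reset_index(drop=True), ModelSpec("DFY"), ped)
        np.testing.assert_allclose(dm1.X[perm], dm2.X)
        np.testing.assert_allclose(dm1.Z[perm].toarray(), dm2.Z.toarray())

    def test_single_level_factor_dropped_with_warning(self):
        ped = small_ped()
        df = small_pheno().assign(year=2017)
        with pytest.warns(UserWarning, match="single level"):
            dm = build_design_matrices(df, ModelSpec("DFY", fixed=("year",)), ped)
        assert dm.X.shape[1] == 1

    def test_duplicate_key_rejected(self):
        ped = small_ped()
        df = pd.concat([small_pheno()] * 2, ignore_index=True)
        with pytest.raises(ValueError, match="duplicated"):
            validate_phenotypes(df, ped)


class TestAssembleSolve:
    def test_invalid_variances_raise(self):
        ped = small_ped()
        dm = build_design_matrices(small_pheno(), ModelSpec("DFY"), ped)
        Ainv = pg.relationship_inverse(ped)
        with pytest.raises(InvalidVarianceError):
            assemble_mme(dm.X, dm.Z, None, Ainv, dm.y, -1.0, 1.0)
        with pytest.raises(InvalidVarianceError):
            assemble_mme(dm.X, dm.Z, None, Ainv, dm.y, 1.0, 0.0)

    def test_hand_assembled_blocks(self):
        # 3 unrelated genotypes, intercept-only model, unit variances
        ped = pg.validate_and_order([R("a"), R("b"), R("c")])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.ones((4, 1))
        Z = sp.csr_matrix(np.array([[1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float))
        sys = assemble_mme(X, Z, None, pg.relationship_inverse(ped), y, 2.0, 1.0)
        C = sys.C.toarray()
        expected = np.array(
            [[4.0, 2.0, 1.0, 1.0],
             [2.0, 2.5, 0.0, 0.0],
             [1.0, 0.0, 1.5, 0.0],
             [1.0, 0.0, 0.0, 1.5]]
        )
        np.testing.assert_allclose(C, expected)
        np.testing.assert_allclose(sys.rhs, [10.0, 3.0, 3.0, 4.0])

    def test_large_sigma2A_limit_is_fixed_effects_fit(self):
        # unrelated genotypes, huge genetic variance: BLUPs -> LSQ genotype effects
        rng = np.random.default_rng(5)
        ped = pg.validate_and_order([R(f"g{i}") for i in range(4)])
        gi = np.repeat(np.arange(4), 5)
        y = rng.normal(size=20) + gi * 1.5
        X = np.ones((20, 1))
        Z = sp.csr_matrix((np.ones(20), (np.arange(20), gi)), shape=(20, 4))
        sys = assemble_mme(X, Z, None, pg.relationship_inverse(ped), y, 1e12, 1.0)
        beta, u, _, _ = solve_mme(sys)
        group_means = np.array([y[gi == k].mean() for k in range(4)])
        np.testing.assert_allclose(beta[0] + u, group_means, atol=1e-6)

    def test_small_sigma2A_limit_shrinks_to_zero(self):
        rng = np.random.default_rng(6)
        ped = pg.validate_and_order([R(f"g{i}") for i in range(4)])
        gi = np.repeat(np.arange(4), 5)
        y = rng.normal(size=20) + gi
        Z = sp.csr_matrix((np.ones(20), (np.arange(20), gi)), shape=(20, 4))
        sys = assemble_mme(np.ones((20, 1)), Z, None, pg.relationship_inverse(ped), y, 1e-10, 1.0)
        _, u, _, _ = solve_mme(sys)
        assert np.abs(u).max() < 1e-6

    def test_balanced_one_way_shrinkage_formula(self):
        # unrelated genotypes, q records each, known variances
        rng = np.random.default_rng(11)
        n_g, q = 6, 8
        ped = pg.validate_and_order([R(f"g{i}") for i in range(n_g)])
        gi = np.repeat(np.arange(n_g), q)
        y = rng.normal(size=n_g * q) * 2.0 + np.repeat(rng.normal(size=n_g), q)
        s2A, s2e = 1.7, 3.1
        Z = sp.csr_matrix((np.ones(len(y)), (np.arange(len(y)), gi)), shape=(len(y), n_g))
        sys = assemble_mme(np.ones((len(y), 1)), Z, None,
                           pg.relationship_inverse(ped), y, s2A, s2e)
        _, u, _, _ = solve_mme(sys)
        k = q * s2A / (q * s2A + s2e)
        means = np.array([y[gi == g].mean() for g in range(n_g)])
        np.testing.assert_allclose(u, k * (means - means.mean()), atol=1e-8)
        # shrinkage: |BLUP| never exceeds the raw deviation
        assert np.all(np.abs(u) <= np.abs(means - means.mean()) + 1e-12)

    def test_weighted_residual_orthogonal_to_X(self):
        rng = np.random.default_rng(1)
        ped = random_pedigree(15, 5, rng)
        n = 40
        gi = rng.integers(0, ped.n, n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Z = sp.csr_matrix((np.ones(n), (np.arange(n), gi)), shape=(n, ped.n))
        y = rng.normal(size=n)
        s2e = rng.uniform(0.5, 2.0, size=n)
        sys = assemble_mme(X, Z, None, pg.relationship_inverse(ped), y, 1.2, s2e)
        _, _, _, e = solve_mme(sys)
        assert np.abs(X.T @ (sys.resid_weight * e)).max() < 1e-8

    @pytest.mark.parametrize("seed", range(6))
    def test_mme_equals_dense_gls_blup(self, seed):
        rng = np.random.default_rng(seed)
        ped = random_pedigree(rng.integers(10, 25), 5, rng)
        A = pg.numerator_relationship_matrix(ped)
        n = int(rng.integers(30, 80))
        gi = rng.integers(0, ped.n, n)
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.integers(0, 2, n)])
        Z = sp.csr_matrix((np.ones(n), (np.arange(n), gi)), shape=(n, ped.n))
        y = rng.normal(size=n) * 2 + X[:, 1]
        s2A, s2e = rng.uniform(0.5, 3), rng.uniform(0.5, 3)
        sys = assemble_mme(X, Z, None, pg.relationship_inverse(ped), y, s2A, s2e)
        beta, u, _, _ = solve_mme(sys)
        beta_o, u_o = dense_gls_blup(y, X, Z.toarray(), s2A * A, s2e * np.eye(n))
        np.testing.assert_allclose(beta, beta_o, atol=1e-6)
        np.testing.assert_allclose(u, u_o, atol=1e-6)

    def test_shift_invariance_of_blups(self):
        rng = np.random.default_rng(9)
        ped = random_pedigree(12, 4, rng)
        n = 30
        gi = rng.integers(0, ped.n, n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Z = sp.csr_matrix((np.ones(n), (np.arange(n), gi)), shape=(n, ped.n))
        y = rng.normal(size=n)
        Ainv = pg.relationship_inverse(ped)
        b1, u1, _, _ = solve_mme(assemble_mme(X, Z, None, Ainv, y, 1.0, 1.0))
        b2, u2, _, _ = solve_mme(assemble_mme(X, Z, None, Ainv, y + 10.0, 1.0, 1.0))
        assert b2[0] - b1[0] == pytest.approx(10.0, abs=1e-8)
        np.testing.assert_allclose(u1, u2, atol=1e-8)
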