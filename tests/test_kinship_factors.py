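import numpy as np
import pytest

import nrmkit as nk
from nrmkit import kinship_factors as kf


class TestInbreeding:
    def test_trio_unrelated_parents(self, trio):
        assert nk.inbreeding(trio).tolist() == [0, 0, 0]

    def test_full_sib_mating(self):
        # progeny of full sibs whose parents are unrelated: F = 0.25
        ped = nk.PedigreeTable(sire=np.array([0, 0, 1, 1, 3]),
                               dam=np.array([0, 0, 2, 2, 4]))
        assert nk.inbreeding(ped)[-1] == 0.25

    def test_worked_example_exact(self, seven):
        assert nk.inbreeding(seven).tolist() == [0, 0, 0, 0, 0.125, 0.25, 0.28125]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_tabular_diagonal(self, seed):
        ped = nk.random_pedigree(250, seed=seed)
        F = nk.inbreeding(ped)
        assert np.allclose(F, np.diag(nk.nrm_tabular(ped)) - 1, atol=1e-12)

    def test_engines_agree(self):
        ped = nk.random_pedigree(400, seed=5)
        f_py = kf.inbreeding(ped, engine="python")
        f_default = kf.inbreeding(ped)
        assert np.array_equal(f_py, f_default)

    def test_unknown_parent_means_no_inbreeding(self):
        ped = nk.random_pedigree(300, seed=9)
        F = nk.inbreeding(ped)
        partial = (ped.sire == 0) | (ped.dam == 0)
        assert np.all(F[partial] == 0)


class TestTinv:
    def test_trio_rows(self, trio):
        tinv = np.asarray(nk.build_tinv(trio).todense())
        expect = np.array([[1, 0, 0], [0, 1, 0], [-0.5, -0.5, 1]])
        assert np.array_equal(tinv, expect)

    def test_founders_identity(self, founders_only):
        assert np.array_equal(
            np.asarray(nk.build_tinv(founders_only).todense()), np.eye(5)
        )

    def test_single_known_parent_row(self, seven):
        row3 = np.asarray(nk.build_tinv(seven).todense())[2]
        assert row3.tolist() == [-0.5, 0, 1, 0, 0, 0, 0]

    def test_offdiagonal_values_and_count(self):
        ped = nk.random_pedigree(200, seed=3)
        tinv = nk.build_tinv(ped).tocoo()
        off = tinv.data[tinv.row != tinv.col]
        assert set(off) <= {-0.5}
        assert off.size == nk.count_known_parents(ped).sum()


class TestT:
    def test_trio_recurrence(self, trio):
        T = np.asarray(nk.build_t(trio).todense())
        assert T[2, 0] == 0.5 and T[2, 1] == 0.5

    def test_worked_example_t71(self, seven):
        T = np.asarray(nk.build_t(seven).todense())
        assert T[6, 0] == 0.625  # (T51 + T61)/2 = (0.5 + 0.75)/2

    @pytest.mark.parametrize("seed", [1, 4])
    def test_recurrence_equals_triangular_inversion(self, seed):
        ped = nk.random_pedigree(150, seed=seed)
        a = np.asarray(nk.build_t(ped, method="recurrence").todense())
        b = np.asarray(nk.build_t(ped, method="invert").todense())
        assert np.allclose(a, b, atol=1e-12)

    def test_t_times_tinv_is_identity(self, seven):
        T = nk.build_t(seven)
        tinv = nk.build_tinv(seven)
        assert np.allclose((T @ tinv).todense(), np.eye(7), atol=1e-12)


class TestL:
    def test_trio_row(self, trio):
        L = np.asarray(nk.build_l(trio).todense())
        assert np.allclose(L[2], [0.5, 0.5, np.sqrt(0.5)], atol=1e-15)

    def test_single_founder_parent_diagonal(self, seven):
        L = np.asarray(nk.build_l(seven).todense())
        assert L[2, 2] == pytest.approx(np.sqrt(0.75), abs=1e-15)

    def test_llt_diagonal_carries_inbreeding(self, seven):
        L = nk.build_l(seven)
        assert (L @ L.T).todense()[6, 6] == pytest.approx(1.28125, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 6])
    def test_llt_equals_tabular(self, seed):
        ped = nk.random_pedigree(180, seed=seed)
        L = nk.build_l(ped)
        assert np.allclose((L @ L.T).todense(), nk.nrm_tabular(ped), atol=1e-10)


class TestD:
    def test_worked_example(self, seven):
        F = nk.inbreeding(seven)
        assert nk.build_d(seven, F).tolist() == [1, 1, 0.75, 0.5, 0.5, 0.5, 0.40625]
        assert nk.build_d0(seven).tolist() == [1, 1, 0.75, 0.5, 0.5, 0.5, 0.5]

    def test_d_equals_d0_without_inbreeding(self, trio):
        assert np.array_equal(nk.build_d(trio), nk.build_d0(trio))

    def test_d_never_exceeds_d0(self):
        ped = nk.random_pedigree(300, seed=11)
        assert np.all(nk.build_d(ped) <= nk.build_d0(ped) + 1e-15)

    def test_dinv(self, seven):
        F = nk.inbreeding(seven)
        assert np.allclose(nk.build_dinv(seven, F) * nk.build_d(seven, F), 1.0)

    def test_length_mismatch(self, trio):
        with pytest.raises(ValueError):
            nk.build_d(trio, np.zeros(7))


class TestIncidence:
    def test_generation_one_sire_block(self, seven):
        # individuals 3 and 4 both have sire 1
        js = np.asarray(
            nk.build_incidence(seven, "sire", rows=[3, 4], n_cols=2).todense()
        )
        assert np.array_equal(js, [[0.5, 0], [0.5, 0]])
        jd = np.asarray(
            nk.build_incidence(seven, "dam", rows=[3, 4], n_cols=2).todense()
        )
        assert np.array_equal(jd, [[0, 0], [0, 0.5]])

    def test_generation_three_dam_block(self, seven):
        jd = np.asarray(nk.build_incidence(seven, "dam", rows=[7]).todense())
        assert jd.shape == (1, 6)
        assert jd[0].tolist() == [0, 0, 0, 0, 0, 0.5]

    def test_founder_rows_all_zero(self, seven):
        j = nk.build_incidence(seven, "both", rows=[1, 2], n_cols=7)
        assert j.nnz == 0

    def test_j_is_sum_of_parts(self, seven):
        rows = [5, 6]
        js = nk.build_incidence(seven, "sire", rows=rows, n_cols=4)
        jd = nk.build_incidence(seven, "dam", rows=rows, n_cols=4)
        j = nk.build_incidence(seven, "both", rows=rows, n_cols=4)
        assert abs(js + jd - j).max() == 0

    def test_parent_outside_columns_raises(self, seven):
        with pytest.raises(ValueError, match="outside columns"):
            nk.build_incidence(seven, "sire", rows=[7], n_cols=4)


class TestAinv:
    def test_trio(self, trio):
        expect = np.array([[1.5, 0.5, -1], [0.5, 1.5, -1], [-1, -1, 2]])
        assert np.allclose(nk.build_ainv(trio).todense(), expect, atol=1e-15)

    def test_founders_identity(self, founders_only):
        assert np.array_equal(
            np.asarray(nk.build_ainv(founders_only).todense()), np.eye(5)
        )

    @pytest.mark.parametrize("seed", [2, 8])
    def test_assemblies_agree(self, seed):
        ped = nk.random_pedigree(220, seed=seed)
        F = nk.inbreeding(ped)
        a = nk.build_ainv(ped, F, method="contrib")
        b = nk.build_ainv(ped, F, method="product")
        assert abs(a - b).max() < 1e-12

    def test_inverse_of_tabular(self, seven, seven_a):
        ainv = nk.build_ainv(seven, nk.inbreeding(seven))
        assert np.allclose(ainv @ seven_a, np.eye(7), atol=1e-8)

    def test_symmetry(self):
        ped = nk.random_pedigree(150, seed=13)
        ainv = nk.build_ainv(ped)
        assert abs(ainv - ainv.T).max() < 1e-12
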