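import numpy as np
import pytest

import nrmkit as nk
from conftest import DIRECT_METHODS


def build(name, ped, F=None):
    if F is None:
        F = nk.inbreeding(ped)
    return DIRECT_METHODS[name](ped, F)


class TestTabular:
    def test_founders_identity(self, founders_only):
        assert np.array_equal(nk.nrm_tabular(founders_only), np.eye(5))

    def test_parent_offspring(self):
        ped = nk.PedigreeTable(sire=np.array([0, 1]), dam=np.array([0, 0]))
        assert nk.nrm_tabular(ped)[0, 1] == 0.5

    def test_worked_example_entries(self, seven_a):
        assert seven_a[6, 6] == 1.28125
        assert seven_a[0, 6] == 0.625
        assert seven_a[4, 6] == 0.84375
        assert seven_a[4, 5] == 0.5625


class TestArrayTabular:
    def test_identical_to_tabular(self, seven, seven_a):
        assert np.array_equal(nk.nrm_tabular_array(seven), seven_a)

    def test_large_scale_agreement(self):
        ped = nk.random_pedigree(800, seed=21)
        dev = np.abs(nk.nrm_tabular_array(ped) - nk.nrm_tabular(ped)).max()
        assert dev <= 1e-12


@pytest.mark.parametrize("name", sorted(DIRECT_METHODS))
class TestAllConstructions:
    def test_worked_example(self, name, seven, seven_a):
        tol = 1e-4 if name == "iterd" else 1e-10
        assert np.abs(build(name, seven) - seven_a).max() <= tol

    def test_founders(self, name, founders_only):
        assert np.allclose(build(name, founders_only), np.eye(5), atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_random_pedigrees(self, name, seed):
        ped = nk.random_pedigree(150, seed=seed)
        A = nk.nrm_tabular(ped)
        tol = 1e-4 if name == "iterd" else 1e-10
        assert np.abs(build(name, ped) - A).max() <= tol

    def test_diag_is_one_plus_f(self, name):
        ped = nk.random_pedigree(120, seed=30)
        F = nk.inbreeding(ped)
        assert np.allclose(np.diag(build(name, ped, F)), 1 + F, atol=1e-10)


class TestIterD:
    def test_non_inbred_converges_immediately(self, trio):
        A, state = nk.nrm_iter_d(trio)
        assert state.iterations == 1
        assert np.array_equal(state.d, nk.build_d0(trio))

    def test_worked_example_final_state(self, seven):
        A, state = nk.nrm_iter_d(seven)
        assert state.converged
        assert state.d[6] == pytest.approx(0.40625, abs=1e-4)
        assert A[6, 6] == pytest.approx(1.28125, abs=1e-4)

    def test_final_d_matches_mendelian_variances(self):
        ped = nk.random_pedigree(200, seed=17)
        _, state = nk.nrm_iter_d(ped, tol=1e-10)
        assert np.allclose(state.d, nk.build_d(ped), atol=1e-8)

    def test_fewer_sweeps_with_larger_litters(self):
        iters = {}
        for litter in (1, 4):
            cfg = nk.SimulationConfig(
                n_base=100, litter_size=litter, target_n=3000, seed=2
            )
            ped = nk.mask_parents(nk.simulate_pedigree(cfg), 0.1, 0.2, seed=3)
            iters[litter] = nk.nrm_iter_d(ped)[1].iterations
        assert iters[4] < iters[1]

    def test_max_iter_exceeded_raises(self, seven):
        with pytest.raises(RuntimeError, match="did not converge"):
            nk.nrm_iter_d(seven, max_iter=1)


class TestByGeneration:
    def test_mendelian_residual_by_generation(self, seven, seven_a):
        # generation 2: o = 1 + A_sd/2 - diag(J A J') = (0.5, 0.5) for 5 and 6
        A = nk.nrm_by_generation(seven)
        assert np.allclose(A, seven_a, atol=1e-12)
        assert A[5, 5] == 1.25
        # cross-check the residual against D (same quantity by definition)
        D = nk.build_d(seven)
        assert D[4] == 0.5 and D[5] == 0.5

    def test_single_generation(self, founders_only):
        assert np.array_equal(nk.nrm_by_generation(founders_only), np.eye(5))

    def test_noncontiguous_generations(self):
        # a founder listed after a generation-1 individual
        ped = nk.pedigree_from_arrays(
            [1, 2, 3, 4, 5], [0, 0, 1, 0, 3], [0, 0, 2, 0, 4]
        )
        assert np.allclose(
            nk.nrm_by_generation(ped), nk.nrm_tabular(ped), atol=1e-12
        )


class TestBlock:
    def test_founder_block_identity(self, seven):
        assert np.array_equal(nk.nrm_block(seven, [1, 2], [1, 2]), np.eye(2))

    def test_row_seven(self, seven):
        row = nk.nrm_block(seven, [7], range(1, 8))[0]
        assert np.allclose(
            row, [0.625, 0.25, 0.5, 0.6875, 0.84375, 0.90625, 1.28125],
            atol=1e-12,
        )

    @pytest.mark.parametrize("method", ["thompson", "henderson"])
    def test_random_slice_equals_tabular_slice(self, method):
        ped = nk.random_pedigree(160, seed=23)
        A = nk.nrm_tabular(ped)
        rng = np.random.default_rng(1)
        rows = rng.choice(np.arange(1, 161), 20, replace=False)
        cols = rng.choice(np.arange(1, 161), 15, replace=False)
        block = nk.nrm_block(ped, rows, cols, method=method)
        assert np.abs(block - A[np.ix_(rows - 1, cols - 1)]).max() <= 1e-12

    def test_empty_sets_rejected(self, seven):
        with pytest.raises(ValueError):
            nk.nrm_block(seven, [], [1])


class TestDummyProgeny:
    def test_unrelated_founders(self, trio):
        assert nk.relationship_dummy_progeny(trio, 1, 2) == 0.0

    def test_worked_example_pairs(self, seven):
        assert nk.relationship_dummy_progeny(seven, 1, 4) == 0.5
        assert nk.relationship_dummy_progeny(seven, 5, 6) == 0.5625

    def test_matches_tabular_everywhere(self, seven, seven_a):
        for i in range(1, 8):
            for j in range(i + 1, 8):
                r = nk.relationship_dummy_progeny(seven, i, j)
                assert r == pytest.approx(seven_a[i - 1, j - 1], abs=1e-12)

    def test_selfing_rejected(self, seven):
        with pytest.raises(ValueError):
            nk.relationship_dummy_progeny(seven, 3, 3)

    def test_pedigree_unmodified(self, seven):
        n_before = seven.n
        nk.relationship_dummy_progeny(seven, 1, 2)
        assert seven.n == n_before


class TestMatrixProperties:
    def test_positive_definite(self):
        ped = nk.random_pedigree(90, seed=31)
        eigs = np.linalg.eigvalsh(nk.nrm_tabular(ped))
        assert eigs.min() > 0

    def test_cauchy_schwarz_bound(self):
        ped = nk.random_pedigree(90, seed=32)
        A = nk.nrm_tabular(ped)
        d = np.sqrt(np.diag(A))
        assert np.all(A <= np.outer(d, d) + 1e-12)
        assert np.all(A >= 0)
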