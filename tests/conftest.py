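import numpy as np
import pytest

import nrmkit as nk


@pytest.fixture(scope="session")
def seven():
    """The 7-animal worked example (3 inbred individuals)."""
    return nk.seven_animal_pedigree()


@pytest.fixture(scope="session")
def seven_a(seven):
    """Tabular-method oracle matrix for the worked example."""
    return nk.nrm_tabular(seven)


@pytest.fixture(scope="session")
def trio():
    return nk.trio_pedigree()


@pytest.fixture(scope="session")
def founders_only():
    return nk.PedigreeTable(sire=np.zeros(5, dtype=int), dam=np.zeros(5, dtype=int))


#: name -> builder(ped, F) for every direct construction of A
DIRECT_METHODS = {
    "tabular": lambda ped, F: nk.nrm_tabular(ped),
    "array": lambda ped, F: nk.nrm_tabular_array(ped),
    "tdt": lambda ped, F: nk.nrm_tdt(ped, F),
    "tdt_tinv": lambda ped, F: nk.nrm_tdt_via_tinv(ped, F),
    "iterd": lambda ped, F: nk.nrm_iter_d(ped)[0],
    "llt": lambda ped, F: nk.nrm_llt(ped),
    "bygen": lambda ped, F: nk.nrm_by_generation(ped),
}

#: name -> solver(ainv) recovering A from its sparse inverse
EXACT_SOLVERS = {
    "solve": nk.nrm_solve,
    "columns": nk.nrm_solve_columns,
    "fbs": nk.nrm_fbs,
    "cholinv": nk.nrm_chol_inv,
}


def write_ped_file(ped, path):
    nk.write_pedigree(ped, path)
    return str(path)
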