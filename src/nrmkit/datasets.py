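"""Small example pedigrees used in docs and tests."""

from __future__ import annotations

import numpy as np

from .pedigree_core import PedigreeTable

__all__ = ["seven_animal_pedigree", "trio_pedigree"]


def seven_animal_pedigree() -> PedigreeTable:
    """A 7-animal, 4-generation worked example.

    Records (id, sire, dam): (1,0,0) (2,0,0) (3,1,0) (4,1,2) (5,3,4)
    (6,1,4) (7,5,6). Individuals 5, 6 and 7 are inbred with
    F = 0.125, 0.25 and 0.28125.
    """
    return PedigreeTable(
        sire=np.array([0, 0, 1, 1, 3, 1, 5]),
        dam=np.array([0, 0, 0, 2, 4, 4, 6]),
    )


def trio_pedigree() -> PedigreeTable:
    """Two unrelated founders and their progeny."""
    return PedigreeTable(sire=np.array([0, 0, 1]), dam=np.array([0, 0, 2]))
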