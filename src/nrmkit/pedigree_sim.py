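"""Discrete-generation pedigree simulator.

Emulates a livestock-style population: an even-sex founder cohort is
randomly mated; in later generations newborns face pre-mating mortality, a
fraction of mature females and a (smaller) fraction of mature males are
selected at random — never on merit — as parents, females breed in a
single generation while males stay available for one extra generation, and
each mating produces a fixed-size litter. Simulation stops after the first
generation that takes the cumulative pedigree size to the target. A
post-hoc masking step hides a fraction of sires and dams in non-base
generations, mimicking incomplete recording.

The generator reproduces the *statistical structure* of such pedigrees
(growth, parent counts, inbreeding build-up as litter size varies), not any
specific recorded population.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pedigree_core import PedigreeTable, count_known_parents

__all__ = [
    "SimulationConfig",
    "simulate_pedigree",
    "mask_parents",
    "pedigree_summary",
    "random_pedigree",
]


class ExtinctionError(RuntimeError):
    """The simulated population ran out of selectable parents."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative process.

    Defaults describe the reference scenario: 200 founders (half male),
    3% pre-mating mortality, 80% of mature females and 20% of mature males
    selected as parents, one generation of male overlap, and simulation
    until 20,000 individuals. ``litters_per_dam`` is the number of matings
    of each selected dam per generation; with 80%/20% selection and equal
    sex ratio the expected cohort growth is about
    0.8·(1−mortality)·0.5·litters_per_dam·litter_size, so 3 is the
    smallest whole number that sustains growth at litter size 1.
    """

    n_base: int = 200
    litter_size: int = 2
    mortality: float = 0.03
    female_sel: float = 0.80
    male_sel: float = 0.20
    male_overlap: int = 1
    litters_per_dam: int = 3
    target_n: int = 20_000
    missing_dam_rate: float = 0.10
    missing_sire_rate: float = 0.20
    seed: int = 0

    def __post_init__(self):
        for name in ("mortality", "female_sel", "male_sel",
                     "missing_dam_rate", "missing_sire_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.litter_size < 1:
            raise ValueError("litter_size must be >= 1")
        if self.litters_per_dam < 1:
            raise ValueError("litters_per_dam must be >= 1")
        if self.n_base < 2 or self.n_base % 2:
            raise ValueError("n_base must be even and >= 2")
        if self.target_n <= self.n_base:
            raise ValueError("target_n must exceed n_base")


def simulate_pedigree(config: SimulationConfig) -> PedigreeTable:
    """Simulate a pedigree of at least ``config.target_n`` individuals.

    Returns a generation-ordered :class:`PedigreeTable` with sex and
    generation annotations and full parentage (apply :func:`mask_parents`
    afterwards for incomplete recording). Fully reproducible per seed.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    sire = [np.zeros(c.n_base, dtype=np.int64)]
    dam = [np.zeros(c.n_base, dtype=np.int64)]
    sex = [np.array(["M"] * (c.n_base // 2) + ["F"] * (c.n_base // 2))]
    gen_of = [np.zeros(c.n_base, dtype=np.int64)]
    alive = [np.ones(c.n_base, dtype=bool)]  # founders: no mortality
    ids = [np.arange(1, c.n_base + 1)]
    total = c.n_base
    g = 0
    while total < c.target_n:
        g += 1
        # mature pools; founders are all mated with no selection
        fem_pool = ids[g - 1][(sex[g - 1] == "F") & alive[g - 1]]
        male_gens = range(max(0, g - 1 - c.male_overlap), g)
        male_pool = np.concatenate(
            [ids[t][(sex[t] == "M") & alive[t]] for t in male_gens]
        )
        if g == 1:
            dams_sel, sires_sel = fem_pool, male_pool
        else:
            n_dams = int(round(c.female_sel * fem_pool.size))
            n_sires = int(round(c.male_sel * male_pool.size))
            if n_dams == 0 or n_sires == 0:
                raise ExtinctionError(
                    f"no selectable parents in generation {g}; "
                    "increase n_base or litter_size"
                )
            dams_sel = rng.choice(fem_pool, size=n_dams, replace=False)
            sires_sel = rng.choice(male_pool, size=n_sires, replace=False)
        # each selected dam is mated litters_per_dam times to sires drawn
        # uniformly with replacement; each mating yields a full-sib litter
        mating_dams = np.repeat(dams_sel, c.litters_per_dam)
        mating_sires = rng.choice(sires_sel, size=mating_dams.size, replace=True)
        n_new = mating_dams.size * c.litter_size
        new_sire = np.repeat(mating_sires, c.litter_size)
        new_dam = np.repeat(mating_dams, c.litter_size)
        new_sex = rng.choice(np.array(["M", "F"]), size=n_new, replace=True)
        new_alive = rng.random(n_new) >= c.mortality
        ids.append(np.arange(total + 1, total + n_new + 1))
        sire.append(new_sire)
        dam.append(new_dam)
        sex.append(new_sex)
        gen_of.append(np.full(n_new, g, dtype=np.int64))
        alive.append(new_alive)
        total += n_new
    return PedigreeTable(
        sire=np.concatenate(sire),
        dam=np.concatenate(dam),
        sex=np.concatenate(sex),
        generation=np.concatenate(gen_of),
    )


def mask_parents(
    ped: PedigreeTable,
    missing_dam_rate: float = 0.10,
    missing_sire_rate: float = 0.20,
    seed: int = 0,
) -> PedigreeTable:
    """Randomly hide parents of non-base individuals.

    Each non-base individual loses its sire record with probability
    ``missing_sire_rate`` and, independently, its dam record with
    probability ``missing_dam_rate``; base-generation records (both
    parents unknown) are untouched.
    """
    if ped.generation is not None:
        non_base = np.asarray(ped.generation) > 0
    else:
        non_base = (ped.sire > 0) | (ped.dam > 0)
    rng = np.random.default_rng(seed)
    drop_sire = non_base & (rng.random(ped.n) < missing_sire_rate)
    drop_dam = non_base & (rng.random(ped.n) < missing_dam_rate)
    return replace(
        ped,
        sire=np.where(drop_sire, 0, ped.sire),
        dam=np.where(drop_dam, 0, ped.dam),
    )


def pedigree_summary(ped: PedigreeTable, F: np.ndarray) -> dict:
    """Descriptive counts of a pedigree and its inbreeding distribution.

    Counts individuals, generations, distinct recorded sires and dams,
    missing-parent records, and the inbred subset (F > 0) with its mean
    and maximum coefficient.
    """
    F = np.asarray(F, dtype=float)
    if F.size != ped.n:
        raise ValueError("inbreeding vector length does not match pedigree")
    if ped.generation is not None:
        n_gen = int(np.max(ped.generation)) + 1
    else:
        from .pedigree_core import stratify_generations

        n_gen = stratify_generations(ped).n_generations
    inbred = F > 0
    return {
        "individuals": int(ped.n),
        "generations": n_gen,
        "sires": int(np.unique(ped.sire[ped.sire > 0]).size),
        "dams": int(np.unique(ped.dam[ped.dam > 0]).size),
        "missing_sires": int(np.sum(ped.sire == 0)),
        "missing_dams": int(np.sum(ped.dam == 0)),
        "missing_both": int(np.sum((ped.sire == 0) & (ped.dam == 0))),
        "inbred": int(inbred.sum()),
        "mean_f_inbred": float(F[inbred].mean()) if inbred.any() else 0.0,
        "max_f": float(F.max()) if ped.n else 0.0,
    }


def random_pedigree(
    n: int,
    founder_frac: float = 0.2,
    missing_rate: float = 0.1,
    seed: int = 0,
) -> PedigreeTable:
    """Arbitrary valid random pedigree for property testing and benchmarks.

    Individuals are created in order; odd ids act as males, even ids as
    females. Each non-founder draws its sire from earlier odd ids and its
    dam from earlier even ids, then each parent is independently hidden
    with ``missing_rate``.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    for j in range(2, n):  # ids 1 and 2 are always founders
        if rng.random() < founder_frac:
            continue
        males = np.arange(1, j + 1, 2)
        females = np.arange(2, j + 1, 2)
        s = int(rng.choice(males)) if rng.random() >= missing_rate else 0
        d = int(rng.choice(females)) if rng.random() >= missing_rate else 0
        sire[j], dam[j] = s, d
    sex = np.where(np.arange(1, n + 1) % 2 == 1, "M", "F")
    return PedigreeTable(sire=sire, dam=dam, sex=sex)
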