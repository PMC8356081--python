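"""Pedigree containers, validation, ordering and text I/O.

A pedigree is a list of (individual, sire, dam) records. After loading,
individuals are renumbered 1..n in a topological order so that every parent
appears before each of its progeny; 0 denotes an unknown parent. All
relationship-matrix constructions in this package consume this ordered form.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeError",
    "PedigreeCycleError",
    "PedigreeTable",
    "GenerationStrata",
    "pedigree_from_arrays",
    "read_pedigree",
    "write_pedigree",
    "topological_order",
    "stratify_generations",
    "count_known_parents",
]

#: strings accepted as "unknown parent" in pedigree files
UNKNOWN_CODES = {"0", "NA", "na", ""}

#: column-name tokens that mark a header line
_HEADER_TOKENS = {
    "id", "ind", "individual", "animal", "progeny",
    "sire", "father", "dam", "mother", "sex", "gen", "generation",
}


class PedigreeError(ValueError):
    """Invalid pedigree (duplicate ids, bad parent codes, ...)."""


class PedigreeCycleError(PedigreeError):
    """An individual is its own ancestor."""


@dataclass(frozen=True)
class PedigreeTable:
    """Topologically ordered pedigree with ids 1..n.

    Attributes
    ----------
    sire, dam : ndarray of int64, length n
        Parent id of individual ``j`` at index ``j - 1``; 0 = unknown.
        Invariant: every known parent id is smaller than its progeny's id.
    sex : ndarray of str or None
        Optional per-individual sex annotation ('M'/'F').
    generation : ndarray of int or None
        Optional per-individual generation annotation (simulator output).
    labels : tuple or None
        Original input label of each individual (index ``id - 1``); kept so
        results can be reported against the labels the caller used.
    """

    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray | None = None
    generation: np.ndarray | None = None
    labels: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "sire", np.asarray(self.sire, dtype=np.int64))
        object.__setattr__(self, "dam", np.asarray(self.dam, dtype=np.int64))
        n = self.sire.size
        if self.dam.size != n:
            raise PedigreeError("sire and dam vectors differ in length")
        ids = np.arange(1, n + 1)
        for name, p in (("sire", self.sire), ("dam", self.dam)):
            if np.any((p < 0) | (p > n)):
                raise PedigreeError(f"{name} id out of range 0..{n}")
            if np.any(p >= ids):
                j = int(ids[p >= ids][0])
                raise PedigreeError(
                    f"pedigree not parent-before-progeny ordered at individual {j}"
                )
        both_zero = (self.sire == 0) & (self.dam == 0)
        if np.any((self.sire == self.dam) & ~both_zero):
            j = int(ids[(self.sire == self.dam) & ~both_zero][0])
            raise PedigreeError(f"individual {j} has sire == dam")

    @property
    def n(self) -> int:
        return self.sire.size

    def __len__(self) -> int:
        return self.n

    @property
    def label_to_id(self) -> dict:
        if self.labels is None:
            return {i: i for i in range(1, self.n + 1)}
        return {lab: i + 1 for i, lab in enumerate(self.labels)}

    def to_frame(self) -> pd.DataFrame:
        """Return the pedigree as a DataFrame (internal 1..n ids)."""
        df = pd.DataFrame(
            {"id": np.arange(1, self.n + 1), "sire": self.sire, "dam": self.dam}
        )
        if self.sex is not None:
            df["sex"] = self.sex
        if self.generation is not None:
            df["generation"] = self.generation
        return df


@dataclass(frozen=True)
class GenerationStrata:
    """Generation assignment: 0 for founders, else 1 + max(parent generations)."""

    gen: np.ndarray
    members: tuple = field(default=())  # members[g] = array of ids in generation g

    @property
    def n_generations(self) -> int:
        return int(self.gen.max()) + 1 if self.gen.size else 0


def _toposort(sires: np.ndarray, dams: np.ndarray) -> np.ndarray:
    """Kahn's algorithm over 0-based parent indices (-1 = unknown).

    Ties are broken by original position, so an already-ordered input maps to
    the identity permutation. Returns positions in topological order.
    """
    n = sires.size
    n_pending = (sires >= 0).astype(np.int64) + (dams >= 0).astype(np.int64)
    children: list[list[int]] = [[] for _ in range(n)]
    for j in range(n):
        if sires[j] >= 0:
            children[sires[j]].append(j)
        if dams[j] >= 0:
            children[dams[j]].append(j)
    ready = [j for j in range(n) if n_pending[j] == 0]
    heapq.heapify(ready)
    order = np.empty(n, dtype=np.int64)
    k = 0
    while ready:
        j = heapq.heappop(ready)
        order[k] = j
        k += 1
        for c in children[j]:
            n_pending[c] -= 1
            if n_pending[c] == 0:
                heapq.heappush(ready, c)
    if k < n:
        stuck = int(np.nonzero(n_pending > 0)[0][0])
        raise PedigreeCycleError(
            f"pedigree contains a cycle involving individual at input position "
            f"{stuck + 1}"
        )
    return order


def pedigree_from_arrays(ids, sires, dams, sex=None, generation=None) -> PedigreeTable:
    """Validate, renumber and topologically order a raw pedigree.

    ``ids`` may be arbitrary labels (strings or integers). Unknown parents are
    coded 0/None/NaN/'NA'/''. Parents referenced but never listed are appended
    as founders with a warning.
    """
    ids = list(ids)
    n0 = len(ids)

    def norm(x):
        if x is None:
            return None
        if isinstance(x, float) and np.isnan(x):
            return None
        s = str(x).strip()
        if s in UNKNOWN_CODES:
            return None
        # canonicalise numeric labels: "3" and "3.0" and 3 are the same id
        try:
            f = float(s)
            if f == int(f):
                return int(f)
        except ValueError:
            pass
        return s

    labels = [norm(x) for x in ids]
    if any(lab is None for lab in labels):
        raise PedigreeError("individual id missing or coded as unknown")
    seen: dict = {}
    for pos, lab in enumerate(labels):
        if lab in seen:
            raise PedigreeError(f"duplicate individual id {lab!r}")
        seen[lab] = pos
    sires = [norm(x) for x in sires]
    dams = [norm(x) for x in dams]
    if len(sires) != n0 or len(dams) != n0:
        raise PedigreeError("id, sire and dam columns differ in length")

    # append parents that never appear as individuals, as founders
    extra = []
    for p in sires + dams:
        if p is not None and p not in seen and p not in extra:
            extra.append(p)
    if extra:
        warnings.warn(
            f"{len(extra)} parent(s) not listed as individuals; appended as founders",
            stacklevel=2,
        )
        for p in extra:
            seen[p] = len(labels)
            labels.append(p)
            sires.append(None)
            dams.append(None)

    n = len(labels)
    s_idx = np.array([-1 if p is None else seen[p] for p in sires], dtype=np.int64)
    d_idx = np.array([-1 if p is None else seen[p] for p in dams], dtype=np.int64)
    self_par = (s_idx == np.arange(n)) | (d_idx == np.arange(n))
    if np.any(self_par):
        j = int(np.nonzero(self_par)[0][0])
        raise PedigreeCycleError(f"individual {labels[j]!r} is its own parent")
    same = (s_idx == d_idx) & (s_idx >= 0)
    if np.any(same):
        j = int(np.nonzero(same)[0][0])
        raise PedigreeError(f"individual {labels[j]!r} has sire == dam")

    order = _toposort(s_idx, d_idx)  # positions in topological order
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)  # position -> new 0-based id

    new_sire = np.zeros(n, dtype=np.int64)
    new_dam = np.zeros(n, dtype=np.int64)
    for new0, pos in enumerate(order):
        new_sire[new0] = rank[s_idx[pos]] + 1 if s_idx[pos] >= 0 else 0
        new_dam[new0] = rank[d_idx[pos]] + 1 if d_idx[pos] >= 0 else 0

    def reorder_annot(a, fill):
        if a is None:
            return None
        a = list(a) + [fill] * (n - n0)
        return np.asarray([a[pos] for pos in order])

    return PedigreeTable(
        sire=new_sire,
        dam=new_dam,
        sex=reorder_annot(sex, "U"),
        generation=reorder_annot(generation, 0),
        labels=tuple(labels[pos] for pos in order),
    )


def _sniff(path) -> tuple[str, bool]:
    """Return (delimiter regex, has_header) for a pedigree text file."""
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        sep = "\t"
    elif "," in first:
        sep = ","
    else:
        sep = r"\s+"
    tokens = [t.strip().lower() for t in pd.Series([first]).str.split(sep)[0]]
    has_header = any(t in _HEADER_TOKENS for t in tokens)
    return sep, has_header


def read_pedigree(path, sep=None, header=None) -> PedigreeTable:
    """Read a delimited pedigree file (>= 3 columns: id, sire, dam).

    Delimiter and header line are sniffed when not given; extra trailing
    columns are ignored, except columns named sex/generation in a header,
    which are kept as annotations. Unknown parents: 0, NA or empty.
    """
    auto_sep, auto_header = _sniff(path)
    sep = sep if sep is not None else auto_sep
    header = header if header is not None else auto_header
    df = pd.read_csv(
        path,
        sep=sep,
        header=0 if header else None,
        dtype=str,
        comment="#",
        skip_blank_lines=True,
        engine="python",
    )
    if df.shape[1] < 3:
        raise PedigreeError(f"{path}: need at least 3 columns, found {df.shape[1]}")
    cols = [str(c).strip().lower() for c in df.columns]
    sex = gen = None
    if header:
        if "sex" in cols:
            sex = df.iloc[:, cols.index("sex")].to_numpy()
        for g in ("generation", "gen"):
            if g in cols:
                gen = df.iloc[:, cols.index(g)].astype(int).to_numpy()
                break
    return pedigree_from_arrays(
        df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2], sex=sex, generation=gen
    )


def write_pedigree(ped: PedigreeTable, path, sep="\t") -> None:
    """Write the ordered pedigree (with any annotations) as delimited text."""
    ped.to_frame().to_csv(path, sep=sep, index=False)


def topological_order(ped: PedigreeTable) -> np.ndarray:
    """Permutation (1-based ids) placing parents before progeny.

    An already-ordered :class:`PedigreeTable` (the invariant of this package)
    yields the identity permutation; exposed for re-checking external tables.
    """
    order = _toposort(ped.sire - 1, ped.dam - 1)
    return order + 1


def count_known_parents(ped: PedigreeTable) -> np.ndarray:
    """p_j in {0, 1, 2}: number of known (nonzero) parents per individual."""
    return (ped.sire > 0).astype(np.int64) + (ped.dam > 0).astype(np.int64)


def stratify_generations(ped: PedigreeTable) -> GenerationStrata:
    """Assign generations: founders (no known parent) are generation 0;
    otherwise gen(j) = 1 + max generation over known parents, so every
    individual in generation i > 0 has a known parent in generation i - 1.
    """
    n = ped.n
    gen = np.zeros(n, dtype=np.int64)
    for j in range(n):
        g = -1
        if ped.sire[j] > 0:
            g = gen[ped.sire[j] - 1]
        if ped.dam[j] > 0:
            g = max(g, gen[ped.dam[j] - 1])
        gen[j] = g + 1
    ids = np.arange(1, n + 1)
    members = tuple(ids[gen == g] for g in range(gen.max() + 1 if n else 0))
    return GenerationStrata(gen=gen, members=members)


def append_individual(ped: PedigreeTable, sire: int, dam: int) -> PedigreeTable:
    """Return a new table with one extra individual (id n+1) appended."""
    pad = lambda a, v: None if a is None else np.append(a, v)
    return replace(
        ped,
        sire=np.append(ped.sire, sire),
        dam=np.append(ped.dam, dam),
        sex=pad(ped.sex, "U"),
        generation=None,  # not maintained for ad-hoc appends
        labels=None if ped.labels is None else ped.labels + (ped.n + 1,),
    )
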