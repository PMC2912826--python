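"""Pedigree storage and the additive (numerator) relationship matrix A.

The pedigree drives both stages of the evaluation: the Cox frailty animal
model penalizes the genetic effects with A⁻¹, and the linear mixed model uses
A ⊗ G0 as genetic covariance. A is computed by the tabular (recursive)
method with exact inbreeding; its sparse inverse is assembled directly from
pedigree structure by Henderson's rules with the inbreeding adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

UNKNOWN = -1


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Animals in topological order (parents before offspring).

    ``ids`` are opaque strings; ``sire_idx``/``dam_idx`` hold positions into
    ``ids`` or ``UNKNOWN`` (-1). Unknown-parent animals are founders:
    unrelated and non-inbred.
    """

    ids: list[str]
    sire_idx: np.ndarray
    dam_idx: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)
    _A: np.ndarray | None = field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {a: i for i, a in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise PedigreeError("duplicate animal identifiers in pedigree")

    # -- construction -------------------------------------------------

    @classmethod
    def from_parent_map(
        cls,
        animals: list[str],
        sire_of: dict[str, str | None],
        dam_of: dict[str, str | None],
    ) -> "Pedigree":
        """Build a pedigree, topologically sorting if needed.

        Parents referenced but not listed as animals are added as founders.
        Raises :class:`PedigreeError` on a cycle (an animal that is its own
        ancestor).
        """
        seen = set(animals)
        if len(seen) != len(animals):
            dupes = [a for a in seen if animals.count(a) > 1]
            raise PedigreeError(f"duplicate animal rows: {dupes[:5]}")
        order = list(animals)
        extra = []
        for a in animals:
            for p in (sire_of.get(a), dam_of.get(a)):
                if p is not None and p not in seen:
                    seen.add(p)
                    extra.append(p)
        if extra:
            logger.info("added %d parents without own rows as founders", len(extra))
        order = extra + order

        # Kahn's algorithm, stable in input order.
        parents = {
            a: tuple(p for p in (sire_of.get(a), dam_of.get(a)) if p is not None)
            for a in order
        }
        children: dict[str, list[str]] = {a: [] for a in order}
        indeg = {a: 0 for a in order}
        for a, ps in parents.items():
            for p in ps:
                children[p].append(a)
                indeg[a] += 1
        ready = [a for a in order if indeg[a] == 0]
        topo: list[str] = []
        pos = 0
        while pos < len(ready):
            a = ready[pos]
            pos += 1
            topo.append(a)
            for c in children[a]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        if len(topo) != len(order):
            stuck = [a for a in order if indeg[a] > 0]
            raise PedigreeError(
                f"animal {stuck[0]!r} is its own ancestor (pedigree cycle)"
            )
        if topo != order:
            logger.info("pedigree reordered so parents precede offspring")

        idx = {a: i for i, a in enumerate(topo)}
        sire = np.full(len(topo), UNKNOWN, dtype=np.int64)
        dam = np.full(len(topo), UNKNOWN, dtype=np.int64)
        for a in topo:
            s, d = sire_of.get(a), dam_of.get(a)
            if s is not None:
                sire[idx[a]] = idx[s]
            if d is not None:
                dam[idx[a]] = idx[d]
        return cls(topo, sire, dam)

    # -- basic queries -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, animal: str) -> int:
        try:
            return self._index[animal]
        except KeyError:
            raise PedigreeError(f"unknown animal id {animal!r}") from None

    def indices(self, animals) -> np.ndarray:
        return np.asarray([self.index(a) for a in animals], dtype=np.int64)

    def ensure(self, animals) -> "Pedigree":
        """Return a pedigree containing every id in ``animals``.

        Ids absent from this pedigree are appended as founders (the
        unknown-pedigree convention: records kept, treated as unrelated).
        """
        missing = [a for a in pd.unique(np.asarray(animals, dtype=object)) if a not in self._index]
        if not missing:
            return self
        logger.info("flagging %d animals with unknown pedigree as founders", len(missing))
        ids = self.ids + [str(a) for a in missing]
        sire = np.concatenate([self.sire_idx, np.full(len(missing), UNKNOWN, dtype=np.int64)])
        dam = np.concatenate([self.dam_idx, np.full(len(missing), UNKNOWN, dtype=np.int64)])
        return Pedigree(ids, sire, dam)

    # -- relationship matrix -------------------------------------------

    def relationship_matrix(self) -> np.ndarray:
        """Dense additive relationship matrix A by the tabular method.

        a_ij = average relationship through j's parents; a_ii = 1 + F_i with
        F_i = a(sire, dam)/2. Cached after first computation.
        """
        if self._A is not None:
            return self._A
        n = self.n
        A = np.zeros((n, n))
        s, d = self.sire_idx, self.dam_idx
        for i in range(n):
            si, di = s[i], d[i]
            row = np.zeros(i)
            if si != UNKNOWN:
                row += 0.5 * A[si, :i]
            if di != UNKNOWN:
                row += 0.5 * A[di, :i]
            A[i, :i] = row
            A[:i, i] = row
            aii = 1.0
            if si != UNKNOWN and di != UNKNOWN:
                aii += 0.5 * A[si, di]
            A[i, i] = aii
        self._A = A
        return A

    def inbreeding(self) -> np.ndarray:
        """F_i = a_ii - 1, computed exactly via the tabular A."""
        return np.diag(self.relationship_matrix()) - 1.0

    def relationship(self, i: str, j: str) -> float:
        """Additive relationship a_ij between two animals (∈ [0, 2])."""
        A = self.relationship_matrix()
        return float(A[self.index(i), self.index(j)])

    def a_inverse(self) -> sparse.csr_matrix:
        """Sparse A⁻¹ by Henderson's rules with the inbreeding adjustment.

        The Mendelian-sampling variance of animal i is
        m_i = 0.5 − 0.25(F_s + F_d) with both parents known,
        m_i = 0.75 − 0.25 F_p with one parent known, and 1 for founders.
        """
        F = self.inbreeding()
        n = self.n
        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []

        def add(r: int, c: int, v: float) -> None:
            rows.append(r)
            cols.append(c)
            vals.append(v)

        for i in range(n):
            si, di = self.sire_idx[i], self.dam_idx[i]
            known = [p for p in (si, di) if p != UNKNOWN]
            if len(known) == 2:
                m = 0.5 - 0.25 * (F[si] + F[di])
            elif len(known) == 1:
                m = 0.75 - 0.25 * F[known[0]]
            else:
                m = 1.0
            alpha = 1.0 / m
            add(i, i, alpha)
            for p in known:
                add(i, p, -alpha / 2.0)
                add(p, i, -alpha / 2.0)
            for p in known:
                for q in known:
                    add(p, q, alpha / 4.0)
        Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        Ainv.sum_duplicates()
        return Ainv


def read_pedigree(path) -> Pedigree:
    """Read a pedigree file with columns animal, sire, dam.

    Comma- or tab-delimited with a header; ``0``, empty, or NA parent codes
    mean unknown. Duplicate animal rows are rejected; rows listed before
    their parents are reordered (logged).
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"animal", "sire", "dam"}
    if not required.issubset(df.columns):
        raise PedigreeError(f"pedigree file must have columns {sorted(required)}")

    def clean(v: str) -> str | None:
        v = v.strip()
        return None if v in ("", "0", "NA", "na", ".") else v

    animals = [a.strip() for a in df["animal"]]
    sire_of = {a: clean(s) for a, s in zip(animals, df["sire"])}
    dam_of = {a: clean(d) for a, d in zip(animals, df["dam"])}
    return Pedigree.from_parent_map(animals, sire_of, dam_of)


def write_pedigree(ped: Pedigree, path) -> None:
    """Write a pedigree in the canonical animal,sire,dam CSV format."""
    sire = [ped.ids[s] if s != UNKNOWN else "0" for s in ped.sire_idx]
    dam = [ped.ids[d] if d != UNKNOWN else "0" for d in ped.dam_idx]
    pd.DataFrame({"animal": ped.ids, "sire": sire, "dam": dam}).to_csv(path, index=False)
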