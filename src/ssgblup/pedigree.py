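"""Pedigree handling and the numerator relationship matrix A.

A pedigree is a list of (animal, sire, dam) triples.  From it we build the
additive (numerator) relationship matrix A by the tabular method, its sparse
inverse by Henderson's rules with inbreeding coefficients computed by the
Meuwissen-Luo recursion, and the block algebra the single-step method needs:
with animals partitioned into a genotyped block (index 1) and a
non-genotyped block (index 2),

    A11        = ((A^-1)_11 - (A^-1)_12 (A^-1)_22^-1 (A^-1)_21)^-1
    A21 A11^-1 = -(A^-1)_22^-1 (A^-1)_21
    log det(A22 - A21 A11^-1 A12) = -log det((A^-1)_22)

so that only A^-1 (sparse) and the small genotyped block are ever formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

__all__ = [
    "Pedigree",
    "AnimalPartition",
    "RelationshipMatrix",
    "PedigreeProjection",
    "read_pedigree",
    "write_pedigree",
    "build_A",
    "build_A_inverse",
    "a11_inverse_projection",
]

UNKNOWN = -1  # internal code for an unknown parent


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Topologically sorted pedigree: parents always precede offspring.

    ``ids`` is the sorted animal order; ``sire`` / ``dam`` hold positional
    parent indices into ``ids`` (-1 = unknown).  ``input_order`` preserves
    the order in which animals were supplied.
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    input_order: list = field(default_factory=list)

    def __post_init__(self):
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self._index = {a: i for i, a in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise PedigreeError("duplicate animal ids")
        if np.any(self.sire >= np.arange(len(self.ids))) or np.any(
            self.dam >= np.arange(len(self.ids))
        ):
            raise PedigreeError("pedigree not topologically sorted")
        if not self.input_order:
            self.input_order = list(self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, animals) -> np.ndarray:
        """Positions of ``animals`` in the topological order."""
        try:
            return np.array([self._index[a] for a in animals], dtype=np.int64)
        except KeyError as e:
            raise PedigreeError(f"animal {e.args[0]!r} not in pedigree") from None

    def __contains__(self, animal) -> bool:
        return animal in self._index

    @classmethod
    def from_records(cls, records, unknown="0", add_missing_parents=True) -> "Pedigree":
        """Build from (animal, sire, dam) triples in any order.

        ``unknown`` is the unknown-parent token.  Parents that never appear
        as animals are auto-added as founders when ``add_missing_parents``,
        otherwise an error is raised.
        """
        records = [(a, s, d) for a, s, d in records]
        seen = set()
        for a, _, _ in records:
            if a in seen:
                raise PedigreeError(f"duplicate animal id {a!r}")
            seen.add(a)
        parents = {}
        for a, s, d in records:
            parents[a] = (None if s == unknown else s, None if d == unknown else d)
        extra = []
        for a, (s, d) in list(parents.items()):
            for p in (s, d):
                if p is not None and p not in parents and p not in {x for x, _ in extra}:
                    if not add_missing_parents:
                        raise PedigreeError(f"parent {p!r} of {a!r} is not in the pedigree")
                    extra.append((p, (None, None)))
        for p, pd_ in extra:
            parents[p] = pd_
        input_order = [a for a, _, _ in records] + [p for p, _ in extra]

        # Kahn's algorithm; on failure name an animal on a cycle.
        children = {a: [] for a in parents}
        indeg = {a: 0 for a in parents}
        for a, (s, d) in parents.items():
            for p in (s, d):
                if p is not None:
                    children[p].append(a)
                    indeg[a] += 1
            if s is not None and s == d is not None and s == a:
                pass  # self-parent caught as cycle below
        order = [a for a in input_order if indeg[a] == 0]
        head = 0
        while head < len(order):
            a = order[head]
            head += 1
            for c in children[a]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    order.append(c)
        if len(order) < len(parents):
            on_cycle = sorted((a for a in parents if indeg[a] > 0), key=str)[0]
            raise PedigreeError(f"pedigree contains a cycle involving animal {on_cycle!r}")
        pos = {a: i for i, a in enumerate(order)}
        sire = np.array([UNKNOWN if parents[a][0] is None else pos[parents[a][0]] for a in order])
        dam = np.array([UNKNOWN if parents[a][1] is None else pos[parents[a][1]] for a in order])
        return cls(order, sire, dam, input_order=input_order)

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F by the Meuwissen-Luo recursion.

        Also caches the Mendelian-sampling variances d_i used by both A and
        its sparse inverse.
        """
        n = len(self)
        F = np.zeros(n)
        D = np.zeros(n)
        sire, dam = self.sire, self.dam
        for i in range(n):
            s, d = sire[i], dam[i]
            if s == UNKNOWN and d == UNKNOWN:
                D[i] = 1.0
            elif s == UNKNOWN or d == UNKNOWN:
                p = d if s == UNKNOWN else s
                D[i] = 0.75 - 0.25 * F[p]
            else:
                D[i] = 0.5 - 0.25 * (F[s] + F[d])
            if s == UNKNOWN or d == UNKNOWN:
                F[i] = 0.0
                continue
            # A_ii = sum_j L_ij^2 d_j accumulated by walking ancestors in
            # decreasing index order, so every L_ij is complete when popped.
            coeff = {i: 1.0}
            aii = 0.0
            while coeff:
                j = max(coeff)
                c = coeff.pop(j)
                aii += c * c * D[j]
                for p in (sire[j], dam[j]):
                    if p != UNKNOWN:
                        coeff[p] = coeff.get(p, 0.0) + 0.5 * c
            F[i] = aii - 1.0
        self._D = D
        return F

    def mendelian_variances(self) -> np.ndarray:
        if not hasattr(self, "_D"):
            self.inbreeding()
        return self._D


@dataclass
class AnimalPartition:
    """Ordered split of the animals: genotyped (block 1) first, then
    non-genotyped (block 2); ``external`` (block 3) holds animals outside
    the estimation run."""

    genotyped: list
    non_genotyped: list
    external: list = field(default_factory=list)

    def __post_init__(self):
        sets = [set(self.genotyped), set(self.non_genotyped), set(self.external)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise PedigreeError("partition blocks are not disjoint")

    @classmethod
    def from_pedigree(cls, ped: Pedigree, genotyped) -> "AnimalPartition":
        gset = set(genotyped)
        missing = gset - set(ped.ids)
        if missing:
            raise PedigreeError(f"genotyped animals not in pedigree: {sorted(missing, key=str)[:5]}")
        return cls(list(genotyped), [a for a in ped.ids if a not in gset])

    @property
    def estimation_order(self) -> list:
        return list(self.genotyped) + list(self.non_genotyped)

    @property
    def n1(self) -> int:
        return len(self.genotyped)


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix over an ordered animal set.

    ``flavor`` tags the construction: "A" (pedigree), "G" (marker),
    "G_star" (pedigree-extended G) or "G_w" (polygenic blend).
    """

    ids: list
    values: np.ndarray
    flavor: str = "A"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship matrix shape does not match animal list")

    def loc(self, a, b) -> float:
        idx = {x: i for i, x in enumerate(self.ids)}
        return float(self.values[idx[a], idx[b]])


def read_pedigree(path, unknown="0", add_missing_parents=True) -> Pedigree:
    """Read a headered CSV/TSV with columns animal, sire, dam."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise PedigreeError("pedigree file needs 3 columns: animal, sire, dam")
    records = list(df.iloc[:, :3].itertuples(index=False, name=None))
    return Pedigree.from_records(records, unknown=unknown, add_missing_parents=add_missing_parents)


def write_pedigree(ped: Pedigree, path, unknown="0", sep=","):
    rows = []
    for a in ped.input_order:
        i = ped.index([a])[0]
        s = unknown if ped.sire[i] == UNKNOWN else ped.ids[ped.sire[i]]
        d = unknown if ped.dam[i] == UNKNOWN else ped.ids[ped.dam[i]]
        rows.append((a, s, d))
    pd.DataFrame(rows, columns=["animal", "sire", "dam"]).to_csv(path, sep=sep, index=False)


def build_A(ped: Pedigree, subset=None) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Computed over the full ancestral pedigree (so inbreeding is exact) and
    then sliced to ``subset`` if given.  Dense; intended for moderate
    pedigrees and for oracle checks of the sparse algebra.
    """
    n = len(ped)
    if subset is not None:
        idx = ped.index(subset)
        if idx.size == 0:
            raise PedigreeError("empty subset")
    # column n is a permanent zero column standing in for unknown parents
    A = np.zeros((n + 1, n + 1))
    sire = np.where(ped.sire == UNKNOWN, n, ped.sire)
    dam = np.where(ped.dam == UNKNOWN, n, ped.dam)
    for i in range(n):
        s, d = sire[i], dam[i]
        A[:i, i] = 0.5 * (A[:i, s] + A[:i, d])
        A[i, :i] = A[:i, i]
        A[i, i] = 1.0 + 0.5 * A[s, d]
    A = A[:n, :n]
    if subset is None:
        return RelationshipMatrix(list(ped.ids), A, flavor="A")
    return RelationshipMatrix(list(subset), A[np.ix_(idx, idx)], flavor="A")


def build_A_inverse(ped: Pedigree) -> sp.csc_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding.

    Never forms A: the inverse is assembled from the per-animal Mendelian
    sampling variances d_i (Meuwissen-Luo), contributing for each animal the
    familiar (animal, sire, dam) stamp 1/d_i * [1, -1/2, -1/2]^T [..].
    Returned in the pedigree's topological order.
    """
    n = len(ped)
    D = ped.mendelian_variances()
    rows, cols, vals = [], [], []
    for i in range(n):
        b = 1.0 / D[i]
        par = [p for p in (ped.sire[i], ped.dam[i]) if p != UNKNOWN]
        rows.append(i)
        cols.append(i)
        vals.append(b)
        for p in par:
            rows += [i, p]
            cols += [p, i]
            vals += [-0.5 * b, -0.5 * b]
        for p in par:
            for q in par:
                rows.append(p)
                cols.append(q)
                vals.append(0.25 * b)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()


def _splu_logdet(lu) -> float:
    diag = lu.U.diagonal()
    return float(np.sum(np.log(np.abs(diag))))


@dataclass
class PedigreeProjection:
    """Block algebra of A for a genotyped/non-genotyped partition.

    Holds dense A11 (the genotyped block is assumed small), the sparse
    factorisation of (A^-1)_22 behind the projections A21 A11^-1 (side 1 to
    side 2) and A11^-1 A12 (side 2 to side 1), and the Schur log-determinant
    log det(A22 - A21 A11^-1 A12) = -log det((A^-1)_22).
    """

    partition: AnimalPartition
    A11: np.ndarray
    A11_inv: np.ndarray
    schur_logdet: float
    Ainv: sp.csc_matrix  # full estimation-set A^-1 in block order (1 then 2)
    _Ainv21: sp.csc_matrix | None = None
    _lu22 = None

    @property
    def n1(self) -> int:
        return self.A11.shape[0]

    @property
    def n2(self) -> int:
        return self.Ainv.shape[0] - self.n1

    def proj_21(self, V) -> np.ndarray:
        """A21 A11^-1 V for V with side-1 rows; returns side-2 rows."""
        V = np.asarray(V, dtype=float)
        if self.n2 == 0:
            return np.zeros((0,) + V.shape[1:])
        return -self._solve22(self._Ainv21 @ V)

    def proj_12(self, V) -> np.ndarray:
        """A11^-1 A12 V for V with side-2 rows; returns side-1 rows."""
        V = np.asarray(V, dtype=float)
        if self.n2 == 0:
            return np.zeros((self.n1,) + V.shape[1:])
        return -(self._Ainv21.T @ self._solve22(V))

    def _solve22(self, B):
        B = np.asarray(B, dtype=float)
        one_d = B.ndim == 1
        X = self._lu22.solve(B if not one_d else B[:, None])
        return X[:, 0] if one_d else X


def a11_inverse_projection(ped: Pedigree, part: AnimalPartition) -> PedigreeProjection:
    """A11, the pedigree projections, and the Schur log-determinant, all
    from the sparse A^-1 only.

    Relies on the block-inverse identities
    A11 = (S)^-1 with S = (A^-1)_11 - (A^-1)_12 (A^-1)_22^-1 (A^-1)_21 and
    A21 A11^-1 = -(A^-1)_22^-1 (A^-1)_21.
    """
    if part.n1 == 0:
        raise PedigreeError("partition has no genotyped animals")
    order = part.estimation_order
    perm = ped.index(order)
    if len(order) != len(ped):
        raise PedigreeError("partition must cover the estimation pedigree")
    Ainv = build_A_inverse(ped)[perm][:, perm].tocsc()
    n1 = part.n1
    n2 = Ainv.shape[0] - n1
    if n2 == 0:
        S = Ainv.toarray()
        A11 = np.linalg.inv(S)
        proj = PedigreeProjection(part, A11, S, 0.0, Ainv)
        return proj
    Ainv11 = Ainv[:n1, :n1]
    Ainv21 = Ainv[n1:, :n1].tocsc()
    Ainv22 = Ainv[n1:, n1:].tocsc()
    lu22 = splu(Ainv22, permc_spec="MMD_AT_PLUS_A")
    S = Ainv11.toarray() - Ainv21.T @ lu22.solve(Ainv21.toarray())
    S = 0.5 * (S + S.T)
    try:
        A11 = np.linalg.inv(S)
    except np.linalg.LinAlgError as e:
        raise PedigreeError("A11 is numerically singular") from e
    proj = PedigreeProjection(part, A11, S, -_splu_logdet(lu22), Ainv, _Ainv21=Ainv21)
    proj._lu22 = lu22
    return proj


def export_A_inverse(ped: Pedigree, path, sep="\t"):
    """Write A^-1 as (animal_i, animal_j, value) triplets, lower triangle."""
    Ainv = build_A_inverse(ped).tocoo()
    mask = Ainv.row >= Ainv.col
    ids = np.asarray(ped.ids, dtype=object)
    pd.DataFrame(
        {
            "animal_i": ids[Ainv.row[mask]],
            "animal_j": ids[Ainv.col[mask]],
            "value": Ainv.data[mask],
        }
    ).to_csv(path, sep=sep, index=False)
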