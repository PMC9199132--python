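"""Pedigree handling and additive (numerator) relationship matrices.

The animal-model analyses in this package need three pedigree-derived
objects: per-individual inbreeding coefficients F, the numerator
relationship matrix A (expected additive relationships: 0.5 for
parent-offspring and full sibs, 0.25 for half sibs in non-inbred
pedigrees), and the sparse inverse of A that enters Henderson's
mixed-model equations.

Inbreeding is computed with the Meuwissen-Luo tabular-kinship recursion,
A with the standard tabular method, and A^-1 directly from pedigree
structure via Henderson's rules with Quaas' inbreeding correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = "0"

__all__ = [
    "UNKNOWN",
    "PedigreeRecord",
    "OrderedPedigree",
    "RelationshipMatrix",
    "PedigreeCycleError",
    "UnknownParentError",
    "validate_and_order",
    "inbreeding_coefficients",
    "numerator_relationship_matrix",
    "relationship_inverse",
    "read_pedigree_csv",
    "write_pedigree_csv",
]


class PedigreeCycleError(ValueError):
    """An individual is its own ancestor."""


class UnknownParentError(KeyError):
    """A parent label does not appear as an individual in the pedigree."""


def _is_unknown(label) -> bool:
    return label is None or label == "" or str(label) == UNKNOWN


@dataclass(frozen=True)
class PedigreeRecord:
    """One pedigree entry: an individual and its (possibly unknown) parents."""

    individual_id: str
    sire_id: str = UNKNOWN
    dam_id: str = UNKNOWN

    @property
    def is_founder(self) -> bool:
        return _is_unknown(self.sire_id) and _is_unknown(self.dam_id)

    @property
    def role(self) -> str:
        return "founder" if self.is_founder else "progeny"


@dataclass
class OrderedPedigree:
    """Topologically ordered pedigree with integer parent pointers.

    ``sire`` / ``dam`` hold the 0-based position of each parent, or -1
    for an unknown parent; parents always precede offspring.  ``F`` is
    filled lazily by :func:`inbreeding_coefficients`.
    """

    ids: list[str]
    sire: np.ndarray  # int, -1 = unknown
    dam: np.ndarray
    index_of: dict[str, int] = field(default_factory=dict)
    F: np.ndarray | None = None

    def __post_init__(self):
        if not self.index_of:
            self.index_of = {lab: i for i, lab in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def records(self) -> list[PedigreeRecord]:
        out = []
        for i, lab in enumerate(self.ids):
            s = self.ids[self.sire[i]] if self.sire[i] >= 0 else UNKNOWN
            d = self.ids[self.dam[i]] if self.dam[i] >= 0 else UNKNOWN
            out.append(PedigreeRecord(lab, s, d))
        return out

    @property
    def founders(self) -> np.ndarray:
        return np.flatnonzero((self.sire < 0) & (self.dam < 0))

    def inbreeding(self) -> np.ndarray:
        if self.F is None:
            self.F = inbreeding_coefficients(self)
        return self.F


@dataclass
class RelationshipMatrix:
    """Numerator relationship matrix A and its sparse inverse."""

    ids: list[str]
    A: np.ndarray | None = None
    A_inv: sp.csr_matrix | None = None

    def value(self, id_i: str, id_j: str) -> float:
        i = self.ids.index(id_i)
        j = self.ids.index(id_j)
        return float(self.A[i, j])


def validate_and_order(records) -> OrderedPedigree:
    """Validate a collection of :class:`PedigreeRecord` and sort it
    topologically (parents before offspring).

    Ordering is deterministic: among individuals whose parents are all
    already placed, input order is preserved (stable Kahn traversal).

    Raises
    ------
    PedigreeCycleError
        if an individual is its own ancestor (self-parenting included).
    UnknownParentError
        if a named parent never appears as an individual.
    ValueError
        on duplicated individual labels.
    """
    records = list(records)
    ids = [str(r.individual_id) for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicated individual ids: {dup}")
    pos = {lab: k for k, lab in enumerate(ids)}

    parents = []
    for r in records:
        ps = []
        for lab in (r.sire_id, r.dam_id):
            if _is_unknown(lab):
                ps.append(-1)
            else:
                lab = str(lab)
                if lab not in pos:
                    raise UnknownParentError(
                        f"parent {lab!r} of {r.individual_id!r} is not in the pedigree"
                    )
                if lab == str(r.individual_id):
                    raise PedigreeCycleError(
                        f"individual {r.individual_id!r} is its own parent"
                    )
                ps.append(pos[lab])
        parents.append(ps)

    # stable Kahn: repeatedly emit, in input order, individuals whose
    # parents are already emitted
    n = len(records)
    placed = np.zeros(n, dtype=bool)
    order: list[int] = []
    remaining = list(range(n))
    while remaining:
        emitted = []
        for k in remaining:
            s, d = parents[k]
            if (s < 0 or placed[s]) and (d < 0 or placed[d]):
                order.append(k)
                placed[k] = True
                emitted.append(k)
        if not emitted:
            # every remaining individual waits on another remaining one
            lab = ids[remaining[0]]
            raise PedigreeCycleError(
                f"pedigree cycle detected involving individual {lab!r}"
            )
        remaining = [k for k in remaining if not placed[k]]

    new_pos = {k: i for i, k in enumerate(order)}
    ordered_ids = [ids[k] for k in order]
    sire = np.array(
        [new_pos[parents[k][0]] if parents[k][0] >= 0 else -1 for k in order],
        dtype=np.int64,
    )
    dam = np.array(
        [new_pos[parents[k][1]] if parents[k][1] >= 0 else -1 for k in order],
        dtype=np.int64,
    )
    return OrderedPedigree(ids=ordered_ids, sire=sire, dam=dam)


def inbreeding_coefficients(ped: OrderedPedigree) -> np.ndarray:
    """Inbreeding coefficients F by the Meuwissen-Luo algorithm.

    F_i is the kinship between i's parents; founders (and any individual
    with an unknown parent) get F = 0.  O(n * pedigree depth) time via
    the L-matrix / within-family variance recursion.
    """
    n = ped.n
    s, d = ped.sire, ped.dam
    F = np.zeros(n)
    # D_i = within-family (mendelian sampling) variance coefficient
    Dvec = np.zeros(n)
    for i in range(n):
        fs = F[s[i]] if s[i] >= 0 else 0.0
        fd = F[d[i]] if d[i] >= 0 else 0.0
        ns = 0.5 if s[i] >= 0 else 0.0
        nd = 0.5 if d[i] >= 0 else 0.0
        # var of mendelian term: 1 - 0.25(1+Fs) - 0.25(1+Fd), with a
        # missing parent contributing as an unrelated non-inbred founder
        Dvec[i] = 1.0 - ns * 0.5 * (1.0 + fs) - nd * 0.5 * (1.0 + fd)
        if s[i] < 0 or d[i] < 0:
            F[i] = 0.0
            continue
        # row i of the L matrix (path coefficients to every ancestor),
        # accumulated by one descending sweep: each ancestor is final
        # once all its descendants on the path set have been visited
        L: dict[int, float] = {i: 1.0}
        for j in range(i, -1, -1):
            c = L.get(j, 0.0)
            if c == 0.0:
                continue
            if s[j] >= 0:
                L[s[j]] = L.get(s[j], 0.0) + 0.5 * c
            if d[j] >= 0:
                L[d[j]] = L.get(d[j], 0.0) + 0.5 * c
        F[i] = sum(c * c * Dvec[j] for j, c in L.items()) - 1.0
    ped.F = F
    return F


def numerator_relationship_matrix(ped: OrderedPedigree) -> np.ndarray:
    """Dense A by the tabular method.

    a_ij = 0.5 (a_{i,sire_j} + a_{i,dam_j}) for i < j;
    a_ii = 1 + 0.5 a_{sire_i, dam_i}; an unknown parent contributes 0.
    """
    n = ped.n
    s, d = ped.sire, ped.dam
    A = np.zeros((n, n))
    for i in range(n):
        asd = A[s[i], d[i]] if (s[i] >= 0 and d[i] >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
        for j in range(i):
            aij = 0.0
            if s[i] >= 0:
                aij += 0.5 * A[j, s[i]]
            if d[i] >= 0:
                aij += 0.5 * A[j, d[i]]
            A[i, j] = A[j, i] = aij
    return A


def relationship_inverse(ped: OrderedPedigree) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding (Quaas).

    For individual i with mendelian-sampling variance
    d_i = 1 - 0.25(1+F_s) - 0.25(1+F_d) (terms dropped for unknown
    parents), add b_i = 1/d_i at (i,i), -b_i/2 between i and each known
    parent, and b_i/4 among known parents.
    """
    F = ped.inbreeding()
    n = ped.n
    s, d = ped.sire, ped.dam
    rows, cols, vals = [], [], []

    def put(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        di = 1.0
        for p in (s[i], d[i]):
            if p >= 0:
                di -= 0.25 * (1.0 + F[p])
        if di <= 0:
            raise np.linalg.LinAlgError(
                f"singular relationship matrix at individual {ped.ids[i]!r}"
            )
        b = 1.0 / di
        put(i, i, b)
        for p in (s[i], d[i]):
            if p >= 0:
                put(i, p, -0.5 * b)
                put(p, i, -0.5 * b)
        for p in (s[i], d[i]):
            for q in (s[i], d[i]):
                if p >= 0 and q >= 0:
                    put(p, q, 0.25 * b)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    Ainv.sum_duplicates()
    return Ainv


def relationship_matrices(ped: OrderedPedigree) -> RelationshipMatrix:
    """Convenience: dense A and sparse A^-1 together."""
    return RelationshipMatrix(
        ids=list(ped.ids),
        A=numerator_relationship_matrix(ped),
        A_inv=relationship_inverse(ped),
    )


def read_pedigree_csv(path) -> OrderedPedigree:
    """Read an `id,sire,dam` CSV (``0`` or empty = unknown parent)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    for need in ("id", "sire", "dam"):
        if need not in cols:
            raise ValueError(f"pedigree CSV must have columns id,sire,dam; got {list(df.columns)}")
    recs = [
        PedigreeRecord(row[cols["id"]], row[cols["sire"]], row[cols["dam"]])
        for _, row in df.iterrows()
    ]
    return validate_and_order(recs)


def write_pedigree_csv(ped: OrderedPedigree, path) -> None:
    rows = []
    for i, lab in enumerate(ped.ids):
        rows.append(
            {
                "id": lab,
                "sire": ped.ids[ped.sire[i]] if ped.sire[i] >= 0 else UNKNOWN,
                "dam": ped.ids[ped.dam[i]] if ped.dam[i] >= 0 else UNKNOWN,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
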