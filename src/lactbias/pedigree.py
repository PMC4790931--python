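"""Numerator-relationship machinery for pedigree BLUP.

Builds everything the animal model needs from animal/sire/dam triples:
generation pruning around the phenotyped cohort, Wright's inbreeding
coefficients, and the sparse inverse of the numerator relationship matrix
``A`` assembled directly by Henderson's rules (with inbreeding, after
Meuwissen & Luo).  ``A`` itself is only ever formed densely for small
pedigrees (oracle checks, GLS cross-validation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io_formats import PedigreeEntry

__all__ = [
    "RelationshipStructure",
    "topological_order",
    "prune_pedigree",
    "compute_inbreeding",
    "build_A_inverse",
    "relationship_matrix",
]


@dataclass
class RelationshipStructure:
    """Ordered pedigree with inbreeding and the sparse A-inverse.

    ``order`` lists animal ids parents-first; ``index`` maps id -> row;
    ``inbreeding`` is Wright's F per animal; ``A_inverse`` is CSC symmetric
    positive definite; ``log_det_A`` is ``log|A|`` (the sum of the log
    Mendelian-sampling variances), needed by the restricted likelihood.
    """

    order: list[str]
    index: dict[str, int]
    inbreeding: np.ndarray
    A_inverse: sp.csc_matrix
    log_det_A: float

    @property
    def n(self) -> int:
        return len(self.order)


def _complete(entries: list[PedigreeEntry]) -> list[PedigreeEntry]:
    """Add entries (unknown parents) for animals appearing only as parents."""
    known = {e.animal_id for e in entries}
    extra = []
    for e in entries:
        for p in (e.sire_id, e.dam_id):
            if p is not None and p not in known:
                known.add(p)
                extra.append(PedigreeEntry(p))
    return extra + entries


def topological_order(entries: list[PedigreeEntry]) -> list[PedigreeEntry]:
    """Return entries sorted parents-before-offspring (Kahn's algorithm)."""
    entries = _complete(entries)
    by_id = {e.animal_id: e for e in entries}
    # edges parent -> child
    children: dict[str, list[str]] = {a: [] for a in by_id}
    indeg = {a: 0 for a in by_id}
    for e in entries:
        for p in (e.sire_id, e.dam_id):
            if p is not None:
                children[p].append(e.animal_id)
                indeg[e.animal_id] += 1
    queue = sorted(a for a, d in indeg.items() if d == 0)
    out: list[PedigreeEntry] = []
    while queue:
        a = queue.pop(0)
        out.append(by_id[a])
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(out) != len(entries):
        raise ValueError("pedigree contains a cycle; cannot sort")
    return out


def prune_pedigree(
    entries: list[PedigreeEntry],
    phenotyped_animals: set[str] | list[str],
    max_generations: int = 6,
) -> list[PedigreeEntry]:
    """Keep phenotyped animals plus ancestors up to ``max_generations`` back.

    Parents falling outside the retained set are re-coded as unknown, so the
    result is a self-contained pedigree.  ``max_generations=0`` keeps the
    phenotyped animals only.
    """
    if max_generations < 0:
        raise ValueError("max_generations must be >= 0")
    by_id = {e.animal_id: e for e in _complete(entries)}
    keep: dict[str, None] = {}
    frontier = [a for a in phenotyped_animals if a in by_id]
    for a in phenotyped_animals:
        if a in by_id:
            keep[a] = None
    for _ in range(max_generations):
        nxt = []
        for a in frontier:
            e = by_id[a]
            for p in (e.sire_id, e.dam_id):
                if p is not None and p in by_id and p not in keep:
                    keep[p] = None
                    nxt.append(p)
        frontier = nxt
        if not frontier:
            break
    out = []
    for a in keep:
        e = by_id[a]
        out.append(
            PedigreeEntry(
                animal_id=a,
                sire_id=e.sire_id if e.sire_id in keep else None,
                dam_id=e.dam_id if e.dam_id in keep else None,
            )
        )
    return topological_order(out)


def compute_inbreeding(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Wright's inbreeding coefficients for a sorted pedigree.

    ``sire``/``dam`` are integer parent indices (-1 unknown), each strictly
    less than the animal's own index.  Uses the recursive kinship on the
    tabular definition, memoised; F_i = kinship(sire_i, dam_i).
    """
    n = len(sire)
    cache: dict[tuple[int, int], float] = {}

    def kin(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i > j:
            i, j = j, i
        key = (i, j)
        if key in cache:
            return cache[key]
        if i == j:
            val = 0.5 * (1.0 + kin(sire[i], dam[i]))
        else:
            # j is the younger: recurse through j's parents
            val = 0.5 * (kin(i, sire[j]) + kin(i, dam[j]))
        cache[key] = val
        return val

    F = np.zeros(n)
    for i in range(n):
        F[i] = kin(sire[i], dam[i])
    return F


def _indices(entries: list[PedigreeEntry]) -> tuple[list[str], np.ndarray, np.ndarray]:
    order = [e.animal_id for e in entries]
    idx = {a: i for i, a in enumerate(order)}
    sire = np.array([idx.get(e.sire_id, -1) if e.sire_id else -1 for e in entries])
    dam = np.array([idx.get(e.dam_id, -1) if e.dam_id else -1 for e in entries])
    for i, (s, d) in enumerate(zip(sire, dam)):
        if s >= i or d >= i:
            raise ValueError("pedigree not sorted parents-first")
    return order, sire, dam


def build_A_inverse(
    entries: list[PedigreeEntry], with_inbreeding: bool = True
) -> RelationshipStructure:
    """Assemble A-inverse by Henderson's rules on a (sortable) pedigree.

    For animal *i* with parents *s*, *d*, the Mendelian-sampling variance is
    ``d_i = 1 - 0.25 (1+F_s)[s known] - 0.25 (1+F_d)[d known]`` and the
    contributions to A-inverse are ``1/d_i`` at (i,i), ``-1/(2 d_i)`` at
    (i, parent) and symmetric, and ``1/(4 d_i)`` at each (parent, parent')
    pair (including parent with itself).
    """
    entries = topological_order(entries)
    order, sire, dam = _indices(entries)
    n = len(order)
    F = compute_inbreeding(sire, dam) if with_inbreeding else np.zeros(n)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    log_det = 0.0
    for i in range(n):
        s, d = sire[i], dam[i]
        di = 1.0
        if s >= 0:
            di -= 0.25 * (1.0 + F[s])
        if d >= 0:
            di -= 0.25 * (1.0 + F[d])
        if di <= 0:
            raise ValueError(f"non-positive Mendelian sampling variance for {order[i]}")
        log_det += np.log(di)
        inv_d = 1.0 / di
        rows.append(i); cols.append(i); vals.append(inv_d)
        for p in (s, d):
            if p >= 0:
                rows += [i, p]; cols += [p, i]; vals += [-0.5 * inv_d] * 2
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    rows.append(p); cols.append(q); vals.append(0.25 * inv_d)
    Ainv = sp.csc_matrix(
        (vals, (rows, cols)), shape=(n, n)
    )
    Ainv.sum_duplicates()
    return RelationshipStructure(
        order=order,
        index={a: i for i, a in enumerate(order)},
        inbreeding=F,
        A_inverse=Ainv,
        log_det_A=log_det,
    )


def relationship_matrix(entries: list[PedigreeEntry]) -> tuple[list[str], np.ndarray]:
    """Dense numerator relationship matrix by the tabular method.

    Only for small pedigrees (oracles, dense GLS checks): O(n^2) memory.
    """
    entries = topological_order(entries)
    order, sire, dam = _indices(entries)
    n = len(order)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        a_sd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = A[j, i] = a
    return order, A
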