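"""Pedigree graph, relationship matrices, and pedigree-derived statistics.

A breeding program's pedigree is a directed acyclic graph of inbred lines:
each line has at most two parents (labelled sire/dam for convention, though
rice lines are hermaphroditic) and an optional year in which the originating
cross was made.  From this graph we derive

* **EqG** (equivalent complete generations), a pedigree-completeness measure
  used as a proxy for the number of realized breeding cycles:
  ``EqG = sum over known ancestors of (1/2)^g`` with *g* the generation
  distance (1 for parents, 2 for grandparents, ...).  An ancestor reachable
  by several paths contributes once per path, matching the recursion
  ``EqG(x) = sum over known parents p of 0.5 * (1 + EqG(p))``.
* the additive (numerator) relationship matrix **A** by the tabular method,
* its sparse inverse by Henderson's rules with inbreeding, where the
  Mendelian-sampling variances come from a Meuwissen–Luo-style pass,
* inbreeding coefficients ``F_i = A_ii - 1`` and the coefficient of
  parentage (kinship) ``f(i, j) = A_ij / 2``,
* structural cross types (single / three-way / backcross / double / complex)
  and elite status of crosses from parental EqG.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger("ricegain")

UNKNOWN = ""  # canonical representation of an unknown parent

_UNKNOWN_TOKENS = {"", "unknown", "na", "nan", "none", "-", "0"}


class EntryType(str, Enum):
    BREEDING_LINE = "breeding_line"
    RELEASED_VARIETY = "released_variety"
    FOUNDER = "founder"
    F1 = "f1"


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates, bad ids)."""


def _norm_parent(p: Optional[str]) -> str:
    if p is None:
        return UNKNOWN
    p = str(p).strip()
    if p.lower() in _UNKNOWN_TOKENS:
        return UNKNOWN
    return p


@dataclass(frozen=True)
class PedigreeRecord:
    """One line of a pedigree: identity, parents, cross year, entry type."""

    line_id: str
    sire_id: str = UNKNOWN
    dam_id: str = UNKNOWN
    cross_year: Optional[int] = None
    entry_type: EntryType = EntryType.BREEDING_LINE
    implicit: bool = False  # materialized because referenced but never declared

    def __post_init__(self) -> None:
        object.__setattr__(self, "sire_id", _norm_parent(self.sire_id))
        object.__setattr__(self, "dam_id", _norm_parent(self.dam_id))
        if isinstance(self.entry_type, str) and not isinstance(self.entry_type, EntryType):
            object.__setattr__(self, "entry_type", EntryType(self.entry_type))
        if self.line_id == UNKNOWN:
            raise PedigreeError("line_id must be a non-empty identifier")
        if self.line_id in (self.sire_id, self.dam_id):
            raise PedigreeError(f"line {self.line_id!r} lists itself as a parent")

    @property
    def parents(self) -> tuple[str, ...]:
        return tuple(p for p in (self.sire_id, self.dam_id) if p != UNKNOWN)

    @property
    def is_founder(self) -> bool:
        return self.sire_id == UNKNOWN and self.dam_id == UNKNOWN


class Pedigree:
    """Topologically ordered pedigree with integer-indexed parent arrays.

    Construct through :func:`build_pedigree`; the constructor assumes records
    are already topologically sorted (parents before offspring).
    """

    def __init__(self, records: Sequence[PedigreeRecord]):
        self.records: list[PedigreeRecord] = list(records)
        self.index: dict[str, int] = {r.line_id: i for i, r in enumerate(self.records)}
        n = len(self.records)
        self.sire = np.full(n, -1, dtype=np.int64)
        self.dam = np.full(n, -1, dtype=np.int64)
        for i, r in enumerate(self.records):
            if r.sire_id != UNKNOWN:
                self.sire[i] = self.index[r.sire_id]
            if r.dam_id != UNKNOWN:
                self.dam[i] = self.index[r.dam_id]
        self.founder_set: set[str] = {r.line_id for r in self.records if r.is_founder}
        self._eqg: Optional[np.ndarray] = None
        self._F: Optional[np.ndarray] = None

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, line_id: str) -> bool:
        return line_id in self.index

    @property
    def ids(self) -> list[str]:
        return [r.line_id for r in self.records]

    def record(self, line_id: str) -> PedigreeRecord:
        return self.records[self._idx(line_id)]

    def _idx(self, line_id: str) -> int:
        try:
            return self.index[line_id]
        except KeyError:
            raise PedigreeError(f"unknown line id {line_id!r}") from None

    # -- derived quantities ------------------------------------------------
    def eqg(self, line_id: Optional[str] = None):
        """Equivalent complete generations, for one line or all lines."""
        if self._eqg is None:
            out = np.zeros(len(self))
            for i in range(len(self)):
                v = 0.0
                for p in (self.sire[i], self.dam[i]):
                    if p >= 0:
                        v += 0.5 * (1.0 + out[p])
                out[i] = v
            self._eqg = out
        if line_id is None:
            return self._eqg.copy()
        return float(self._eqg[self._idx(line_id)])

    def inbreeding(self, line_id: Optional[str] = None):
        """Inbreeding coefficients F (Meuwissen–Luo pass; F = A_ii - 1)."""
        if self._F is None:
            self._F, _ = _meuwissen_luo(self.sire, self.dam)
        if line_id is None:
            return self._F.copy()
        return float(self._F[self._idx(line_id)])

    def ancestors(self, line_id: str) -> set[str]:
        """All known ancestors of a line (excluding itself)."""
        seen: set[int] = set()
        stack = [self._idx(line_id)]
        while stack:
            i = stack.pop()
            for p in (self.sire[i], self.dam[i]):
                if p >= 0 and p not in seen:
                    seen.add(p)
                    stack.append(p)
        return {self.records[i].line_id for i in seen}


def build_pedigree(records: Iterable[PedigreeRecord]) -> Pedigree:
    """Validate records, materialize implicit founders, and topologically sort.

    Parents that are referenced but never declared are added as flagged
    implicit founders (with a warning).  Duplicate ids and cycles are errors.
    """
    records = list(records)
    if not records:
        raise PedigreeError("pedigree must contain at least one record")

    seen: dict[str, int] = {}
    for row, r in enumerate(records):
        if r.line_id in seen:
            raise PedigreeError(
                f"duplicate line_id {r.line_id!r} (records {seen[r.line_id]} and {row})"
            )
        seen[r.line_id] = row

    declared = set(seen)
    implicit: list[PedigreeRecord] = []
    for r in records:
        for p in r.parents:
            if p not in declared:
                declared.add(p)
                implicit.append(
                    PedigreeRecord(p, entry_type=EntryType.FOUNDER, implicit=True)
                )
    if implicit:
        names = [r.line_id for r in implicit]
        warnings.warn(
            f"{len(implicit)} parent id(s) not declared; added as implicit founders: "
            f"{names[:10]}{'...' if len(names) > 10 else ''}",
            stacklevel=2,
        )
        logger.info("materialized %d implicit founders", len(implicit))

    all_records = {r.line_id: r for r in list(records) + implicit}
    g = nx.DiGraph()
    g.add_nodes_from(all_records)
    for r in all_records.values():
        for p in r.parents:
            g.add_edge(p, r.line_id)
    try:
        order = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        ids = sorted({u for e in cycle for u in e[:2]})
        raise PedigreeError(f"pedigree contains a cycle involving: {ids}") from None

    ped = Pedigree([all_records[i] for i in order])
    # cross_year monotonicity: offspring never predate their parents
    for r in ped.records:
        if r.cross_year is None:
            continue
        for p in r.parents:
            py = all_records[p].cross_year
            if py is not None and r.cross_year < py:
                warnings.warn(
                    f"line {r.line_id!r} has cross_year {r.cross_year} earlier than "
                    f"parent {p!r} ({py})",
                    stacklevel=2,
                )
    return ped


def equivalent_generations(ped: Pedigree, line_id: str) -> float:
    """EqG of one line: ``sum over known parents p of 0.5 * (1 + EqG(p))``."""
    return ped.eqg(line_id)


def _meuwissen_luo(sire: np.ndarray, dam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inbreeding F and Mendelian-sampling variances D in one topological pass.

    For each individual the diagonal A_ii is accumulated as ``sum L_j^2 D_j``
    over its ancestors, where L are the gamete-contribution coefficients; then
    ``F_i = A_ii - 1``.  D depends only on parental F, available earlier in
    the ordering.
    """
    n = len(sire)
    F = np.zeros(n)
    D = np.ones(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0:
            D[i] = 0.75 - 0.25 * F[s]
        elif d >= 0:
            D[i] = 0.75 - 0.25 * F[d]
        else:
            D[i] = 1.0
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        # trace ancestor contributions of i (largest index first)
        L = {i: 1.0}
        heap = [-i]
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            if j not in L:
                continue
            c = L.pop(j)
            aii += c * c * D[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    if p in L:
                        L[p] += 0.5 * c
                    else:
                        L[p] = 0.5 * c
                        heapq.heappush(heap, -p)
        F[i] = aii - 1.0
    return F, D


@dataclass
class RelationshipMatrix:
    """Additive relationship matrix over an ordered id list."""

    ids: list[str]
    A: np.ndarray

    @property
    def F(self) -> np.ndarray:
        return np.diag(self.A) - 1.0

    def loc(self, i: str, j: str) -> float:
        ix = {v: k for k, v in enumerate(self.ids)}
        return float(self.A[ix[i], ix[j]])


def relationship_matrix(
    ped: Pedigree,
    subset: Optional[Sequence[str]] = None,
    fully_inbred_terminal: bool = False,
) -> RelationshipMatrix:
    """Tabular-method A matrix, optionally restricted to ``subset``.

    When a subset is given, its full ancestral closure is used internally so
    relationships through shared ancestors are captured, and the returned
    matrix is restricted to the requested ids (in the requested order).

    ``fully_inbred_terminal=True`` treats terminal lines (those that are not
    parents of any recorded line) as completely inbred: their diagonal is
    set to 2 (F = 1), reflecting selfing to fixation beyond what the
    recorded sire-dam pedigree implies.  Selfing a line does not change its
    expected identity-by-descent with other lines, so off-diagonals are
    unchanged.  Off by default: the standard tabular A is what pedigree-BLUP
    tooling uses for inbred crops.
    """
    if subset is None:
        keep_ids = ped.ids
        closure_idx = np.arange(len(ped))
    else:
        keep_ids = list(subset)
        need: set[str] = set()
        for i in keep_ids:
            need.add(i)
            if i not in ped.index:
                raise PedigreeError(f"unknown line id {i!r}")
            need |= ped.ancestors(i)
        closure_idx = np.array(sorted(ped.index[i] for i in need), dtype=np.int64)

    pos = {int(gi): k for k, gi in enumerate(closure_idx)}
    m = len(closure_idx)
    A = np.zeros((m, m))
    for k, gi in enumerate(closure_idx):
        s, d = ped.sire[gi], ped.dam[gi]
        ks = pos.get(int(s), -1) if s >= 0 else -1
        kd = pos.get(int(d), -1) if d >= 0 else -1
        A[k, k] = 1.0 + (0.5 * A[ks, kd] if ks >= 0 and kd >= 0 else 0.0)
        for j in range(k):
            v = 0.0
            if ks >= 0:
                v += 0.5 * A[j, ks]
            if kd >= 0:
                v += 0.5 * A[j, kd]
            A[k, j] = A[j, k] = v
    sel = np.array([pos[ped.index[i]] for i in keep_ids], dtype=np.int64)
    out = A[np.ix_(sel, sel)].copy()
    if fully_inbred_terminal:
        is_parent = set(ped.sire[ped.sire >= 0]) | set(ped.dam[ped.dam >= 0])
        for k, lid in enumerate(keep_ids):
            if ped.index[lid] not in is_parent:
                out[k, k] = 2.0
    return RelationshipMatrix(ids=keep_ids, A=out)


def a_inverse(ped: Pedigree) -> sp.csr_matrix:
    """Sparse inverse of A over the whole pedigree (Henderson's rules).

    Mendelian-sampling variances account for parental inbreeding (unknown
    parents are treated as unrelated non-inbred founders).
    """
    inv, _ = a_inverse_with_logdet(ped)
    return inv


def a_inverse_with_logdet(ped: Pedigree) -> tuple[sp.csr_matrix, float]:
    """A-inverse plus ``log|A| = sum log D_i`` (needed by REML likelihoods)."""
    _, D = _meuwissen_luo(ped.sire, ped.dam)
    if ped._F is None:  # cache F computed alongside D
        ped._F = _meuwissen_luo(ped.sire, ped.dam)[0]
    n = len(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        alpha = 1.0 / D[i]
        parents = [int(p) for p in (ped.sire[i], ped.dam[i]) if p >= 0]
        rows.append(i)
        cols.append(i)
        vals.append(alpha)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-alpha / 2.0, -alpha / 2.0]
        for p in parents:
            for q in parents:
                rows.append(p)
                cols.append(q)
                vals.append(alpha / 4.0)
    inv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    logdet_a = float(np.sum(np.log(D)))
    return inv, logdet_a


def coefficient_of_parentage(ped: Pedigree, i: str, j: str) -> float:
    """Kinship ``f(i, j) = A_ij / 2``; ``f(i, i) = (1 + F_i) / 2``."""
    rm = relationship_matrix(ped, subset=[i] if i == j else [i, j])
    if i == j:
        return float(rm.A[0, 0]) / 2.0
    return float(rm.A[0, 1]) / 2.0


def kinship_matrix(ped: Pedigree, subset: Sequence[str]) -> RelationshipMatrix:
    """Pairwise coefficient of parentage over a subset (A/2)."""
    rm = relationship_matrix(ped, subset=subset)
    return RelationshipMatrix(ids=rm.ids, A=rm.A / 2.0)


class CrossType(str, Enum):
    SINGLE = "single"
    THREE_WAY = "three_way"
    BACKCROSS = "backcross"
    DOUBLE = "double"
    COMPLEX = "complex"


class CrossStatus(str, Enum):
    ELITE_ELITE = "elite_elite"
    ELITE_NONELITE = "elite_nonelite"
    NONELITE_NONELITE = "nonelite_nonelite"


@dataclass
class CrossClassification:
    cross_id: str
    cross_type: CrossType
    cross_status: CrossStatus
    parent_eqgs: tuple[float, float]
    flagged: bool = False  # set when a parent was missing/unresolvable


def classify_cross(
    ped: Pedigree,
    cross: tuple[str, str],
    elite_threshold: float = 4.0,
) -> CrossClassification:
    """Classify a cross structurally and by parental elite status.

    A parent with ``EqG >= elite_threshold`` is elite (the program's
    convention: a threshold of 4 corresponded to the most advanced breeding
    cycle available in 1985).  Structural rules: both parents F1 entries →
    double; exactly one F1 → backcross if the other parent is a parent of
    that F1, else three-way; neither F1 → backcross if one parent is a parent
    of the other, else single.  Unresolvable parents → complex, flagged.
    """
    p1, p2 = cross
    flagged = False
    eqgs = []
    for p in (p1, p2):
        if p in ped:
            eqgs.append(ped.eqg(p))
        else:
            eqgs.append(float("nan"))
            flagged = True

    if flagged:
        ctype = CrossType.COMPLEX
    else:
        r1, r2 = ped.record(p1), ped.record(p2)
        f1_1 = r1.entry_type == EntryType.F1
        f1_2 = r2.entry_type == EntryType.F1
        if f1_1 and f1_2:
            ctype = CrossType.DOUBLE
        elif f1_1 or f1_2:
            f1_rec, other = (r1, p2) if f1_1 else (r2, p1)
            ctype = (
                CrossType.BACKCROSS if other in f1_rec.parents else CrossType.THREE_WAY
            )
        else:
            if p1 in r2.parents or p2 in r1.parents:
                ctype = CrossType.BACKCROSS
            else:
                ctype = CrossType.SINGLE

    def elite(e: float) -> bool:
        # NaN (missing parent) counts as non-elite
        return bool(e >= elite_threshold)

    n_elite = sum(elite(e) for e in eqgs)
    status = (
        CrossStatus.ELITE_ELITE
        if n_elite == 2
        else CrossStatus.ELITE_NONELITE
        if n_elite == 1
        else CrossStatus.NONELITE_NONELITE
    )
    return CrossClassification(
        cross_id=f"{p1}/{p2}",
        cross_type=ctype,
        cross_status=status,
        parent_eqgs=(eqgs[0], eqgs[1]),
        flagged=flagged,
    )
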