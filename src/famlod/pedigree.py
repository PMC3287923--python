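"""Pedigree representation, validation, kinship computation, and PED/FAM I/O.

Pedigrees are the unit of analysis throughout: kinship matrices computed
here parameterize the polygenic covariance term ``2 * Phi * sigma_a^2`` of
the variance-component trait model, and the topologically sorted member
order is what makes single-pass gene dropping and the kinship recursion
valid.

File dialect: whitespace-delimited PED/FAM columns ``FID IID PAT MAT SEX``
(extra columns ignored), ``0`` meaning "no parent in the pedigree", sex
coded 1 = male / 2 = female, ``#`` starting a comment line.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Individual",
    "Pedigree",
    "KinshipMatrix",
    "PedigreeError",
    "read_pedigrees",
    "write_pedigrees",
    "kinship",
]

MISSING_PARENT = "0"
MALE, FEMALE = 1, 2


class PedigreeError(ValueError):
    """Structural problem in a pedigree (dangling parent, cycle, duplicate id...)."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father``/``mother`` are ``None`` for founders; non-founders must have
    both parents present in the same family.
    """

    iid: str
    fid: str
    father: str | None
    mother: str | None
    sex: int

    def __post_init__(self) -> None:
        if (self.father is None) != (self.mother is None):
            raise PedigreeError(
                f"individual {self.iid!r} in family {self.fid!r} has exactly one "
                "parent recorded; founders must have neither, non-founders both"
            )
        if self.sex not in (MALE, FEMALE):
            raise PedigreeError(f"individual {self.iid!r}: sex must be 1 or 2, got {self.sex!r}")

    @property
    def is_founder(self) -> bool:
        return self.father is None


class Pedigree:
    """A single family, members stored in ancestor-before-descendant order."""

    def __init__(self, fid: str, members: Sequence[Individual], *, sort: bool = True):
        self.fid = str(fid)
        members = list(members)
        if not members:
            raise PedigreeError(f"family {fid!r} has no members")
        for ind in members:
            if ind.fid != self.fid:
                raise PedigreeError(
                    f"individual {ind.iid!r} has family id {ind.fid!r}, expected {self.fid!r}"
                )
        self._validate(members)
        if sort:
            members = _toposort(self.fid, members)
        self.members: list[Individual] = members
        self._index = {ind.iid: k for k, ind in enumerate(members)}

    # -- basic protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __contains__(self, iid: str) -> bool:
        return iid in self._index

    def __getitem__(self, iid: str) -> Individual:
        return self.members[self._index[iid]]

    def index(self, iid: str) -> int:
        return self._index[iid]

    def __eq__(self, other) -> bool:
        return isinstance(other, Pedigree) and self.fid == other.fid and self.members == other.members

    def __repr__(self) -> str:
        return f"Pedigree(fid={self.fid!r}, n={len(self)}, founders={len(self.founders)})"

    @property
    def ids(self) -> list[str]:
        return [ind.iid for ind in self.members]

    @property
    def founders(self) -> list[Individual]:
        return [ind for ind in self.members if ind.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [ind for ind in self.members if not ind.is_founder]

    def is_sorted(self) -> bool:
        """True when every parent is listed before each of its children."""
        seen: set[str] = set()
        for ind in self.members:
            if not ind.is_founder and (ind.father not in seen or ind.mother not in seen):
                return False
            seen.add(ind.iid)
        return True

    # -- validation ----------------------------------------------------
    @staticmethod
    def _validate(members: Sequence[Individual]) -> None:
        ids = [m.iid for m in members]
        seen: set[str] = set()
        for iid in ids:
            if iid in seen:
                raise PedigreeError(f"duplicate individual id {iid!r} within family {members[0].fid!r}")
            seen.add(iid)
        by_id = {m.iid: m for m in members}
        for m in members:
            if m.is_founder:
                continue
            for role, pid in (("father", m.father), ("mother", m.mother)):
                if pid not in by_id:
                    raise PedigreeError(
                        f"individual {m.iid!r} in family {m.fid!r} lists {role} {pid!r} "
                        "who is not a member of the family"
                    )
            if by_id[m.father].sex != MALE:
                raise PedigreeError(f"father {m.father!r} of {m.iid!r} is not coded male")
            if by_id[m.mother].sex != FEMALE:
                raise PedigreeError(f"mother {m.mother!r} of {m.iid!r} is not coded female")


def _toposort(fid: str, members: Sequence[Individual]) -> list[Individual]:
    """Ancestor-before-descendant order, stable w.r.t. the input order."""
    graph = nx.DiGraph()
    order = {m.iid: k for k, m in enumerate(members)}
    graph.add_nodes_from(order)
    for m in members:
        if not m.is_founder:
            graph.add_edge(m.father, m.iid)
            graph.add_edge(m.mother, m.iid)
    try:
        sorted_ids = list(nx.lexicographical_topological_sort(graph, key=lambda iid: order[iid]))
    except nx.NetworkXUnfeasible:
        cycle = [u for u, _ in nx.find_cycle(graph)]
        raise PedigreeError(
            f"family {fid!r} contains an ancestry cycle: {' -> '.join(cycle + cycle[:1])}"
        ) from None
    by_id = {m.iid: m for m in members}
    return [by_id[iid] for iid in sorted_ids]


@dataclass
class KinshipMatrix:
    """Kinship coefficients Phi_ij for one pedigree.

    ``2 * values`` is the numerator relationship matrix used in the
    polygenic covariance term of the variance-component model.
    """

    ids: list[str]
    values: np.ndarray
    fid: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"kinship matrix shape {self.values.shape} does not match {n} ids")

    def phi(self, i: str, j: str) -> float:
        idx = {iid: k for k, iid in enumerate(self.ids)}
        return float(self.values[idx[i], idx[j]])

    def subset(self, ids: Sequence[str]) -> np.ndarray:
        idx = {iid: k for k, iid in enumerate(self.ids)}
        pos = [idx[i] for i in ids]
        return self.values[np.ix_(pos, pos)]


def kinship(ped: Pedigree) -> KinshipMatrix:
    """Kinship matrix by the standard tabular recursion.

    With members sorted so parents precede offspring, and taking i as the
    later-listed individual with parents f, m:

        Phi_ii = 0.5 * (1 + Phi_fm)         (founders: 0.5)
        Phi_ij = 0.5 * (Phi_fj + Phi_mj)    (founders: 0 with all earlier)

    Handles inbreeding loops and half-sibs without special cases; raises if
    the member list is not in ancestor-before-descendant order.
    """
    if not ped.is_sorted():
        raise PedigreeError(
            f"family {ped.fid!r}: members are not in parent-before-offspring order; "
            "construct the Pedigree with sort=True"
        )
    n = len(ped)
    phi = np.zeros((n, n))
    for i, ind in enumerate(ped.members):
        if ind.is_founder:
            phi[i, i] = 0.5
            continue
        f, m = ped.index(ind.father), ped.index(ind.mother)
        row = 0.5 * (phi[f, :i] + phi[m, :i])
        phi[i, :i] = row
        phi[:i, i] = row
        phi[i, i] = 0.5 * (1.0 + phi[f, m])
    return KinshipMatrix(ids=ped.ids, values=phi, fid=ped.fid)


# -- file I/O ----------------------------------------------------------


def _parse_lines(lines: Iterable[str], source: str) -> list[Pedigree]:
    rows: list[tuple[str, str, str, str, int]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 5:
            raise PedigreeError(f"{source}:{lineno}: expected at least 5 columns (FID IID PAT MAT SEX)")
        fid, iid, pat, mat = parts[:4]
        try:
            sex = int(parts[4])
        except ValueError:
            raise PedigreeError(f"{source}:{lineno}: sex column must be integer, got {parts[4]!r}") from None
        rows.append((fid, iid, pat, mat, sex))

    seen_pairs: set[tuple[str, str]] = set()
    iid_to_fid: dict[str, str] = {}
    by_family: dict[str, list[Individual]] = {}
    for fid, iid, pat, mat, sex in rows:
        if (fid, iid) in seen_pairs:
            raise PedigreeError(f"duplicate individual {iid!r} in family {fid!r}")
        seen_pairs.add((fid, iid))
        if iid in iid_to_fid and iid_to_fid[iid] != fid:
            raise PedigreeError(
                f"individual id {iid!r} appears in two families ({iid_to_fid[iid]!r} and {fid!r})"
            )
        iid_to_fid[iid] = fid
        by_family.setdefault(fid, []).append(
            Individual(
                iid=iid,
                fid=fid,
                father=None if pat == MISSING_PARENT else pat,
                mother=None if mat == MISSING_PARENT else mat,
                sex=sex,
            )
        )
    return [Pedigree(fid, members) for fid, members in by_family.items()]


def read_pedigrees(path: str | Path | io.TextIOBase) -> list[Pedigree]:
    """Read a PED/FAM file into one validated, sorted :class:`Pedigree` per family."""
    if isinstance(path, io.TextIOBase):
        return _parse_lines(path, "<stream>")
    p = Path(path)
    with p.open() as fh:
        return _parse_lines(fh, str(p))


def write_pedigrees(peds: Sequence[Pedigree], path: str | Path) -> None:
    """Write pedigrees in the PED/FAM dialect read by :func:`read_pedigrees`."""
    with Path(path).open("w") as fh:
        fh.write("# FID IID PAT MAT SEX\n")
        for ped in peds:
            for ind in ped.members:
                fh.write(
                    f"{ped.fid}\t{ind.iid}\t{ind.father or MISSING_PARENT}\t"
                    f"{ind.mother or MISSING_PARENT}\t{ind.sex}\n"
                )
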