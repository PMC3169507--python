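"""In-memory containers for complexome data.

A complexome dataset is a list of role-labelled memberships: protein *i*
belongs to complex *j* either as a *core* component (the stable skeleton
of the complex) or as an *attachment* (a more promiscuous, loosely bound
component). The binary membership indicator U_ij and the stoichiometric
count S_ij both live here; with the default ``copies=1`` the two
coincide.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping


class Role(str, enum.Enum):
    """Membership role of a protein within a complex."""

    CORE = "core"
    ATTACHMENT = "attachment"


FUNCTION_CODE_RE = re.compile(r"^\d+(\.\d+)*$")


@dataclass(frozen=True)
class Membership:
    """One (complex, protein, role) record with stoichiometric count.

    ``copies`` is the stoichiometric count S_ij; it defaults to 1, in
    which case S reduces to the binary indicator U.
    """

    complex_id: str
    protein_id: str
    role: Role
    copies: int = 1

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError(
                f"copies must be >= 1, got {self.copies} for "
                f"({self.complex_id}, {self.protein_id})"
            )


@dataclass
class ComplexomeDataset:
    """A validated, deterministic-order complexome.

    ``complexes`` and ``proteins`` are lexicographically sorted tuples;
    memberships are deduplicated on (complex, protein, role).
    """

    memberships: tuple[Membership, ...]
    complexes: tuple[str, ...] = field(default=())
    proteins: tuple[str, ...] = field(default=())

    @classmethod
    def from_memberships(cls, memberships: Iterable[Membership]) -> "ComplexomeDataset":
        seen: dict[tuple[str, str, Role], Membership] = {}
        for m in memberships:
            seen.setdefault((m.complex_id, m.protein_id, m.role), m)
        ms = tuple(
            sorted(seen.values(), key=lambda m: (m.complex_id, m.protein_id, m.role.value))
        )
        complexes = tuple(sorted({m.complex_id for m in ms}))
        proteins = tuple(sorted({m.protein_id for m in ms}))
        return cls(memberships=ms, complexes=complexes, proteins=proteins)

    @property
    def n_complexes(self) -> int:
        return len(self.complexes)

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    def members_of(self, complex_id: str, roles: frozenset[Role] | None = None) -> list[Membership]:
        """Memberships of one complex, optionally restricted by role."""
        return [
            m
            for m in self.memberships
            if m.complex_id == complex_id and (roles is None or m.role in roles)
        ]

    def restrict_roles(self, roles: Iterable[Role]) -> "ComplexomeDataset":
        """Sub-dataset with only the given roles (nodes re-derived)."""
        roleset = frozenset(roles)
        return ComplexomeDataset.from_memberships(
            m for m in self.memberships if m.role in roleset
        )


@dataclass
class AbundanceTable:
    """Protein abundances (arbitrary units) per growth condition.

    Missing (protein, condition) entries mean the abundance is unknown.
    Proteins listed with a blank value are kept in ``proteins`` so that
    "measured but unknown" is distinguishable from "never measured".
    """

    entries: dict[tuple[str, str], float]
    conditions: tuple[str, ...]
    proteins: tuple[str, ...]

    @classmethod
    def from_entries(
        cls,
        entries: Mapping[tuple[str, str], float],
        proteins: Iterable[str] = (),
    ) -> "AbundanceTable":
        for (pid, cond), v in entries.items():
            if v < 0:
                raise ValueError(f"negative abundance {v} for ({pid}, {cond})")
        conds = tuple(sorted({c for (_, c) in entries}))
        prots = tuple(sorted({p for (p, _) in entries} | set(proteins)))
        return cls(entries=dict(entries), conditions=conds, proteins=prots)

    def known(self, condition: str) -> dict[str, float]:
        """Proteins with a known, strictly positive abundance in ``condition``."""
        return {
            pid: v
            for (pid, cond), v in self.entries.items()
            if cond == condition and v > 0
        }

    def get(self, protein_id: str, condition: str) -> float | None:
        return self.entries.get((protein_id, condition))


@dataclass
class FunctionTable:
    """Per-protein sets of hierarchical function codes (dotted, FunCat-style)."""

    entries: dict[str, frozenset[str]]

    @classmethod
    def from_entries(cls, entries: Mapping[str, Iterable[str]]) -> "FunctionTable":
        out: dict[str, frozenset[str]] = {}
        for pid, codes in entries.items():
            fs = frozenset(codes)
            for code in fs:
                if not FUNCTION_CODE_RE.match(code):
                    raise ValueError(f"malformed function code {code!r} for {pid}")
            if fs:
                out[pid] = fs
        return cls(entries=out)

    @property
    def universe(self) -> tuple[str, ...]:
        """All distinct codes, sorted (size F)."""
        codes: set[str] = set()
        for fs in self.entries.values():
            codes |= fs
        return tuple(sorted(codes))

    @property
    def n_functions(self) -> int:
        return len(self.universe)

    def functions_of(self, protein_id: str) -> frozenset[str]:
        return self.entries.get(protein_id, frozenset())
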