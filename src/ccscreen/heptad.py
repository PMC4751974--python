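"""Heptad-register model for dimeric coiled coils.

A coiled coil is built on a seven-residue repeat, conventionally labelled
``abcdefg``, in which ``a`` and ``d`` residues form the hydrophobic core of
the dimer interface while ``e`` and ``g`` residues flank it and make
interhelical electrostatic contacts.  In a parallel dimer the ``g`` residue
of heptad *n* on one chain contacts the ``e`` residue of heptad *n* on the
partner chain (the residue five positions C-terminal of the partner's ``g``),
and the ``a`` residues of matching heptads pack against one another.  In an
antiparallel dimer the flanking contacts become ``g``-``g'`` and ``e``-``e'``
between heptads counted from opposite ends, and buried polar contacts move to
``a``-``d'``.

This module provides the registered-peptide container and the enumeration of
interhelical residue pairs for both geometries.  Alignment is strictly
in-register (heptad *n* against heptad *n*, or its mirror for antiparallel
chains); no axial sliding is searched, because an Asn-Asn ``a``-``a'`` pair
in the intended designs pins a single axial alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "RegisteredPeptide",
    "ResiduePair",
    "RegisterWarning",
    "assign_register",
    "parallel_core_pairs",
    "parallel_electrostatic_pairs",
    "antiparallel_core_pairs",
    "antiparallel_electrostatic_pairs",
]

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Cap marker in register strings: residue excluded from all scoring.
CAP = "-"

_NEXT_LETTER = {"g": "a", "a": "b", "b": "c", "c": "d", "d": "e", "e": "f", "f": "g"}
REGISTER_LETTERS = frozenset(_NEXT_LETTER)


class RegisterWarning(UserWarning):
    """Non-fatal register oddity (no complete g..e span, truncated overlap)."""


@dataclass(frozen=True)
class RegisteredPeptide:
    """An amino-acid sequence with a heptad register annotation.

    Parameters
    ----------
    id:
        Short unique label used in reports and interaction tables.
    sequence:
        One-letter amino-acid string (standard 20 residues).
    register:
        String of the same length over ``gabcdef-``; ``-`` marks cap
        residues (contiguous N/C-terminal flanks) excluded from scoring.
        Non-cap positions must follow the cyclic heptad order
        g→a→b→c→d→e→f→g without gaps.
    """

    id: str
    sequence: str
    register: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.register):
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != "
                f"register length {len(self.register)}"
            )
        bad = set(self.sequence) - STANDARD_AA
        if bad:
            raise ValueError(
                f"{self.id}: non-standard residue(s) {sorted(bad)} in sequence"
            )
        core = self.register.strip(CAP)
        if CAP in core:
            raise ValueError(f"{self.id}: cap marker '-' must be terminal only")
        bad_reg = set(core) - REGISTER_LETTERS
        if bad_reg:
            raise ValueError(f"{self.id}: invalid register letter(s) {sorted(bad_reg)}")
        if not core:
            raise ValueError(f"{self.id}: register has no scored positions")
        for prev, cur in zip(core, core[1:]):
            if _NEXT_LETTER[prev] != cur:
                raise ValueError(
                    f"{self.id}: register breaks cyclic heptad order at '{prev}{cur}'"
                )
        if not self.electro_heptads():
            warnings.warn(
                f"{self.id}: no complete g..e span; "
                "no electrostatic pairs can be enumerated",
                RegisterWarning,
                stacklevel=2,
            )

    # -- register geometry ------------------------------------------------

    def positions(self, letter: str) -> tuple[int, ...]:
        """0-based indices of residues at the given register letter."""
        return tuple(i for i, r in enumerate(self.register) if r == letter)

    def scored_indices(self) -> tuple[int, ...]:
        """Indices of all non-cap residues."""
        return tuple(i for i, r in enumerate(self.register) if r != CAP)

    def scored_sequence(self) -> str:
        return "".join(self.sequence[i] for i in self.scored_indices())

    def electro_heptads(self) -> tuple[tuple[int, int], ...]:
        """(g_index, e_index) for every complete g..e span.

        The e residue of a heptad sits five positions C-terminal of its g;
        only spans fully inside the scored region are emitted.
        """
        n = len(self.register)
        return tuple(
            (i, i + 5)
            for i in self.positions("g")
            if i + 5 < n and self.register[i + 5] == "e"
        )

    def residue(self, i: int) -> str:
        return self.sequence[i]


@dataclass(frozen=True)
class ResiduePair:
    """One interhelical residue contact between chain A and chain B.

    ``kind`` encodes the register letters involved: ``core_aa`` (a-a'),
    ``core_ad`` (a-d', antiparallel), ``electro_ge``/``electro_eg``
    (parallel g-e' and e-g'), ``electro_gg``/``electro_ee`` (antiparallel).
    Positions are 0-based indices into the respective peptide.
    """

    kind: str
    posA: int
    posB: int
    resA: str
    resB: str

    def swapped(self) -> "ResiduePair":
        swap = {
            "electro_ge": "electro_eg",
            "electro_eg": "electro_ge",
        }
        return ResiduePair(
            swap.get(self.kind, self.kind), self.posB, self.posA, self.resB, self.resA
        )


def assign_register(
    sequence: str,
    start_letter: str = "g",
    cap_prefix_len: int = 0,
    cap_suffix_len: int = 0,
    *,
    id: str = "peptide",
) -> RegisteredPeptide:
    """Annotate a sequence with a cyclic heptad register.

    Non-cap residues are labelled cyclically from ``start_letter``; the first
    ``cap_prefix_len`` and last ``cap_suffix_len`` residues are marked as
    caps (``-``) and never scored.
    """
    if start_letter not in REGISTER_LETTERS:
        raise ValueError(f"start_letter must be one of a..g, got {start_letter!r}")
    if cap_prefix_len < 0 or cap_suffix_len < 0:
        raise ValueError("cap lengths must be >= 0")
    n_core = len(sequence) - cap_prefix_len - cap_suffix_len
    if n_core <= 0:
        raise ValueError("cap lengths must leave at least one scored residue")
    letters = []
    cur = start_letter
    for _ in range(n_core):
        letters.append(cur)
        cur = _NEXT_LETTER[cur]
    register = CAP * cap_prefix_len + "".join(letters) + CAP * cap_suffix_len
    return RegisteredPeptide(id=id, sequence=sequence, register=register)


def _truncate_warn(pA: RegisteredPeptide, pB: RegisteredPeptide, nA: int, nB: int, what: str) -> int:
    n = min(nA, nB)
    if nA != nB:
        warnings.warn(
            f"{pA.id}/{pB.id}: unequal numbers of {what} ({nA} vs {nB}); "
            f"pairing the {n} overlapping heptads from the N-terminus",
            RegisterWarning,
            stacklevel=3,
        )
    return n


def parallel_core_pairs(
    pA: RegisteredPeptide, pB: RegisteredPeptide
) -> list[ResiduePair]:
    """a-a' core contacts of the in-register parallel dimer.

    The n-th ``a`` residue of A packs against the n-th ``a`` residue of B.
    """
    aA, aB = pA.positions("a"), pB.positions("a")
    n = _truncate_warn(pA, pB, len(aA), len(aB), "a positions")
    return [
        ResiduePair("core_aa", aA[k], aB[k], pA.residue(aA[k]), pB.residue(aB[k]))
        for k in range(n)
    ]


def parallel_electrostatic_pairs(
    pA: RegisteredPeptide, pB: RegisteredPeptide
) -> list[ResiduePair]:
    """g-e' and e-g' contacts of the in-register parallel dimer.

    For each heptad n present in both chains, the g of A contacts the e of B
    five residues C-terminal in the same heptad, and symmetrically the e of A
    contacts the g of B.  Four complete heptads per chain give eight pairs.
    """
    hA, hB = pA.electro_heptads(), pB.electro_heptads()
    n = _truncate_warn(pA, pB, len(hA), len(hB), "complete g..e spans")
    out: list[ResiduePair] = []
    for k in range(n):
        gA, eA = hA[k]
        gB, eB = hB[k]
        out.append(ResiduePair("electro_ge", gA, eB, pA.residue(gA), pB.residue(eB)))
        out.append(ResiduePair("electro_eg", eA, gB, pA.residue(eA), pB.residue(gB)))
    return out


def antiparallel_electrostatic_pairs(
    pA: RegisteredPeptide, pB: RegisteredPeptide
) -> list[ResiduePair]:
    """g-g' and e-e' contacts of the in-register antiparallel dimer.

    With N complete electrostatic heptads, heptad n of A faces heptad
    N+1-n of B, so its g contacts the partner's g and its e the partner's e.
    """
    hA, hB = pA.electro_heptads(), pB.electro_heptads()
    n = _truncate_warn(pA, pB, len(hA), len(hB), "complete g..e spans")
    out: list[ResiduePair] = []
    for k in range(n):
        gA, eA = hA[k]
        gB, eB = hB[n - 1 - k]
        out.append(ResiduePair("electro_gg", gA, gB, pA.residue(gA), pB.residue(gB)))
        out.append(ResiduePair("electro_ee", eA, eB, pA.residue(eA), pB.residue(eB)))
    return out


def antiparallel_core_pairs(
    pA: RegisteredPeptide, pB: RegisteredPeptide
) -> list[ResiduePair]:
    """a-d' buried contacts of the antiparallel dimer.

    Enumerable for completeness but excluded from scoring by default: with
    Leu fixed at every d position the a-d' layer carries no specificity
    signal in this design family.
    """
    aA, dB = pA.positions("a"), pB.positions("d")
    n = _truncate_warn(pA, pB, len(aA), len(dB), "a/d positions")
    out: list[ResiduePair] = []
    for k in range(n):
        i, j = aA[k], dB[n - 1 - k]
        out.append(ResiduePair("core_ad", i, j, pA.residue(i), pB.residue(j)))
    return out
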