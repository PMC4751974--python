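"""Constraint search for mutually heterospecific coiled-coil sets.

Starting from the stored candidate interactions (heterodimers whose
predicted Tm reaches the desired-pair floor), the search combines candidates
iteratively:

* pair search — every unordered pair of candidate interactions over four
  distinct peptides forms a 4-peptide mini-interactome of 10 pairings
  (2 desired + 4 homodimers + 4 cross heterodimers).  The set is accepted
  when every off-target Tm stays at or below the pair-level ceiling and the
  worst-case margin min(desired) − max(off-target) reaches the pair-level
  ΔTm floor.
* quadruple search — every unordered pair of accepted 4-peptide sets over
  eight distinct peptides forms a 36-pairing mini-interactome (4 desired +
  8 homodimers + 24 cross heterodimers = 32 off-targets), judged against
  the (laxer) quadruple-level ceiling and ΔTm floor.

Candidate combinations sharing any peptide are skipped without scoring:
cross-talk through the shared chain is certain, no quantification needed.
Homodimers are re-checked inside every mini-interactome even though import
filtering bounds them, so acceptance is self-contained and re-verifiable.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

import pandas as pd

__all__ = [
    "Interaction",
    "OrthogonalSet",
    "TmTable",
    "find_pairs",
    "find_quadruples",
    "rank_sets",
    "verify_set",
    "write_sets",
    "read_sets",
]


class TmProvider(Protocol):
    """Anything that can report a predicted Tm for an unordered id pair."""

    def tm(self, idA: str, idB: str) -> float: ...


class TmTable:
    """Dict-backed symmetric Tm lookup (hand-built tables, toy instances)."""

    def __init__(self, values: Mapping[tuple[str, str], float]) -> None:
        self._values = {frozenset((a, b)) if a != b else frozenset((a,)): float(v)
                        for (a, b), v in values.items()}

    def tm(self, idA: str, idB: str) -> float:
        key = frozenset((idA, idB)) if idA != idB else frozenset((idA,))
        return self._values[key]


@dataclass(frozen=True, order=True)
class Interaction:
    """One candidate desired heterodimer (canonical: idA <= idB)."""

    idA: str
    idB: str
    tm: float

    def __post_init__(self) -> None:
        if self.idA > self.idB:
            a, b = self.idB, self.idA
            object.__setattr__(self, "idA", a)
            object.__setattr__(self, "idB", b)

    @staticmethod
    def make(idA: str, idB: str, tm: float) -> "Interaction":
        a, b = sorted((idA, idB))
        return Interaction(a, b, float(tm))

    @property
    def members(self) -> frozenset[str]:
        return frozenset((self.idA, self.idB))


@dataclass(frozen=True)
class OrthogonalSet:
    """2 or 4 designated heterodimers over 4 or 8 peptides, with evidence.

    ``offtarget_max_tm`` is the worst off-target inside the set's full
    mini-interactome (homodimers included); ``delta_tm`` the worst-case
    margin min(desired) − max(off-target).
    """

    desired: tuple[Interaction, ...]
    offtarget_max_tm: float

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for inter in self.desired:
            if inter.members & seen:
                raise ValueError("a peptide appears in two desired interactions")
            seen |= inter.members

    @property
    def peptides(self) -> tuple[str, ...]:
        return tuple(sorted(p for inter in self.desired for p in inter.members))

    @property
    def min_desired_tm(self) -> float:
        return min(inter.tm for inter in self.desired)

    @property
    def delta_tm(self) -> float:
        return self.min_desired_tm - self.offtarget_max_tm

    def canonical(self) -> "OrthogonalSet":
        return OrthogonalSet(tuple(sorted(self.desired)), self.offtarget_max_tm)


def _offtargets(
    desired: Sequence[Interaction], tms: TmProvider
) -> list[tuple[str, str, float]]:
    """All pairings of the set's peptides other than the desired ones."""
    members = sorted(p for inter in desired for p in inter.members)
    wanted = {inter.members for inter in desired}
    out = []
    for a, b in itertools.combinations_with_replacement(members, 2):
        key = frozenset((a, b)) if a != b else frozenset((a,))
        if key in wanted:
            continue
        out.append((a, b, tms.tm(a, b)))
    return out


def _accept(
    desired: Sequence[Interaction],
    tms: TmProvider,
    max_offtarget: float,
    min_delta: float,
) -> OrthogonalSet | None:
    off = _offtargets(desired, tms)
    worst = max(tm for _, _, tm in off)
    if worst > max_offtarget:
        return None
    if min(i.tm for i in desired) - worst < min_delta:
        return None
    return OrthogonalSet(tuple(sorted(desired)), worst)


def _as_interactions(store) -> list[Interaction]:
    if isinstance(store, pd.DataFrame):
        rows = store.itertuples(index=False)
        return [Interaction.make(r.idA, r.idB, r.tm) for r in rows]
    return [
        i if isinstance(i, Interaction) else Interaction.make(*i) for i in store
    ]


def find_pairs(store, tms: TmProvider, criteria) -> list[OrthogonalSet]:
    """Search candidate interactions for orthogonal 4-peptide sets.

    ``store`` is the candidate interaction table (DataFrame with columns
    idA/idB/tm, or an iterable of (idA, idB, tm)); ``tms`` supplies the
    off-target Tm values (typically the :class:`~ccscreen.screen.Interactome`
    the store came from).  Candidates below ``criteria.min_desired_tm`` and
    homodimeric entries are ignored.  Output is ranked (see
    :func:`rank_sets`) and canonically deduplicated.
    """
    candidates = [
        c for c in _as_interactions(store)
        if c.tm >= criteria.min_desired_tm and c.idA != c.idB
    ]
    out: list[OrthogonalSet] = []
    for c1, c2 in itertools.combinations(sorted(candidates), 2):
        if c1.members & c2.members:
            continue  # shared peptide: cross-talk is certain, skip unscored
        s = _accept(
            (c1, c2), tms, criteria.max_offtarget_tm_pairs, criteria.min_delta_tm_pairs
        )
        if s is not None:
            out.append(s)
    return rank_sets(out)


def find_quadruples(
    pairsets: Iterable[OrthogonalSet], tms: TmProvider, criteria
) -> list[OrthogonalSet]:
    """Combine disjoint 4-peptide sets into orthogonal 8-peptide sets."""
    out: list[OrthogonalSet] = []
    pairsets = sorted(pairsets, key=lambda s: (s.peptides, s.desired))
    for s1, s2 in itertools.combinations(pairsets, 2):
        if set(s1.peptides) & set(s2.peptides):
            continue
        s = _accept(
            s1.desired + s2.desired,
            tms,
            criteria.max_offtarget_tm_quads,
            criteria.min_delta_tm_quads,
        )
        if s is not None:
            out.append(s)
    return rank_sets(out)


def rank_sets(sets: Iterable[OrthogonalSet]) -> list[OrthogonalSet]:
    """Strongest sets first: highest worst-case desired Tm, then widest
    margin, then lexicographic peptide ids as a deterministic tiebreak."""
    uniq = {s.canonical().desired: s.canonical() for s in sets}
    return sorted(
        uniq.values(), key=lambda s: (-s.min_desired_tm, -s.delta_tm, s.peptides)
    )


def verify_set(
    s: OrthogonalSet, tms: TmProvider, max_offtarget: float, min_delta: float
) -> bool:
    """Independent re-check: rescore every pairing of the set from scratch."""
    n = len(s.peptides)
    off = _offtargets(s.desired, tms)
    expected_off = n * (n + 1) // 2 - len(s.desired)
    if len(off) != expected_off:
        return False
    worst = max(tm for _, _, tm in off)
    desired_ok = all(
        abs(tms.tm(i.idA, i.idB) - i.tm) < 1e-9 for i in s.desired
    )
    return (
        desired_ok
        and worst <= max_offtarget
        and min(i.tm for i in s.desired) - worst >= min_delta
        and abs(worst - s.offtarget_max_tm) < 1e-9
    )


# -- serialisation --------------------------------------------------------


def write_sets(sets: Sequence[OrthogonalSet], path: str | Path) -> None:
    """JSON-lines: one object per set with peptides, desired pairs, margins."""
    with open(path, "w") as fh:
        for s in sets:
            fh.write(json.dumps({
                "peptides": list(s.peptides),
                "desired": [[i.idA, i.idB, i.tm] for i in s.desired],
                "offtarget_max_tm": s.offtarget_max_tm,
                "min_desired_tm": s.min_desired_tm,
                "delta_tm": s.delta_tm,
            }) + "\n")


def read_sets(path: str | Path) -> list[OrthogonalSet]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            desired = tuple(Interaction.make(a, b, tm) for a, b, tm in obj["desired"])
            out.append(OrthogonalSet(desired, obj["offtarget_max_tm"]))
    return out
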