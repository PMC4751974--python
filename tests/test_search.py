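"""Orthogonal-set search against exhaustive enumeration oracles."""

import itertools

import pytest

from ccscreen.screen import ScreenCriteria
from ccscreen.search import (
    Interaction,
    OrthogonalSet,
    TmTable,
    find_pairs,
    find_quadruples,
    rank_sets,
    verify_set,
    read_sets,
    write_sets,
)
from ccscreen.search import _offtargets  # oracle support


def toy_table(ids, desired, desired_tm=75.0, homodimer_tm=5.0, offtarget_tm=12.0,
              overrides=None):
    """Hand-set symmetric Tm table over `ids` with planted desired pairs."""
    values = {}
    for a in ids:
        values[(a, a)] = homodimer_tm
    for a, b in itertools.combinations(ids, 2):
        values[(a, b)] = offtarget_tm
    for a, b in desired:
        values[(a, b)] = desired_tm
    for k, v in (overrides or {}).items():
        values[k] = v
    return TmTable(values)


def exhaustive_pairs(candidates, tms, criteria):
    """Unpruned oracle: test every combination of two candidate interactions
    by recomputing the full 4-peptide mini-interactome condition."""
    out = []
    for c1, c2 in itertools.combinations(sorted(candidates), 2):
        members = c1.members | c2.members
        if len(members) < 4:
            continue
        off = [
            tms.tm(a, b)
            for a, b in itertools.combinations_with_replacement(sorted(members), 2)
            if frozenset((a, b)) not in (c1.members, c2.members)
        ]
        if max(off) <= criteria.max_offtarget_tm_pairs and (
            min(c1.tm, c2.tm) - max(off) >= criteria.min_delta_tm_pairs
        ):
            out.append(OrthogonalSet(tuple(sorted((c1, c2))), max(off)))
    return rank_sets(out)


CRIT = ScreenCriteria()  # 10/70/20/50 pair level, 30/40 quadruple level


class TestFindPairs:
    def test_planted_instance_equals_exhaustive_oracle(self):
        ids = list("ABCDEF")
        desired = [("A", "B"), ("C", "D"), ("E", "F")]
        # E-F's neighbourhood is too sticky to combine with anything
        overrides = {("A", "E"): 25.0, ("C", "E"): 35.0}
        tms = toy_table(ids, desired, overrides=overrides)
        candidates = [Interaction.make(a, b, tms.tm(a, b)) for a, b in desired]
        got = find_pairs(candidates, tms, CRIT)
        oracle = exhaustive_pairs(candidates, tms, CRIT)
        assert [s.desired for s in got] == [s.desired for s in oracle]
        assert {s.peptides for s in got} == {tuple("ABCD")}

    def test_candidates_sharing_a_peptide_never_combine(self):
        ids = list("ABC")
        tms = toy_table(ids, [("A", "B"), ("A", "C")])
        candidates = [
            Interaction.make("A", "B", 75.0),
            Interaction.make("A", "C", 75.0),
        ]
        assert find_pairs(candidates, tms, CRIT) == []

    def test_subthreshold_and_homodimeric_candidates_ignored(self):
        ids = list("ABCD")
        tms = toy_table(ids, [("A", "B"), ("C", "D")], desired_tm=75.0)
        candidates = [
            Interaction.make("A", "B", 75.0),
            Interaction.make("C", "D", 60.0),  # below the 70 degC floor
            Interaction.make("A", "A", 80.0),  # homodimer, never a candidate
        ]
        assert find_pairs(candidates, tms, CRIT) == []

    def test_empty_store(self):
        assert find_pairs([], toy_table(["A"], []), CRIT) == []

    def test_every_emitted_set_reverifies(self):
        ids = list("ABCDEFGH")
        desired = [("A", "B"), ("C", "D"), ("E", "F"), ("G", "H")]
        tms = toy_table(ids, desired)
        candidates = [Interaction.make(a, b, 75.0) for a, b in desired]
        sets = find_pairs(candidates, tms, CRIT)
        assert len(sets) == 6  # all C(4,2) combinations pass here
        for s in sets:
            assert verify_set(s, tms, CRIT.max_offtarget_tm_pairs, CRIT.min_delta_tm_pairs)

    def test_offtarget_count_for_pair_set(self):
        tms = toy_table(list("ABCD"), [("A", "B"), ("C", "D")])
        s = find_pairs(
            [Interaction.make("A", "B", 75.0), Interaction.make("C", "D", 75.0)],
            tms, CRIT,
        )[0]
        assert len(_offtargets(s.desired, tms)) == 8  # 4 homodimers + 4 cross


class TestFindQuadruples:
    def _pairsets(self, tms, desired):
        candidates = [Interaction.make(a, b, tms.tm(a, b)) for a, b in desired]
        return find_pairs(candidates, tms, CRIT)

    def test_twelve_peptide_instance_equals_exhaustive_oracle(self):
        ids = [f"p{i:02d}" for i in range(12)]
        desired = [(ids[i], ids[i + 1]) for i in range(0, 12, 2)]
        # make one cross-set neighbourhood fail the 30 degC quadruple ceiling
        overrides = {(ids[0], ids[4]): 32.0}
        tms = toy_table(ids, desired, offtarget_tm=25.0, overrides=overrides)
        # pair level: off-targets 25 > 20, so relax the pair stage to feed
        # the quadruple stage a full slate of 4-peptide sets
        crit = ScreenCriteria(
            max_offtarget_tm_pairs=26.0, min_delta_tm_pairs=40.0,
            max_offtarget_tm_quads=30.0, min_delta_tm_quads=40.0,
        )
        candidates = [Interaction.make(a, b, 75.0) for a, b in desired]
        pairsets = find_pairs(candidates, tms, crit)
        got = find_quadruples(pairsets, tms, crit)

        oracle = []
        for s1, s2 in itertools.combinations(pairsets, 2):
            members = set(s1.peptides) | set(s2.peptides)
            if len(members) < 8:
                continue
            wanted = {i.members for i in s1.desired + s2.desired}
            off = [
                tms.tm(a, b)
                for a, b in itertools.combinations_with_replacement(sorted(members), 2)
                if frozenset((a, b)) not in wanted
            ]
            if max(off) <= crit.max_offtarget_tm_quads and 75.0 - max(off) >= crit.min_delta_tm_quads:
                oracle.append(
                    OrthogonalSet(tuple(sorted(s1.desired + s2.desired)), max(off))
                )
        assert {s.desired for s in got} == {s.desired for s in oracle}
        assert got  # the instance is not vacuous
        assert all(ids[0] not in s.peptides or ids[4] not in s.peptides for s in got)
        for s in got:
            assert len(s.peptides) == 8
            assert len(_offtargets(s.desired, tms)) == 32
            assert verify_set(s, tms, crit.max_offtarget_tm_quads, crit.min_delta_tm_quads)

    def test_pairsets_sharing_a_peptide_skipped(self):
        tms = toy_table(list("ABCDEF"), [("A", "B"), ("C", "D"), ("A", "F")])
        s1 = OrthogonalSet(
            (Interaction.make("A", "B", 75.0), Interaction.make("C", "D", 75.0)), 12.0
        )
        s2 = OrthogonalSet(
            (Interaction.make("A", "F", 75.0), Interaction.make("C", "D", 75.0)), 12.0
        )
        assert find_quadruples([s1, s2], tms, CRIT) == []


class TestMonotonicity:
    def test_threshold_monotonicity(self):
        """Tightening the off-target ceiling never adds sets; loosening
        never removes them."""
        ids = list("ABCDEFGH")
        desired = [("A", "B"), ("C", "D"), ("E", "F"), ("G", "H")]
        overrides = {("A", "C"): 18.0, ("A", "E"): 14.0, ("B", "G"): 19.5}
        tms = toy_table(ids, desired, offtarget_tm=12.0, overrides=overrides)
        candidates = [Interaction.make(a, b, 75.0) for a, b in desired]
        previous: set = set()
        for ceiling in (13.0, 15.0, 18.5, 20.0):
            crit = ScreenCriteria(max_offtarget_tm_pairs=ceiling, min_delta_tm_pairs=40.0)
            current = {s.desired for s in find_pairs(candidates, tms, crit)}
            assert previous <= current
            previous = current
        assert len(previous) == 6


class TestRanking:
    def test_wider_margin_ranks_first_at_equal_desired_tm(self):
        a = OrthogonalSet(
            (Interaction.make("A", "B", 73.0), Interaction.make("C", "D", 73.0)), 28.0
        )  # delta 45
        b = OrthogonalSet(
            (Interaction.make("E", "F", 73.0), Interaction.make("G", "H", 73.0)), 33.0
        )  # delta 40
        assert rank_sets([b, a]) == [a, b]

    def test_single_set(self):
        s = OrthogonalSet((Interaction.make("A", "B", 73.0),), 10.0)
        assert rank_sets([s]) == [s]

    def test_permutation_invariant_and_deduplicating(self):
        s1 = OrthogonalSet(
            (Interaction.make("A", "B", 73.0), Interaction.make("C", "D", 72.0)), 20.0
        )
        s2 = OrthogonalSet(
            (Interaction.make("C", "D", 72.0), Interaction.make("A", "B", 73.0)), 20.0
        )
        s3 = OrthogonalSet((Interaction.make("E", "F", 75.0),), 20.0)
        assert rank_sets([s1, s3, s2]) == rank_sets([s3, s2, s1])
        assert len(rank_sets([s1, s2])) == 1

    def test_shared_peptide_within_set_rejected(self):
        with pytest.raises(ValueError, match="two desired"):
            OrthogonalSet(
                (Interaction.make("A", "B", 73.0), Interaction.make("A", "C", 73.0)),
                10.0,
            )


class TestSerialisation:
    def test_jsonl_round_trip(self, tmp_path):
        sets = [
            OrthogonalSet(
                (Interaction.make("A", "B", 73.0), Interaction.make("C", "D", 72.5)),
                18.0,
            )
        ]
        path = tmp_path / "sets.jsonl"
        write_sets(sets, path)
        assert read_sets(path) == sets
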