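"""Register assignment and interhelical pair enumeration."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ccscreen.heptad import (
    RegisterWarning,
    RegisteredPeptide,
    antiparallel_electrostatic_pairs,
    assign_register,
    parallel_core_pairs,
    parallel_electrostatic_pairs,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestAssignRegister:
    def test_reference_peptide_register(self, pep):
        """The g-start, 2/3-capped register puts NNII at a and EKKE at g/e."""
        p = pep["pep1"]
        assert p.register.startswith("--g") and p.register.endswith("---")
        assert [p.sequence[i] for i in p.positions("a")] == list("NNII")
        assert [p.sequence[i] for i in p.positions("g")] == list("EKKE")
        assert [p.sequence[i] for i in p.positions("e")] == list("EKKE")
        assert len(p.electro_heptads()) == 4

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError, match="non-standard residue"):
            assign_register("ABCDEFG", "a")

    def test_single_heptad_from_a(self):
        with pytest.warns(RegisterWarning, match="no complete g..e span"):
            p = assign_register("LLLLLLL", "a")
        assert p.register == "abcdefg"
        assert parallel_electrostatic_pairs(p, p) == []

    def test_register_sequence_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            RegisteredPeptide("x", "LLL", "gabc")

    def test_broken_cyclic_order_rejected(self):
        with pytest.raises(ValueError, match="cyclic"):
            RegisteredPeptide("x", "LLLLLLL", "gabcdfe")

    def test_internal_cap_rejected(self):
        with pytest.raises(ValueError, match="terminal"):
            RegisteredPeptide("x", "LLLLLLLLL", "ga-bcdefg")

    def test_caps_excluded_from_scoring(self, pep):
        p = pep["pep1"]
        assert len(p.scored_sequence()) == 27
        assert p.scored_sequence() == p.sequence[2:-3]

    @given(
        start=st.sampled_from("abcdefg"),
        n=st.integers(min_value=7, max_value=30),
        caps=st.tuples(st.integers(0, 3), st.integers(0, 3)),
    )
    def test_register_is_cyclic_and_cap_flanked(self, start, n, caps):
        pre, suf = caps
        seq = "L" * (n + pre + suf)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RegisterWarning)
            p = assign_register(seq, start, pre, suf)
        core = p.register.strip("-")
        assert len(core) == n
        order = "gabcdef"
        k = order.index(start)
        assert core == "".join(order[(k + i) % 7] for i in range(n))


def _kinds(pairs):
    return sorted(tuple(sorted((p.resA, p.resB))) for p in pairs)


class TestParallelPairs:
    @pytest.mark.parametrize(
        "a, b, expected_core",
        [
            ("pep1", "pep2", [("N", "N"), ("N", "N"), ("I", "I"), ("I", "I")]),
            ("pep1", "pep3", [("I", "N")] * 4),
            ("pep1", "pep5", [("N", "N"), ("I", "N"), ("I", "I"), ("I", "N")]),
        ],
    )
    def test_core_pair_compositions(self, pep, a, b, expected_core):
        pairs = parallel_core_pairs(pep[a], pep[b])
        assert _kinds(pairs) == sorted(tuple(sorted(p)) for p in expected_core)
        assert all(p.kind == "core_aa" for p in pairs)

    def test_desired_pair_fully_attractive_electrostatics(self, pep):
        pairs = parallel_electrostatic_pairs(pep["pep1"], pep["pep2"])
        assert len(pairs) == 8
        assert _kinds(pairs) == [("E", "K")] * 8

    def test_homodimer_fully_repulsive_electrostatics(self, pep):
        pairs = parallel_electrostatic_pairs(pep["pep1"], pep["pep1"])
        assert len(pairs) == 8
        assert all(p.resA == p.resB for p in pairs)  # all E-E or K-K

    def test_offtarget_half_attractive(self, pep):
        pairs = parallel_electrostatic_pairs(pep["pep1"], pep["pep3"])
        attractive = [p for p in pairs if p.resA != p.resB]
        assert len(pairs) == 8 and len(attractive) == 4

    def test_zero_a_positions_gives_empty_core(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RegisterWarning)
            p = assign_register("LLL", "b")  # b c d: no a position
        assert parallel_core_pairs(p, p) == []

    def test_unequal_heptads_truncate_with_warning(self, pep):
        short = assign_register("E" + "NAALEA" + "KNAALKY", "g", id="short")  # 2 heptads
        with pytest.warns(RegisterWarning, match="overlapping"):
            pairs = parallel_electrostatic_pairs(pep["pep1"], short)
        assert len(pairs) == 4  # 2 common heptads x 2 contacts


class TestAntiparallelPairs:
    def test_octet_back_half_fully_complementary(self, pep):
        for pid in ("pep5", "pep6", "pep7", "pep8"):
            pairs = antiparallel_electrostatic_pairs(pep[pid], pep[pid])
            assert len(pairs) == 8
            assert _kinds(pairs) == [("E", "K")] * 8

    def test_all_acidic_homodimer_fully_repulsive(self, pep):
        pairs = antiparallel_electrostatic_pairs(pep["pep3"], pep["pep3"])
        assert _kinds(pairs) == [("E", "E")] * 8

    def test_front_half_homodimers_mixed(self, pep):
        pairs = antiparallel_electrostatic_pairs(pep["pep1"], pep["pep1"])
        kinds = set(_kinds(pairs))
        assert len(pairs) == 8
        assert kinds != {("E", "K")}  # not fully complementary
        assert any(k in kinds for k in (("E", "E"), ("K", "K")))


class TestInvariants:
    def test_symmetry_over_all_36_pairs(self, octet):
        """(A,B) and (B,A) enumerate the same contacts with members swapped."""
        for pA, pB in itertools.combinations_with_replacement(octet, 2):
            for fn in (
                parallel_core_pairs,
                parallel_electrostatic_pairs,
                antiparallel_electrostatic_pairs,
            ):
                ab = {((q.posA, q.posB), (q.resA, q.resB)) for q in fn(pA, pB)}
                ba = {((q.posB, q.posA), (q.resB, q.resA)) for q in fn(pB, pA)}
                assert ab == ba

    def test_count_conservation(self, octet):
        """Four-heptad chains always give 4 core and 8 electrostatic pairs."""
        for pA, pB in itertools.combinations_with_replacement(octet, 2):
            assert len(parallel_core_pairs(pA, pB)) == 4
            assert len(parallel_electrostatic_pairs(pA, pB)) == 8
            assert len(antiparallel_electrostatic_pairs(pA, pB)) == 8

    @given(
        data=st.data(),
        length=st.integers(min_value=12, max_value=33),
        start=st.sampled_from("abcdefg"),
    )
    def test_brute_force_index_oracle(self, data, length, start):
        """Enumeration equals a raw scan over index pairs filtered by
        register letters and the +/-5 (parallel) or mirrored (antiparallel)
        offset rules."""
        import warnings

        seqA = data.draw(st.text(AA, min_size=length, max_size=length))
        seqB = data.draw(st.text(AA, min_size=length, max_size=length))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RegisterWarning)
            pA = assign_register(seqA, start, id="A")
            pB = assign_register(seqB, start, id="B")
        reg = pA.register
        L = length

        expected_par = {
            (i, i + 5) for i in range(L) if reg[i] == "g" and i + 5 < L and reg[i + 5] == "e"
        } | {
            (j, j - 5) for j in range(L) if reg[j] == "e" and j - 5 >= 0 and reg[j - 5] == "g"
        }
        got_par = {(q.posA, q.posB) for q in parallel_electrostatic_pairs(pA, pB)}
        assert got_par == expected_par

        g_complete = [i for i in range(L) if reg[i] == "g" and i + 5 < L and reg[i + 5] == "e"]
        n = len(g_complete)
        expected_anti = {(g_complete[k], g_complete[n - 1 - k]) for k in range(n)} | {
            (g_complete[k] + 5, g_complete[n - 1 - k] + 5) for k in range(n)
        }
        got_anti = {(q.posA, q.posB) for q in antiparallel_electrostatic_pairs(pA, pB)}
        assert got_anti == expected_anti
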