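"""Pattern energies, initiation rules, assembly and the entropy split."""

import math

import pytest

from nnmelt.energetics import (EnergyModel, assemble, compute_breakdown,
                               initiation_energy, internal_loop_energy_lu,
                               pattern_energy, perfect_energy,
                               pre_correct_0p1M_set, symmetry_energy)
from nnmelt.errors import (MissingParameterError, NoFormulaError,
                           TerminalMismatchError)
from nnmelt.fixtures import FixtureSpec, make_duplex, make_fixture_set
from nnmelt.paramstore import ParameterSet, ThermoResult, key
from nnmelt.segmentation import PatternSegment, segment
from nnmelt.sequences import build_duplex


def _perfect_seg(duplex):
    return PatternSegment("perfect", 0, len(duplex))


class TestPerfectEnergy:
    def test_uniform_five_mer_has_four_stacks(self, uniform_set):
        duplex = build_duplex("ACGTA", None, "dnadna")
        e = perfect_energy(_perfect_seg(duplex), duplex, uniform_set)
        assert e.thermo == ThermoResult(-32000, -88)

    def test_two_mer_has_one_stack(self, uniform_set):
        duplex = build_duplex("AC", None, "dnadna")
        e = perfect_energy(_perfect_seg(duplex), duplex, uniform_set)
        assert e.thermo == ThermoResult(-8000, -22)

    def test_heterogeneous_hand_sum(self, tiny_neighbor_set):
        # AAT: stacks AA/TT (-7900) + AT/TA (-7200)
        duplex = build_duplex("AAT", None, "dnadna")
        e = perfect_energy(_perfect_seg(duplex), duplex, tiny_neighbor_set)
        assert e.thermo.dh == pytest.approx(-15100)
        assert e.thermo.ds == pytest.approx(-42.6)

    def test_missing_stack_names_descriptor(self, tiny_neighbor_set):
        duplex = build_duplex("AGC", None, "dnadna")
        with pytest.raises(MissingParameterError, match="AG/TC"):
            perfect_energy(_perfect_seg(duplex), duplex, tiny_neighbor_set)


class TestInitiation:
    def test_per_terminal_counts_both_classes(self, tiny_neighbor_set):
        duplex = build_duplex("ATGC", None, "dnadna")  # ends A.T and C.G
        e = initiation_energy(duplex, tiny_neighbor_set)
        assert e == ThermoResult(2300 + 100, 4.1 - 2.8)

    def test_two_class_rule(self):
        pset = ParameterSet(id="b", hybridization_scope="dnadna",
                            metadata={"initiation-rule": "two_class"})
        pset.entries[key("initiation", type="two_AT")] = ThermoResult(0, -20.1)
        pset.entries[key("initiation", type="at_least_one_GC")] = \
            ThermoResult(0, -16.8)
        both_at = build_duplex("ATTA", None, "dnadna")
        one_gc = build_duplex("ATTG", None, "dnadna")
        assert initiation_energy(both_at, pset) == ThermoResult(0, -20.1)
        assert initiation_energy(one_gc, pset) == ThermoResult(0, -16.8)

    def test_base_plus_terminal_au_rule(self):
        pset = ParameterSet(id="x", hybridization_scope="rnarna",
                            metadata={"initiation-rule": "base_plus_terminal_AU"})
        pset.entries[key("initiation", type="base")] = ThermoResult(3610, -1.5)
        pset.entries[key("initiation", type="per_AU")] = ThermoResult(3720, 10.5)
        duplex = build_duplex("AGCG", None, "rnarna")  # one terminal A.U
        assert initiation_energy(duplex, pset) == ThermoResult(3610 + 3720, 9.0)

    def test_cng_duplex_has_zero_initiation(self, uniform_set):
        duplex = build_duplex("CAGCAG", None, "dnadna", self_flag=True)
        assert initiation_energy(duplex, uniform_set, is_cng=True) == \
            ThermoResult(0, 0)

    def test_dangling_columns_do_not_shift_the_terminals(self, tiny_neighbor_set):
        plain = build_duplex("ATGC", None, "dnadna")
        hung = build_duplex("CATGC", "-TACG", "dnadna")
        assert initiation_energy(hung, tiny_neighbor_set) == \
            initiation_energy(plain, tiny_neighbor_set)


class TestSymmetry:
    def test_non_self_complementary_is_zero(self, tiny_neighbor_set):
        duplex = build_duplex("ATGC", None, "dnadna")
        assert symmetry_energy(duplex, tiny_neighbor_set) == ThermoResult(0, 0)

    def test_self_complementary_reads_the_entry(self, tiny_neighbor_set):
        duplex = build_duplex("CATG", None, "dnadna")
        assert symmetry_energy(duplex, tiny_neighbor_set) == ThermoResult(0, -1.4)

    def test_flag_and_detection_agree(self, tiny_neighbor_set):
        detected = build_duplex("CATG", None, "dnadna")
        flagged = build_duplex("CATG", None, "dnadna", self_flag=True)
        assert symmetry_energy(detected, tiny_neighbor_set) == \
            symmetry_energy(flagged, tiny_neighbor_set)


class TestLuLoop:
    def _loop_duplex_and_set(self, closing="GC", dh_asym=-500.0):
        # perfect flanks around a 1x3 loop; the closing pairs are G.C or A.U
        if closing == "GC":
            seq1, seq2 = "GGA--GC", "CCCUGCG"
        else:
            seq1, seq2 = "GAC--AU", "CUAGGUA"
        duplex = build_duplex(seq1, seq2, "rnarna")
        pset = ParameterSet(id="lu", hybridization_scope="rnarna")
        pset.entries[key("mismatch", type="initiation", size="4")] = \
            ThermoResult(4000, -10.0)
        pset.entries[key("asymmetry")] = ThermoResult(dh_asym, -3.0)
        pset.entries[key("closure", type="per_AU_GU")] = ThermoResult(900, -2.0)
        return duplex, pset

    def test_entropy_is_exactly_zero(self):
        duplex, pset = self._loop_duplex_and_set()
        seg = segment(duplex)[1]
        e = internal_loop_energy_lu(seg, duplex, pset)
        assert e.thermo.ds == 0.0

    def test_gc_closings_no_penalty_terms(self):
        duplex, pset = self._loop_duplex_and_set()
        seg = segment(duplex)[1]
        e = internal_loop_energy_lu(seg, duplex, pset)
        # initiation + signed (1-3) asymmetry only
        assert e.thermo.dh == 4000 + (1 - 3) * -500.0

    def test_au_closings_add_two_penalties(self):
        duplex, pset = self._loop_duplex_and_set(closing="AU")
        seg = segment(duplex)[1]
        e = internal_loop_energy_lu(seg, duplex, pset)
        assert e.thermo.dh == 4000 + 2 * 900 + (1 - 3) * -500.0

    def test_rejected_outside_rnarna(self):
        duplex = build_duplex("GGA--GC", "CCCTGCG", "dnadna")
        seg = segment(duplex)[1]
        _, pset = self._loop_duplex_and_set()
        from nnmelt.errors import NotApplicableError
        with pytest.raises(NotApplicableError):
            internal_loop_energy_lu(seg, duplex, pset)


class TestDispatchAndAssembly:
    def test_fig1_style_total(self, uniform_set):
        # perfect + single mismatch + perfect, uniform values: the total is
        # initiation + 2 mismatch doublets + (L1-1) + (L3-1) stacks
        duplex = build_duplex("AAAGTTT", "TTTGAAA", "dnadna")
        segments, breakdown = compute_breakdown(duplex, EnergyModel(uniform_set))
        assert [s.kind for s in segments] == \
            ["perfect", "single_mismatch", "perfect"]
        n_terms = 2 + 2 + 2          # stacks + mismatch doublets
        expected_dh = n_terms * -8000 + 2 * -8000  # + 2 initiation entries
        assert breakdown.total.dh == expected_dh

    def test_terminal_mismatch_rejected(self, uniform_set):
        duplex = build_duplex("GAAAA", "ATTTT", "dnadna")  # 5' terminal G.A
        with pytest.raises(TerminalMismatchError):
            compute_breakdown(duplex, EnergyModel(uniform_set))

    def test_azobenzene_outside_dnadna_has_no_formula(self):
        rna_set = make_fixture_set(FixtureSpec(hybridization="rnarna"))
        duplex = build_duplex("AAX_CUU", "UU-AA", "rnarna")
        with pytest.raises(NoFormulaError):
            compute_breakdown(duplex, EnergyModel(rna_set))

    def test_cng_pattern_is_single_lookup(self):
        duplex = build_duplex("CAG" * 3, None, "dnadna", self_flag=True)
        pset = ParameterSet(id="cng", hybridization_scope="dnadna")
        pset.entries[key("CNG", sequence="CAG", repeats="3")] = \
            ThermoResult(-40000, -120)
        seg = segment(duplex)[0]
        assert pattern_energy(seg, duplex, EnergyModel(pset)) == \
            ThermoResult(-40000, -120)

    def test_dangling_lookup_uses_sens(self):
        duplex = build_duplex("AGC", "-CG", "dnadna")
        pset = ParameterSet(id="d", hybridization_scope="dnadna")
        pset.entries[key("dangling", sequence="AG/-C", sens="5")] = \
            ThermoResult(-500, -1.0)
        seg = segment(duplex)[0]
        assert seg.kind == "single_dangling"
        assert pattern_energy(seg, duplex, EnergyModel(pset)) == \
            ThermoResult(-500, -1.0)

    def test_terminal_inosine_penalty_added_for_rna(self):
        duplex = build_duplex("IGC", "UCG", "rnarna")
        pset = ParameterSet(id="t", hybridization_scope="rnarna")
        pset.entries[key("modified", sequence="IG/UC")] = ThermoResult(-1000, -3)
        base = pattern_energy(segment(duplex)[0], duplex, EnergyModel(pset))
        pset.entries[key("terminal", type="IU")] = ThermoResult(400, 1.0)
        with_pen = pattern_energy(segment(duplex)[0], duplex, EnergyModel(pset))
        assert with_pen == base + ThermoResult(400, 1.0)

    def test_strand_reversal_invariance(self):
        spec = FixtureSpec(defects=("single_mismatch", "single_bulge"),
                           scheme="random", seed=11)
        duplex, _ = make_duplex(spec)
        pset = make_fixture_set(spec)
        _, fwd = compute_breakdown(duplex, EnergyModel(pset))
        # reading the duplex from the other end: the former bottom strand,
        # reversed, becomes the 5'->3' top strand
        rev = build_duplex(duplex.bottom.text[::-1], duplex.top.text[::-1],
                           "dnadna")
        pset2 = make_fixture_set(spec, duplexes=[duplex, rev])
        _, fwd2 = compute_breakdown(duplex, EnergyModel(pset2))
        _, bwd = compute_breakdown(rev, EnergyModel(pset2))
        assert bwd.total == fwd2.total

    def test_additivity_of_perfect_stacks(self, uniform_set):
        left = build_duplex("ACGT", None, "dnadna")
        right = build_duplex("TACG", None, "dnadna")
        joined = build_duplex("ACGTACG", None, "dnadna")
        seg = _perfect_seg
        total = (perfect_energy(seg(left), left, uniform_set).thermo
                 + perfect_energy(seg(right), right, uniform_set).thermo
                 + uniform_set.lookup(key("neighbor", sequence="TT/AA")))
        # 'right' shares its first base with 'left''s last: discount the
        # duplicated boundary residue by construction of the sequences
        got = perfect_energy(seg(joined), joined, uniform_set).thermo
        assert got == ThermoResult(total.dh + 8000, total.ds + 22)


class TestEntropySplit:
    def _loop_breakdown(self, l1=3, l2=4):
        spec = FixtureSpec(defects=("internal_loop",), loop_sizes=(l1, l2),
                           scheme="random", seed=5)
        duplex, _ = make_duplex(spec)
        pset = make_fixture_set(spec)
        return compute_breakdown(duplex, EnergyModel(pset))[1], pset, (l1, l2)

    def test_large_loop_split_matches_hand_recomputation(self):
        breakdown, pset, (l1, l2) = self._loop_breakdown(3, 4)
        init_ds = pset.lookup(key("mismatch", type="initiation",
                                  size=str(l1 + l2))).ds
        asym_ds = pset.lookup(key("asymmetry")).ds * abs(l1 - l2)
        assert breakdown.ds_salt_independent == pytest.approx(init_ds + asym_ds)
        assert breakdown.ds_salt_dependent + breakdown.ds_salt_independent == \
            pytest.approx(breakdown.total.ds)

    def test_small_loop_is_fully_salt_dependent(self):
        breakdown, _, _ = self._loop_breakdown(1, 3)
        assert breakdown.ds_salt_independent == 0.0


class TestPreCorrection:
    def _set_at(self, ref):
        pset = ParameterSet(id="m", hybridization_scope="mrnarna",
                            metadata={"reference-sodium": ref})
        pset.entries[key("neighbor", sequence="AA/UU")] = ThermoResult(-7000, -20)
        return pset

    def test_1M_set_unchanged(self):
        pset = self._set_at(1.0)
        assert pre_correct_0p1M_set(pset) is pset

    def test_only_entropies_move(self):
        pset = self._set_at(0.1)
        corrected = pre_correct_0p1M_set(pset)
        k = key("neighbor", sequence="AA/UU")
        assert corrected.entries[k].dh == pset.entries[k].dh
        assert corrected.entries[k].ds != pset.entries[k].ds
        assert corrected.reference_sodium == 1.0

    def test_inverse_recovers_original(self):
        pset = self._set_at(0.1)
        corrected = pre_correct_0p1M_set(pset)
        k = key("neighbor", sequence="AA/UU")
        back = corrected.entries[k].ds + 0.368 * math.log(0.1)
        assert back == pytest.approx(pset.entries[k].ds, abs=1e-9)
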