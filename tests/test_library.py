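"""Mutant-library enumeration, fragment design and chip layout."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinachscan import library
from spinachscan.library import (
    AlphabetError,
    CapacityError,
    FragmentTags,
    MutantSpec,
    PointMutation,
    ReferenceMismatchError,
    apply_mutations,
    design_fragments,
    deletion_spec,
    dpm_count,
    enumerate_compensatory_dpms,
    enumerate_spms,
    expand_ranges,
    plan_chip_layout,
    stitch_fragments,
    wildtype_spec,
)

rna_seq = st.text(alphabet="ACGU", min_size=1, max_size=30)


class TestEnumerateSpms:
    def test_87nt_reference_yields_261(self, reference):
        seq, _ = reference
        assert len(seq) == 87
        assert len(enumerate_spms(seq)) == 261

    def test_two_nt_sequence_yields_six(self):
        specs = enumerate_spms("AC")
        assert len(specs) == 6
        assert len({s.id for s in specs}) == 6

    def test_each_position_gets_transition_then_transversions(self):
        specs = enumerate_spms("A")
        classes = [s.substitutions[0].mut_class for s in specs]
        assert classes == ["transition", "transversion", "transversion"]
        # transversions in alphabetical order
        assert [s.substitutions[0].alt_base for s in specs] == ["G", "C", "U"]

    @given(seq=rna_seq)
    @settings(max_examples=50, deadline=None)
    def test_count_is_3n_and_wt_bases_match(self, seq):
        specs = enumerate_spms(seq)
        assert len(specs) == 3 * len(seq)
        assert len({s.id for s in specs}) == len(specs)
        for s in specs:
            m = s.substitutions[0]
            assert seq[m.position - 1] == m.wt_base

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(AlphabetError):
            enumerate_spms("ACGT")  # DNA thymine in an RNA library


class TestEnumerateDpms:
    def test_complete_scan_87nt_yields_11223(self, reference):
        seq, _ = reference
        assert dpm_count(len(seq)) == 11223
        assert len(enumerate_compensatory_dpms(seq)) == 11223

    def test_three_nt_complete_scan_matches_brute_force(self):
        seq = "ACG"
        specs = enumerate_compensatory_dpms(seq)
        assert len(specs) == 9
        # brute force: every unordered pair x 3 joint substitution classes
        brute = set()
        for i, j in itertools.combinations(range(1, 4), 2):
            for k in range(3):
                ai = library.substitution_alternatives(seq[i - 1])[k]
                aj = library.substitution_alternatives(seq[j - 1])[k]
                brute.add(((i, ai), (j, aj)))
        got = {
            tuple((m.position, m.alt_base) for m in s.substitutions) for s in specs
        }
        assert got == brute

    def test_empty_pair_set_yields_empty_list(self):
        assert enumerate_compensatory_dpms("ACGU", pairs=[]) == []

    def test_equal_positions_rejected(self):
        with pytest.raises(ValueError):
            enumerate_compensatory_dpms("ACGU", pairs=[(2, 2)])

    def test_pairing_map_restores_watson_crick(self):
        # A1 pairs U4: every DPM's position-4 base must complement position 1
        specs = enumerate_compensatory_dpms("AGCU", pairs=[(1, 4)], pairing_map=[(1, 4)])
        assert len(specs) == 3
        for s in specs:
            by_pos = {m.position: m.alt_base for m in s.substitutions}
            assert library.WC_PAIR[by_pos[1]] == by_pos[4]

    @given(n=st.integers(min_value=2, max_value=10))
    @settings(max_examples=10, deadline=None)
    def test_count_matches_closed_form(self, n):
        seq = ("ACGU" * 3)[:n]
        assert len(enumerate_compensatory_dpms(seq)) == dpm_count(n)


class TestApplyMutations:
    def test_stated_deletions_shrink_98nt_parent_to_87(self):
        parent = ("ACGU" * 25)[:98]
        spec = deletion_spec(expand_ranges([(37, 43), (56, 59)]), id="truncation")
        assert len(apply_mutations(parent, spec)) == 87

    def test_wildtype_spec_is_identity(self):
        seq = "ACGUACGU"
        assert apply_mutations(seq, wildtype_spec()) == seq

    def test_single_substitution_changes_one_index(self):
        seq = "ACGUACGU"
        spec = MutantSpec(id="G3A", substitutions=(PointMutation(3, "G", "A"),))
        out = apply_mutations(seq, spec)
        assert sum(a != b for a, b in zip(seq, out)) == 1
        assert out[2] == "A"

    @given(seq=st.text(alphabet="ACGU", min_size=2, max_size=20), data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_corrupted_wt_base_always_raises(self, seq, data):
        pos = data.draw(st.integers(min_value=1, max_value=len(seq)))
        true_base = seq[pos - 1]
        wrong_wt = data.draw(st.sampled_from(sorted(set("ACGU") - {true_base})))
        alt = data.draw(st.sampled_from(sorted(set("ACGU") - {wrong_wt})))
        spec = MutantSpec(
            id="bad", substitutions=(PointMutation(pos, wrong_wt, alt),)
        )
        with pytest.raises(ReferenceMismatchError):
            apply_mutations(seq, spec)


class TestFragmentDesign:
    def test_mutation_left_of_overlap_is_5prime_and_round_trips(self):
        seq = "ACGUACGUACGUACGUACGUACGUACGUACGU"  # 32 nt
        design = design_fragments(seq, mutated_positions=[2], overlap_len=10)
        assert design.mutation_placement == "5prime"
        assert stitch_fragments(design) == seq

    def test_mutation_inside_overlap_needs_both_fragments(self):
        seq = "ACGU" * 8
        design = design_fragments(seq, mutated_positions=[16], overlap_len=10)
        lo, hi = design.overlap_window
        assert lo <= 16 <= hi
        assert design.mutation_placement == "both"

    def test_wildtype_has_no_placement(self):
        design = design_fragments("ACGU" * 8, overlap_len=10)
        assert design.mutation_placement is None

    def test_tags_prepended_and_stripped_on_stitch(self):
        seq = "ACGU" * 8
        tags = FragmentTags(promoter="TAATACGACTCACTATAG", anchor="AAA", probe="CCC")
        design = design_fragments(seq, overlap_len=10, tags=tags)
        assert design.fragment5.startswith(tags.prefix)
        assert stitch_fragments(design) == seq

    def test_round_trip_on_1000_random_mutants(self, reference, rng):
        seq, _ = reference
        spms = enumerate_spms(seq)
        for _ in range(1000):
            spec = spms[rng.integers(len(spms))]
            mut_seq = apply_mutations(seq, spec)
            design = design_fragments(
                mut_seq, [m.position for m in spec.substitutions]
            )
            assert stitch_fragments(design) == mut_seq


class TestChipLayout:
    def test_640_cells_4_replicates_host_160_mutants(self, reference):
        seq, _ = reference
        mutants = [wildtype_spec()] + enumerate_spms(seq)[:159]
        layout = plan_chip_layout(mutants, n_cells=640, replicates=4)
        assert layout.capacity == 160
        assert len(layout.assignments) == 640
        counts = {}
        for a in layout.assignments:
            counts[a.mutant_id] = counts.get(a.mutant_id, 0) + 1
        assert set(counts.values()) == {4}

    def test_small_chip_capacity(self):
        layout = plan_chip_layout([wildtype_spec(), MutantSpec(id="x")][:2],
                                  n_cells=8, replicates=4)
        assert layout.capacity == 2

    def test_over_capacity_reports_required_cells(self, reference):
        seq, _ = reference
        mutants = enumerate_spms(seq)[:161]
        with pytest.raises(CapacityError, match="644"):
            plan_chip_layout(mutants, n_cells=640, replicates=4)

    def test_seeded_shuffle_is_reproducible(self):
        mutants = [MutantSpec(id=f"m{i}") for i in range(10)]
        a = plan_chip_layout(mutants, n_cells=40, replicates=4, seed=7)
        b = plan_chip_layout(mutants, n_cells=40, replicates=4, seed=7)
        assert a == b
        c = plan_chip_layout(mutants, n_cells=40, replicates=4, seed=8)
        assert [x.cell for x in a.assignments] != [x.cell for x in c.assignments]
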