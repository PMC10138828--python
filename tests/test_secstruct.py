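"""α-helix/β-turn assignment and β-sheet domain detection."""

import numpy as np
import pytest

from conftest import frame_from_points
from ssmdscan.alignment import alignment_matrix
from ssmdscan.contact_maps import ContactCriterion, ContactMap, contact_map, distance_map
from ssmdscan.kernels import build_kernel_library
from ssmdscan.secstruct import (
    beta_sheet_domains,
    find_alpha_and_turn,
    helix_content,
    max_consecutive_run,
    peptides_in_beta_fraction,
    strand_pair_col_vector,
    strand_pair_row_vector,
    triplet_projection,
    turn_content,
)
from ssmdscan.synth import make_helix, make_sheet


def contacts_to_matrix(contacts, res):
    C = np.zeros((res, res), dtype=np.uint8)
    for i, j in contacts:
        C[i, j] = C[j, i] = 1
    return C


class TestHelixTurnAssignment:
    def test_ideal_helix_pace_hand_trace(self):
        contacts = [(0, 4), (1, 5), (2, 6), (3, 7)]
        a = find_alpha_and_turn(contacts_to_matrix(contacts, 8))
        assert a.count_alpha == 4
        assert a.pace_helix == pytest.approx(4.0)
        assert a.count_beta_turn == 0
        assert a.helix_residues == frozenset(range(8))

    def test_long_range_contact_is_a_turn(self):
        a = find_alpha_and_turn(contacts_to_matrix([(0, 7)], 8))
        assert a.count_beta_turn == 1
        assert a.length_beta_turn == pytest.approx(7.0)
        assert a.count_alpha == 0
        assert a.turn_residues == frozenset(range(8))

    def test_empty_map_all_zero(self):
        a = find_alpha_and_turn(np.zeros((8, 8), dtype=np.uint8))
        assert (a.count_alpha, a.count_beta_turn) == (0, 0)
        assert a.pace_helix == 0.0 and a.length_beta_turn == 0.0

    def test_mixed_contacts_split_into_classes(self):
        a = find_alpha_and_turn(
            contacts_to_matrix([(0, 4), (0, 5), (1, 4), (0, 7)], 8)
        )
        assert a.count_alpha == 2  # separations 4 and 5
        assert a.pace_helix == pytest.approx(4.5)
        assert a.count_beta_turn == 2  # separations 3 and 7
        assert a.length_beta_turn == pytest.approx(5.0)

    def test_running_mean_equals_plain_mean(self):
        rng = np.random.default_rng(0)
        seps = rng.integers(4, 6, size=12)
        contacts = [(0, int(s)) for s in seps]  # same i reused is fine
        a = find_alpha_and_turn(contacts_to_matrix(contacts, 10))
        expected = np.mean([j - i for i, j in a.alpha_contact_list])
        assert a.pace_helix == pytest.approx(expected, abs=1e-12)

    def test_noise_free_synthetic_helix_recovery(self):
        pts = make_helix(12)
        frame = frame_from_points(pts)
        cm = contact_map(distance_map(frame), ContactCriterion.alpha())
        a = find_alpha_and_turn(cm, 0)
        # every residue with a valid (i, i+4) partner contributes
        assert a.count_alpha == 8
        assert a.count_beta_turn == 0
        assert 4 <= a.pace_helix <= 5
        assert helix_content(a, 12) == pytest.approx(100.0)

    def test_extended_chain_has_no_alpha_or_turn(self):
        chain = frame_from_points([[i * 3.8, 0, 0] for i in range(12)])
        cm = contact_map(distance_map(chain), ContactCriterion.alpha())
        a = find_alpha_and_turn(cm, 0)
        assert a.count_alpha == 0 and a.count_beta_turn == 0


class TestContentPercentages:
    def test_single_alpha_contact_spans_five_of_eight(self):
        a = find_alpha_and_turn(contacts_to_matrix([(0, 4)], 8))
        assert helix_content(a, 8) == pytest.approx(62.5)

    def test_no_contacts_zero_full_coverage_hundred(self):
        empty = find_alpha_and_turn(np.zeros((8, 8), dtype=np.uint8))
        assert helix_content(empty, 8) == 0.0
        full = find_alpha_and_turn(
            contacts_to_matrix([(0, 4), (1, 5), (2, 6), (3, 7)], 8)
        )
        assert helix_content(full, 8) == 100.0

    def test_turn_content_counts_turn_spans(self):
        a = find_alpha_and_turn(contacts_to_matrix([(0, 3)], 8))
        assert turn_content(a, 8) == pytest.approx(50.0)
        assert helix_content(a, 8) == 0.0


class TestReducedVectors:
    def _ladder_map(self, n_strands=3, strand_len=4, **kw):
        strands, _truth = make_sheet(n_strands, strand_len, **kw)
        frame = frame_from_points(*strands)
        return contact_map(distance_map(frame), ContactCriterion.beta())

    def test_antidiagonal_block_reduces_to_ones(self):
        cm = self._ladder_map(orientation="A", shift=0)
        assert np.array_equal(strand_pair_row_vector(cm, 0, 1), [1, 1, 1, 1])
        assert np.array_equal(strand_pair_col_vector(cm, 1, 2), [1, 1, 1, 1])

    def test_zero_block_zero_vector(self):
        cm = self._ladder_map()
        # strands 0 and 2 are 2 gaps apart: no contacts
        assert not strand_pair_row_vector(cm, 0, 2).any()

    def test_column_multiplicity_is_counted(self):
        block = np.zeros((4, 4), dtype=np.uint8)
        block[0, 2] = block[1, 2] = 1
        from conftest import two_molecule_map

        cm = two_molecule_map(block)
        assert np.array_equal(strand_pair_row_vector(cm, 0, 1), [0, 0, 2, 0])

    def test_projection_rules(self):
        assert triplet_projection([1, 1, 0, 0], [0, 0, 1, 1]) == 0
        assert triplet_projection([1, 1, 1, 1], [1, 1, 1, 1]) == 4
        assert triplet_projection([0, 0, 0, 0], [1, 2, 3, 4]) == 0
        with pytest.raises(ValueError):
            triplet_projection([1, 0], [1, 0, 0])

    def test_max_consecutive_run(self):
        assert max_consecutive_run([1, 1, 0, 1, 1, 1]) == 3
        assert max_consecutive_run([0, 0]) == 0
        assert max_consecutive_run([2, 1, 5]) == 3


class TestBetaSheetDomains:
    def _analyze(self, n_strands, strand_len=4, **kw):
        strands, truth = make_sheet(n_strands, strand_len, **kw)
        frame = frame_from_points(*strands)
        cm = contact_map(distance_map(frame), ContactCriterion.beta())
        lib = build_kernel_library(strand_len)
        P = alignment_matrix(cm, lib, min_contact=3)
        return beta_sheet_domains(P, cm), P, truth

    def test_three_strand_ladder_gives_one_triplet(self):
        domains, _P, _truth = self._analyze(3, orientation="A", shift=0)
        assert domains.triplets == ((0, 1, 2),)
        assert domains.pairs == ()
        assert domains.run_lengths[(0, 1, 2)] == 4

    def test_two_strands_give_one_pair(self):
        domains, _P, _truth = self._analyze(2, orientation="A", shift=0)
        assert domains.triplets == ()
        assert domains.pairs == ((0, 1),)
        assert domains.run_lengths[(0, 1)] == 4

    def test_empty_alignment_gives_no_domains(self, lib4):
        from conftest import two_molecule_map

        cm = two_molecule_map(np.zeros((4, 4), dtype=np.uint8))
        P = alignment_matrix(cm, lib4)
        domains = beta_sheet_domains(P, cm)
        assert domains.triplets == () and domains.pairs == ()

    @pytest.mark.parametrize("orientation", ["P", "A"])
    @pytest.mark.parametrize("shift", [0, 1, 2])
    def test_recovered_orientation_and_shift_match_generator(
        self, orientation, shift
    ):
        domains, P, truth = self._analyze(
            3, strand_len=8, orientation=orientation, shift=shift
        )
        for p, q, want_cls, want_shift in truth:
            got_cls, got_shift = P.classify(p, q)
            assert got_shift == want_shift
            if want_cls == "AP+" and want_shift == 0:
                assert got_cls in ("AP+", "AP-")
            else:
                assert got_cls == want_cls
        assert domains.triplets == ((0, 1, 2),)

    def test_molecule_permutation_permutes_output(self):
        strands, _ = make_sheet(2, 4, orientation="A", shift=0)
        far = np.array([[100.0 + 3.8 * i, 0, 0] for i in range(4)])
        lib = build_kernel_library(4)
        frame_a = frame_from_points(strands[0], strands[1], far)
        frame_b = frame_from_points(far, strands[0], strands[1])
        for frame, expected_pair in ((frame_a, (0, 1)), (frame_b, (1, 2))):
            cm = contact_map(distance_map(frame), ContactCriterion.beta())
            P = alignment_matrix(cm, lib, min_contact=3)
            domains = beta_sheet_domains(P, cm)
            assert domains.pairs == (expected_pair,)


class TestPeptidesInBetaFraction:
    def test_fraction_counts_unique_molecules(self):
        from ssmdscan.secstruct import BetaSheetDomains

        domains = BetaSheetDomains(
            triplets=((0, 1, 2),), pairs=(), run_lengths={}, pair_labels={}
        )
        assert peptides_in_beta_fraction(domains, 10) == pytest.approx(0.3)
        empty = BetaSheetDomains(
            triplets=(), pairs=(), run_lengths={}, pair_labels={}
        )
        assert peptides_in_beta_fraction(empty, 10) == 0.0
        full = BetaSheetDomains(
            triplets=((0, 1, 2),), pairs=((2, 3),), run_lengths={},
            pair_labels={},
        )
        assert peptides_in_beta_fraction(full, 4) == 1.0
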