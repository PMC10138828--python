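"""α-helix / β-turn assignment per molecule and β-sheet domains across
molecules.

α-helix and β-turn are read off the intramolecular α-criterion contact
map: every contact (i, j), j > i, is an α contact when the sequence
separation j − i is 4 or 5 (the helix pace window — one turn of an
α-helix spans ~3.6 residues, so the backbone centres that come within
the 5.1–6.3 Å band are the (i, i+4) pairs) and a β-turn contact
otherwise (a chain reversal bringing sequence-distant residues close).
Per molecule the routine tallies contact counts, the running mean
sequence separation of each class (helix pace, turn length) and the
residues covered.

β-sheets are read off the molecular alignment matrix ``P`` and the β
contact map: for each classified pair p < q the inter-molecular block
is reduced to a row vector (column sums); a second classified pair
q < s reduces to a column vector (row sums); a nonzero dot product
means the shared strand q couples both pairs on overlapping residues,
confirming a three-strand sheet.  Pairs that join no triplet remain
two-strand sheets.  The run length of a domain is the longest stretch
of consecutive nonzero entries of its defining pair's reduced vector —
the number of consecutive residues structured along the strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ssmdscan.alignment import AlignmentMatrix
from ssmdscan.contact_maps import ContactMap, molecule_block

HELIX_PACE_WINDOW = (4, 5)  # j - i values counted as α contacts


@dataclass(frozen=True)
class HelixTurnAssignment:
    """Per-molecule α-helix / β-turn tally from the α contact map."""

    count_alpha: int
    count_beta_turn: int
    pace_helix: float  # mean j−i of α contacts; 0 when none
    length_beta_turn: float  # mean j−i of turn contacts; 0 when none
    alpha_contact_list: tuple[tuple[int, int], ...]
    turn_contact_list: tuple[tuple[int, int], ...]
    helix_residues: frozenset[int]
    turn_residues: frozenset[int]


def intra_block(cm: ContactMap, m: int) -> np.ndarray:
    """Square intramolecular contact sub-matrix of molecule ``m``."""
    o = cm.index_offsets
    return cm.C[o[m]:o[m + 1], o[m]:o[m + 1]]


def find_alpha_and_turn(cm_alpha: np.ndarray | ContactMap,
                        molecule: int | None = None) -> HelixTurnAssignment:
    """Classify one molecule's α-criterion contacts into helix vs turn.

    Accepts either the molecule's square intramolecular contact matrix
    or a full :class:`ContactMap` plus a molecule index.  Scans i < j
    with a contact: j − i in the helix pace window {4, 5} → α contact,
    anything else → β-turn contact.  Means are accumulated
    incrementally; residues covered are the union of the inclusive
    spans [i, j] of each class's contacts.
    """
    if isinstance(cm_alpha, ContactMap):
        if molecule is None:
            raise ValueError("molecule index required with a full ContactMap")
        block = intra_block(cm_alpha, molecule)
    else:
        block = np.asarray(cm_alpha)
        if block.ndim != 2 or block.shape[0] != block.shape[1]:
            raise ValueError("intramolecular contact matrix must be square")

    count_a = count_b = 0
    pace = length = 0.0
    alpha_contacts: list[tuple[int, int]] = []
    turn_contacts: list[tuple[int, int]] = []
    helix_res: set[int] = set()
    turn_res: set[int] = set()
    lo, hi = HELIX_PACE_WINDOW
    ii, jj = np.nonzero(np.triu(block, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        sep = j - i
        if lo <= sep <= hi:
            count_a += 1
            pace += (sep - pace) / count_a
            alpha_contacts.append((i, j))
            helix_res.update(range(i, j + 1))
        else:
            count_b += 1
            length += (sep - length) / count_b
            turn_contacts.append((i, j))
            turn_res.update(range(i, j + 1))
    return HelixTurnAssignment(
        count_alpha=count_a,
        count_beta_turn=count_b,
        pace_helix=pace,
        length_beta_turn=length,
        alpha_contact_list=tuple(alpha_contacts),
        turn_contact_list=tuple(turn_contacts),
        helix_residues=frozenset(helix_res),
        turn_residues=frozenset(turn_res),
    )


def helix_content(assignment: HelixTurnAssignment, res: int) -> float:
    """Percentage of residues covered by α contacts (span union)."""
    if res < 1:
        raise ValueError("res must be >= 1")
    return 100.0 * len(assignment.helix_residues) / res


def turn_content(assignment: HelixTurnAssignment, res: int) -> float:
    """Percentage of residues covered by β-turn contacts (span union)."""
    if res < 1:
        raise ValueError("res must be >= 1")
    return 100.0 * len(assignment.turn_residues) / res


def strand_pair_row_vector(cm: ContactMap, p: int, q: int) -> np.ndarray:
    """Column sums of the (p, q) block: per-residue-of-q contact tally."""
    return molecule_block(cm, p, q).sum(axis=0).astype(np.int64)


def strand_pair_col_vector(cm: ContactMap, q: int, s: int) -> np.ndarray:
    """Row sums of the (q, s) block: per-residue-of-q contact tally."""
    return molecule_block(cm, q, s).sum(axis=1).astype(np.int64)


def triplet_projection(v_r: np.ndarray, v_c: np.ndarray) -> int:
    """Dot product of the two reduced vectors; nonzero confirms a triplet."""
    v_r = np.asarray(v_r)
    v_c = np.asarray(v_c)
    if v_r.shape != v_c.shape:
        raise ValueError(f"length mismatch: {v_r.shape} vs {v_c.shape}")
    return int(v_r @ v_c)


def max_consecutive_run(v: np.ndarray) -> int:
    """Longest run of consecutive nonzero elements."""
    best = cur = 0
    for x in np.asarray(v).ravel():
        if x:
            cur += 1
            best = max(best, cur)
        else:
            cur = 0
    return best


@dataclass(frozen=True)
class BetaSheetDomains:
    """β-sheet domains of one frame: strand triplets and residual pairs."""

    triplets: tuple[tuple[int, int, int], ...]
    pairs: tuple[tuple[int, int], ...]
    run_lengths: dict[tuple[int, ...], int] = field(repr=False)
    pair_labels: dict[tuple[int, int], tuple[str, int]] = field(repr=False)

    def molecules(self) -> frozenset[int]:
        out: set[int] = set()
        for t in self.triplets:
            out.update(t)
        for p in self.pairs:
            out.update(p)
        return frozenset(out)


def beta_sheet_domains(P: AlignmentMatrix, cm: ContactMap) -> BetaSheetDomains:
    """Detect strand triplets and two-strand sheets from P and the β map.

    For every classified p < q and every classified q < s, a nonzero
    projection of the (p, q) row vector onto the (q, s) column vector
    emits the triplet (p, q, s); classified pairs not absorbed into any
    triplet are reported as two-strand sheets.  Run lengths come from
    the defining pair's reduced row vector.
    """
    classified = P.classified_pairs()
    triplets: list[tuple[int, int, int]] = []
    run_lengths: dict[tuple[int, ...], int] = {}
    pair_labels: dict[tuple[int, int], tuple[str, int]] = {}
    for p, q in classified:
        pair_labels[(p, q)] = P.classify(p, q)
    classified_set = set(classified)
    nmol = P.n_molecules
    for p, q in classified:
        v_r = strand_pair_row_vector(cm, p, q)
        for s in range(q + 1, nmol):
            if (q, s) not in classified_set:
                continue
            v_c = strand_pair_col_vector(cm, q, s)
            if triplet_projection(v_r, v_c) != 0:
                triplets.append((p, q, s))
                run_lengths[(p, q, s)] = max_consecutive_run(v_r)
    in_triplet = {frozenset(pair) for t in triplets
                  for pair in ((t[0], t[1]), (t[1], t[2]), (t[0], t[2]))}
    pairs = [
        (p, q) for p, q in classified if frozenset((p, q)) not in in_triplet
    ]
    for p, q in pairs:
        run_lengths[(p, q)] = max_consecutive_run(
            strand_pair_row_vector(cm, p, q)
        )
    return BetaSheetDomains(
        triplets=tuple(triplets),
        pairs=tuple(pairs),
        run_lengths=run_lengths,
        pair_labels=pair_labels,
    )


def peptides_in_beta_fraction(domains: BetaSheetDomains, nmol: int) -> float:
    """Fraction of molecules participating in any β-sheet domain."""
    if nmol < 1:
        raise ValueError("nmol must be >= 1")
    return len(domains.molecules()) / nmol
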