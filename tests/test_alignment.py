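"""NCC classification, alignment matrix, interaction graph and clusters."""

import numpy as np
import pytest

from conftest import two_molecule_map
from ssmdscan.alignment import (
    alignment_matrix,
    cluster_majority_orientation,
    contact_graph,
    ncc,
    write_alignment_tsv,
    write_graph_tsv,
)
from ssmdscan.kernels import build_kernel_library


def exhaustive_best_kernel(block, lib):
    """Independent argmax: score every kernel with an explicit loop."""
    best_k, best_score = None, 0.0
    for k in range(len(lib)):
        kern = lib[k].astype(float)
        sb, sk = float(block.sum()), float(kern.sum())
        score = 0.0 if sb == 0 or sk == 0 else (
            float((block * kern).sum()) / np.sqrt(sb * sk)
        )
        if score > best_score:
            best_k, best_score = k, score
    return best_k


class TestNcc:
    def test_perfect_match_scores_one(self, lib8):
        for k in (0, 5, 11, 17, 23, 30):
            assert ncc(lib8[k], lib8[k]) == pytest.approx(1.0)

    def test_zero_conventions(self, lib8):
        zero = np.zeros((8, 8))
        assert ncc(zero, lib8[0]) == 0.0
        assert ncc(lib8[0], np.zeros((8, 8))) == 0.0
        # disjoint supports: identity block vs anti-diagonal kernel (even RES)
        assert ncc(np.eye(8), lib8[2 * 8]) == 0.0

    def test_shape_mismatch_rejected(self, lib8):
        with pytest.raises(ValueError, match="shape"):
            ncc(np.zeros((4, 4)), lib8[0])

    def test_partial_overlap_value(self):
        block = np.zeros((4, 4))
        block[0, 0] = block[1, 1] = 1  # half the identity kernel
        assert ncc(block, np.eye(4)) == pytest.approx(2 / np.sqrt(2 * 4))


class TestAlignmentMatrix:
    def test_self_recovery_every_kernel(self, lib8):
        """A block equal to kernel k is classified with k's class and shift.

        At shift 0 both parallel kernels are the identity and both
        antiparallel kernels are the anti-diagonal; those pairs are one
        equivalence class, and the tie resolves to the lower index.
        """
        for k in range(len(lib8)):
            cm = two_molecule_map(lib8[k])
            P = alignment_matrix(cm, lib8, min_contact=1)
            won = P.kernel_index(0, 1)
            assert np.array_equal(lib8[won], lib8[k])
            want_cls, want_shift = lib8.report_class(k)
            got_cls, got_shift = P.classify(0, 1)
            assert got_shift == want_shift
            if want_shift == 0:
                assert got_cls[0] == want_cls[0]  # P vs AP family preserved
            else:
                assert got_cls == want_cls

    def test_matches_exhaustive_scoring_on_random_blocks(self, lib8):
        rng = np.random.default_rng(42)
        for _ in range(100):
            block = (rng.random((8, 8)) < 0.25).astype(np.uint8)
            cm = two_molecule_map(block)
            P = alignment_matrix(cm, lib8, min_contact=1)
            expected = exhaustive_best_kernel(block.astype(float), lib8)
            if block.sum() == 0 or expected is None:
                assert P.kernel_index(0, 1) is None
            else:
                assert P.kernel_index(0, 1) == expected

    def test_min_contact_threshold(self, lib8):
        block = np.zeros((8, 8), dtype=np.uint8)
        block[0, 0] = 1
        cm = two_molecule_map(block)
        assert alignment_matrix(cm, lib8, min_contact=3).kernel_index(0, 1) is None
        # below threshold the pair stays unclassified; at min_contact=1 the
        # lone (0,0) contact matches best the kernel that is exactly that
        # point: antiparallel-negative at full shift (i + j = 0)
        assert alignment_matrix(cm, lib8, min_contact=1).kernel_index(0, 1) == 31

    def test_empty_map_gives_all_zero_matrix(self, lib8):
        cm = two_molecule_map(np.zeros((8, 8), dtype=np.uint8))
        P = alignment_matrix(cm, lib8)
        assert not P.P.any()
        assert P.classified_pairs() == []

    def test_single_bit_flip_keeps_orientation(self, lib8):
        """Deleting or adding one contact must not change the P/AP call."""
        rng = np.random.default_rng(5)
        for k in range(len(lib8)):
            if lib8[k].sum() < 4:
                continue
            want_cls, _ = lib8.report_class(k)
            for flip_to in (0, 1):
                block = lib8[k].copy()
                targets = np.argwhere(block != flip_to)
                i, j = targets[rng.integers(len(targets))]
                block[i, j] = flip_to
                P = alignment_matrix(two_molecule_map(block), lib8,
                                     min_contact=1)
                got_cls, _ = P.classify(0, 1)
                assert got_cls[0] == want_cls[0], f"kernel {k} flip {flip_to}"

    def test_unequal_molecule_lengths_rejected(self, lib8):
        from ssmdscan.contact_maps import ContactCriterion, ContactMap

        cm = ContactMap(
            C=np.zeros((10, 10), dtype=np.uint8),
            criterion=ContactCriterion.beta(),
            index_offsets=np.array([0, 4, 10]),
            molecule_lengths=(4, 6),
        )
        with pytest.raises(ValueError, match="length"):
            alignment_matrix(cm, lib8)


def union_find_components(n, edges):
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    comps = {}
    for v in range(n):
        comps.setdefault(find(v), []).append(v)
    return sorted(tuple(sorted(c)) for c in comps.values())


class TestContactGraph:
    def _graph_from_blocks(self, lib, pairs, nmol, res=4):
        """Build a contact map with given kernel-shaped blocks and classify."""
        n = nmol * res
        C = np.zeros((n, n), dtype=np.uint8)
        for p, q, k in pairs:
            C[p * res:(p + 1) * res, q * res:(q + 1) * res] = lib[k]
            C[q * res:(q + 1) * res, p * res:(p + 1) * res] = lib[k].T
        from ssmdscan.contact_maps import ContactCriterion, ContactMap

        cm = ContactMap(
            C=C,
            criterion=ContactCriterion.beta(),
            index_offsets=np.arange(0, n + 1, res),
            molecule_lengths=(res,) * nmol,
        )
        return cm, alignment_matrix(cm, lib, min_contact=1)

    def test_sheet_chain_forms_one_cluster(self, lib4):
        cm, P = self._graph_from_blocks(lib4, [(0, 1, 8), (1, 2, 8)], 4)
        g = contact_graph(P, cm)
        assert g.clusters == ((0, 1, 2), (3,))

    def test_components_match_union_find_on_random_graphs(self, lib4):
        rng = np.random.default_rng(11)
        for _ in range(100):
            nmol = int(rng.integers(2, 31))
            n_edges = int(rng.integers(0, nmol))
            pairs = set()
            while len(pairs) < n_edges:
                a, b = rng.integers(0, nmol, 2)
                if a != b:
                    pairs.add((min(a, b), max(a, b)))
            cm, P = self._graph_from_blocks(
                lib4, [(p, q, 8) for p, q in pairs], nmol
            )
            g = contact_graph(P, cm)
            assert sorted(g.clusters) == union_find_components(nmol, pairs)

    def test_edge_weights_and_networkx_export(self, lib4):
        cm, P = self._graph_from_blocks(lib4, [(0, 1, 8)], 2)
        g = contact_graph(P, cm)
        assert g.edges == ((0, 1, 4, "AP+", 0),)
        nxg = g.to_networkx()
        assert nxg.edges[0, 1]["n_contacts"] == 4

    def test_majority_orientation_labels(self, lib4):
        # AP edge with 4 contacts + P edge with 3 contacts -> AP majority
        cm, P = self._graph_from_blocks(lib4, [(0, 1, 8), (1, 2, 1)], 3)
        g = contact_graph(P, cm)
        assert cluster_majority_orientation(g) == ["AP"]
        # single-edge cluster takes that edge's label; isolated node "none"
        cm, P = self._graph_from_blocks(lib4, [(0, 1, 0)], 3)
        g = contact_graph(P, cm)
        assert cluster_majority_orientation(g) == ["P", "none"]
        # tie: one AP and one P edge with equal contact counts
        cm, P = self._graph_from_blocks(lib4, [(0, 1, 8)], 3)
        g = contact_graph(P, cm)
        from ssmdscan.alignment import ContactGraph

        tie = ContactGraph(n_molecules=3,
                           edges=g.edges + ((1, 2, 4, "P", 0),),
                           clusters=((0, 1, 2),))
        assert cluster_majority_orientation(tie) == ["mixed"]


def test_tsv_exports(tmp_path, lib4):
    block = lib4[8]
    cm = two_molecule_map(block)
    P = alignment_matrix(cm, lib4, min_contact=1)
    write_alignment_tsv(P, tmp_path / "P.tsv")
    rows = (tmp_path / "P.tsv").read_text().strip().splitlines()
    assert rows[0].split("\t") == ["-1", "8"]
    g = contact_graph(P, cm)
    write_graph_tsv(g, tmp_path / "g.tsv")
    assert "0\t1\t4\tAP+\t0" in (tmp_path / "g.tsv").read_text()
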