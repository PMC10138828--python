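"""Strand-pair classification by normalized cross-correlation and the
per-frame molecular interaction graph.

For every ordered molecule pair (p, q) the inter-molecular block ``BB``
of the β contact map is scored against each kernel ``L_k`` of the shift
library with the normalized cross-correlation

    NCC(p, q, k) = Σ_ij BB_ij · L_ijk / sqrt(Σ_ij BB_ij · Σ_ij L_ijk)

i.e. the overlap normalized by the geometric mean of the two matrices'
mass (for binary matrices this is the cosine similarity of the
flattened templates, the standard zero-offset NCC; it is 1 exactly
when block and kernel coincide).  Normalizing by the plain product of
the sums instead would let any single-entry kernel contained in the
block tie or beat the full-size match, so kernel size must enter the
denominator at the square root.  The score is 0-guarded for empty
blocks or kernels.  The winning kernel index is the argmax over k
(ties resolve to the lowest index), recorded in the
molecular alignment matrix ``P``; pairs with fewer than ``min_contact``
contacts, or with no overlapping kernel at all, stay unclassified.
Classified pairs become edges of an undirected interaction graph whose
connected components (found by depth-first search) are the molecular
aggregates of the frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ssmdscan.contact_maps import ContactMap, molecule_block
from ssmdscan.kernels import REPORT_CLASS, KernelLibrary

MIN_CONTACT_DEFAULT = 3


@dataclass(frozen=True)
class AlignmentMatrix:
    """nmol × nmol matrix of winning kernel indices per molecule pair.

    ``P`` stores the winning kernel index **plus one**; 0 means "no
    classified interaction".  (Kernel index 0 is itself a valid kernel
    — parallel in-register — so a sentinel shift removes the ambiguity;
    exports report plain kernel indices.)
    """

    P: np.ndarray = field(repr=False)  # int matrix, 0 = none, else k+1
    res: int
    min_contact: int

    @property
    def n_molecules(self) -> int:
        return self.P.shape[0]

    def kernel_index(self, p: int, q: int) -> int | None:
        """Winning kernel index for the ordered pair, or None."""
        v = int(self.P[p, q])
        return v - 1 if v else None

    def classify(self, p: int, q: int) -> tuple[str, int] | None:
        """(reporting class "P"/"AP+"/"AP-", shift) for the pair, or None."""
        k = self.kernel_index(p, q)
        if k is None:
            return None
        family = ("P+", "P-", "A+", "A-")[k // self.res]
        return REPORT_CLASS[family], k % self.res

    def classified_pairs(self) -> list[tuple[int, int]]:
        """Ordered pairs (p, q), p < q, with a classified interaction."""
        ii, jj = np.nonzero(np.triu(self.P, k=1))
        return list(zip(ii.tolist(), jj.tolist()))


def ncc(block: np.ndarray, kernel: np.ndarray) -> float:
    """Normalized cross-correlation of a contact block with one kernel.

    ``overlap / sqrt(Σblock · Σkernel)``; 1.0 for a perfect match,
    0 when either matrix is all-zero or the supports are disjoint.
    """
    block = np.asarray(block)
    kernel = np.asarray(kernel)
    if block.shape != kernel.shape:
        raise ValueError(
            f"shape mismatch: block {block.shape} vs kernel {kernel.shape}"
        )
    sb = float(block.sum())
    sk = float(kernel.sum())
    if sb == 0.0 or sk == 0.0:
        return 0.0
    return float((block * kernel).sum()) / np.sqrt(sb * sk)


def alignment_matrix(
    cm: ContactMap,
    lib: KernelLibrary,
    min_contact: int = MIN_CONTACT_DEFAULT,
) -> AlignmentMatrix:
    """Classify every ordered molecule pair against the kernel library.

    A pair is classified only if its block carries at least
    ``min_contact`` contacts and at least one kernel overlaps it; ties
    in the NCC argmax resolve to the lowest kernel index.
    """
    lengths = set(cm.molecule_lengths)
    if len(lengths) > 1:
        raise ValueError(
            f"molecules differ in length ({sorted(lengths)}); kernel "
            "matching requires equal-length molecules"
        )
    res = cm.molecule_lengths[0]
    if res != lib.res:
        raise ValueError(f"library res {lib.res} != molecule length {res}")
    nmol = cm.n_molecules
    P = np.zeros((nmol, nmol), dtype=np.int64)
    kernel_sums = lib.stack.reshape(len(lib), -1).sum(axis=1).astype(float)
    flat_kernels = lib.stack.reshape(len(lib), -1).astype(float)
    for p in range(nmol):
        for q in range(nmol):
            if p == q:
                continue
            block = molecule_block(cm, p, q).astype(float)
            sb = block.sum()
            if sb < min_contact:
                continue
            overlaps = flat_kernels @ block.ravel()
            scores = overlaps / np.sqrt(sb * kernel_sums)
            k = int(np.argmax(scores))  # argmax takes the lowest index on ties
            if scores[k] > 0.0:
                P[p, q] = k + 1
    return AlignmentMatrix(P=P, res=res, min_contact=min_contact)


@dataclass(frozen=True)
class ContactGraph:
    """Per-frame molecular interaction graph and its aggregates.

    edges: (p, q, n_contacts, reporting class, shift) for p < q;
    clusters: connected components as sorted tuples of molecule indices.
    """

    n_molecules: int
    edges: tuple[tuple[int, int, int, str, int], ...]
    clusters: tuple[tuple[int, ...], ...]

    def to_networkx(self):
        """The same graph as a networkx.Graph (for plotting/custom analysis)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_molecules))
        for p, q, w, cls, shift in self.edges:
            g.add_edge(p, q, n_contacts=w, orientation=cls, shift=shift)
        return g


def _dfs_components(n_nodes: int, adjacency: dict[int, list[int]]
                    ) -> list[tuple[int, ...]]:
    """Connected components by iterative depth-first search."""
    seen = [False] * n_nodes
    components = []
    for start in range(n_nodes):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adjacency.get(u, ()):
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        components.append(tuple(sorted(comp)))
    return components


def contact_graph(P: AlignmentMatrix, cm: ContactMap) -> ContactGraph:
    """Build the interaction graph from classified pairs.

    Each undirected edge joins a pair with ``P[p][q] != 0``; the weight
    is the pair's inter-molecular contact count and the label comes
    from the winning kernel.  Clusters are DFS connected components.
    """
    edges = []
    adjacency: dict[int, list[int]] = {}
    for p, q in P.classified_pairs():
        n_contacts = int(molecule_block(cm, p, q).sum())
        cls, shift = P.classify(p, q)
        edges.append((p, q, n_contacts, cls, shift))
        adjacency.setdefault(p, []).append(q)
        adjacency.setdefault(q, []).append(p)
    clusters = _dfs_components(P.n_molecules, adjacency)
    return ContactGraph(
        n_molecules=P.n_molecules,
        edges=tuple(edges),
        clusters=tuple(clusters),
    )


def cluster_majority_orientation(graph: ContactGraph) -> list[str]:
    """Label each cluster P or AP by majority of its edge contact counts.

    Ties are "mixed"; clusters without edges (isolated molecules) are
    "none".
    """
    labels = []
    for comp in graph.clusters:
        members = set(comp)
        ap = 0
        par = 0
        for p, q, w, cls, _shift in graph.edges:
            if p in members:
                if cls.startswith("AP"):
                    ap += w
                else:
                    par += w
        if ap == 0 and par == 0:
            labels.append("none")
        elif ap > par:
            labels.append("AP")
        elif par > ap:
            labels.append("P")
        else:
            labels.append("mixed")
    return labels


def write_alignment_tsv(P: AlignmentMatrix, path: str | Path) -> None:
    """Export the alignment matrix as TSV of plain kernel indices.

    Unclassified pairs are written as -1 (kernel 0 is a valid kernel).
    """
    out = np.where(P.P > 0, P.P - 1, -1)
    np.savetxt(path, out, fmt="%d", delimiter="\t")


def write_graph_tsv(graph: ContactGraph, path: str | Path) -> None:
    """Export edges as TSV: p, q, n_contacts, orientation, shift."""
    with open(path, "w") as fh:
        fh.write("p\tq\tn_contacts\torientation\tshift\n")
        for p, q, w, cls, shift in graph.edges:
            fh.write(f"{p}\t{q}\t{w}\t{cls}\t{shift}\n")
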