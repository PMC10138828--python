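"""Distance maps and criterion-specific binary contact maps.

A frame's selected points (one per residue: the MARTINI BB bead or the
Cα / backbone centre of mass) are flattened in molecule order.  The
distance map ``D`` holds all pairwise Euclidean distances in Å.  A
contact criterion turns it into a binary contact map:

* ``beta``  — ``C[i, j] = 1`` iff ``D[i, j] <= d0`` (default 5.3 Å, the
  upper end of the 4.7–5.3 Å inter-strand spacing window of cross-β
  packing).
* ``alpha`` — ``C[i, j] = 1`` iff ``d_low <= D[i, j] <= d_high``
  (default band 5.1–6.3 Å, the backbone-centre distance range between
  residues of an α-helix) and both residues belong to the same
  molecule with sequence separation ``|i - j| >= min_sequence_separation``.

The diagonal is always 0.  β classification works on inter-molecular
blocks, so its sequence-separation default is 0; the α criterion is
strictly intramolecular.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ssmdscan.traj_io import SystemFrame

BETA_THRESHOLD_DEFAULT = 5.3  # Å, upper end of the 4.7-5.3 Å cross-β window
ALPHA_BAND_DEFAULT = (5.1, 6.3)  # Å
# |i-j| >= 3: separations of 2 fall inside the α band even in an ideal
# helix (d(i,i+2) ≈ 5.4 Å), which would miscount helical residues as turns.
ALPHA_MIN_SEPARATION_DEFAULT = 3


@dataclass(frozen=True)
class DistanceMap:
    """Symmetric pairwise distance matrix over a frame's points (Å)."""

    D: np.ndarray = field(repr=False)
    index_offsets: np.ndarray = field(repr=False)  # len nmol+1, point offsets
    molecule_lengths: tuple[int, ...]

    @property
    def n_points(self) -> int:
        return self.D.shape[0]

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_lengths)

    def molecule_of(self, i: int) -> int:
        """Molecule index owning flat point index ``i``."""
        return int(np.searchsorted(self.index_offsets, i, side="right") - 1)


@dataclass(frozen=True)
class ContactCriterion:
    """Distance rule that converts a DistanceMap into a ContactMap.

    kind="beta": single threshold ``d0``; kind="alpha": closed band
    ``(d_low, d_high)`` applied intramolecularly only.
    """

    kind: str  # "beta" | "alpha"
    d0: float | tuple[float, float]
    min_sequence_separation: int = 0

    def __post_init__(self):
        if self.kind == "beta":
            if not np.isscalar(self.d0) or self.d0 <= 0:
                raise ValueError("beta criterion needs a positive scalar d0")
        elif self.kind == "alpha":
            lo, hi = self.d0
            if not 0 < lo < hi:
                raise ValueError("alpha criterion needs 0 < d_low < d_high")
        else:
            raise ValueError(f"unknown criterion kind {self.kind!r}")

    @classmethod
    def beta(cls, d0: float = BETA_THRESHOLD_DEFAULT,
             min_sequence_separation: int = 0) -> "ContactCriterion":
        return cls("beta", d0, min_sequence_separation)

    @classmethod
    def alpha(cls, band: tuple[float, float] = ALPHA_BAND_DEFAULT,
              min_sequence_separation: int = ALPHA_MIN_SEPARATION_DEFAULT,
              ) -> "ContactCriterion":
        return cls("alpha", tuple(band), min_sequence_separation)


@dataclass(frozen=True)
class ContactMap:
    """Binary symmetric contact matrix plus the criterion that made it."""

    C: np.ndarray = field(repr=False)  # uint8, zero diagonal
    criterion: ContactCriterion
    index_offsets: np.ndarray = field(repr=False)
    molecule_lengths: tuple[int, ...]
    D: np.ndarray | None = field(default=None, repr=False)  # distances, for export

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_lengths)

    def n_contacts(self) -> int:
        """Number of unordered contact pairs."""
        return int(self.C.sum()) // 2


def distance_map(frame: SystemFrame) -> DistanceMap:
    """All-vs-all Euclidean distance matrix of a frame's points (Å)."""
    points = frame.stacked()
    if points.shape[0] < 1:
        raise ValueError("frame has no points")
    bad = ~np.isfinite(points).all(axis=1)
    if bad.any():
        flat = int(np.flatnonzero(bad)[0])
        offsets = frame.index_offsets()
        m = int(np.searchsorted(offsets, flat, side="right") - 1)
        raise ValueError(
            f"non-finite coordinate at molecule {m}, residue {flat - offsets[m]}"
        )
    D = squareform(pdist(points))
    return DistanceMap(
        D=D,
        index_offsets=frame.index_offsets(),
        molecule_lengths=tuple(frame.molecule_lengths),
    )


def _same_molecule_mask(offsets: np.ndarray) -> np.ndarray:
    owner = np.repeat(np.arange(len(offsets) - 1), np.diff(offsets))
    return owner[:, None] == owner[None, :]


def contact_map(dm: DistanceMap, criterion: ContactCriterion) -> ContactMap:
    """Apply a contact criterion to a distance map.

    β: ``D <= d0`` everywhere (inter- and intramolecular), optional
    sequence-separation gate within a molecule.  α: distance within the
    closed band, same molecule only, ``|i - j| >= min_sequence_separation``.
    """
    D = dm.D
    n = D.shape[0]
    same_mol = _same_molecule_mask(dm.index_offsets)
    idx = np.arange(n)
    # residue index within its own molecule
    local = idx - dm.index_offsets[:-1][
        np.searchsorted(dm.index_offsets, idx, side="right") - 1
    ]
    sep = np.abs(local[:, None] - local[None, :])

    if criterion.kind == "beta":
        C = D <= criterion.d0
        if criterion.min_sequence_separation > 0:
            C &= ~(same_mol & (sep < criterion.min_sequence_separation))
    else:
        lo, hi = criterion.d0
        C = (D >= lo) & (D <= hi)
        C &= same_mol
        C &= sep >= criterion.min_sequence_separation
    np.fill_diagonal(C, False)
    return ContactMap(
        C=C.astype(np.uint8),
        criterion=criterion,
        index_offsets=dm.index_offsets,
        molecule_lengths=dm.molecule_lengths,
        D=D,
    )


def molecule_block(cm: ContactMap, p: int, q: int) -> np.ndarray:
    """Inter-molecular RES×RES sub-matrix: rows = residues of p, cols = q.

    Both molecules must have the same length (kernel matching operates
    on square blocks); ``block(p, q) == block(q, p).T``.
    """
    if p == q:
        raise ValueError("molecule_block requires two distinct molecules")
    lp = cm.molecule_lengths[p]
    lq = cm.molecule_lengths[q]
    if lp != lq:
        raise ValueError(
            f"molecules {p} (len {lp}) and {q} (len {lq}) differ in length; "
            "kernel matching requires square blocks"
        )
    o = cm.index_offsets
    return cm.C[o[p]:o[p + 1], o[q]:o[q + 1]]


def write_edge_list(cm: ContactMap, path: str | Path) -> None:
    """Export contacts as a TSV edge list ``i<TAB>j<TAB>distance``."""
    ii, jj = np.nonzero(np.triu(cm.C, k=1))
    with open(path, "w") as fh:
        fh.write("i\tj\tdistance\n")
        for i, j in zip(ii.tolist(), jj.tolist()):
            d = float(cm.D[i, j]) if cm.D is not None else float("nan")
            fh.write(f"{i}\t{j}\t{d:.6g}\n")
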