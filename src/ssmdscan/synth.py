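"""Synthetic backbone generators with ground-truth secondary structure.

Every detection algorithm in this package is testable closed-loop
against geometry built here: ideal α-helix backbones, β-sheet ladders
with controlled orientation and register shift, and self-avoiding
random coils, optionally perturbed by Gaussian positional noise.

Helix defaults (radius 2.3 Å, rise 1.5 Å/residue, twist 100°/residue)
reproduce the Cα geometry of an ideal α-helix, whose (i, i+4) distance
of ≈ 6.20 Å falls inside the 5.1–6.3 Å α-contact band.  Sheet defaults
(intra-strand step 3.5 Å, inter-strand gap 4.8 Å) put matched residues
of adjacent strands inside the 4.7–5.3 Å cross-β window while the
nearest off-register pair (√(3.5² + 4.8²) ≈ 5.94 Å) stays outside it,
so a noise-free ladder's contact block is exactly one shift kernel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ssmdscan.traj_io import SystemFrame, write_frames_pdb

HELIX_RADIUS = 2.3  # Å
HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = 100.0  # degrees per residue
SHEET_STEP = 3.5  # Å intra-strand residue spacing
SHEET_GAP = 4.8  # Å inter-strand spacing (inside the 4.7-5.3 Å window)
COIL_STEP = 3.8  # Å, trans Cα-Cα virtual bond
COIL_MIN_APPROACH = 4.0  # Å self-avoidance radius
GROUP_SPACING = 20.0  # Å clearance between placed molecules/groups


def _rng(seed, rng=None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(seed)


def make_helix(
    n: int,
    radius: float = HELIX_RADIUS,
    rise: float = HELIX_RISE,
    twist: float = HELIX_TWIST,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Points on an ideal helical curve, optionally with Gaussian noise."""
    if n < 2:
        raise ValueError("helix needs at least 2 residues")
    i = np.arange(n)
    theta = np.deg2rad(i * twist)
    pts = np.column_stack(
        (radius * np.cos(theta), radius * np.sin(theta), i * rise)
    )
    if noise_sigma > 0:
        pts = pts + _rng(seed, rng).normal(0.0, noise_sigma, pts.shape)
    return pts


def helix_chord_distance(m: int, radius: float = HELIX_RADIUS,
                         rise: float = HELIX_RISE,
                         twist: float = HELIX_TWIST) -> float:
    """Closed-form d(i, i+m) of the noise-free helix (chord + rise)."""
    chord = 2.0 * radius * abs(np.sin(np.deg2rad(m * twist) / 2.0))
    return float(np.hypot(chord, m * rise))


def make_sheet(
    n_strands: int,
    strand_len: int,
    step: float = SHEET_STEP,
    gap: float = SHEET_GAP,
    orientation: str = "A",
    shift: int = 0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[np.ndarray], list[tuple[int, int, str, int]]]:
    """β-sheet ladder: straight strands along x stacked along y.

    Every adjacent strand pair takes the same ``orientation`` ("P"
    parallel, "A" antiparallel) and register ``shift``.  Returns the
    per-strand coordinates and the ground-truth labels
    ``(p, q, reporting class, shift)`` per adjacent pair, where the
    reporting class is "P" or "AP+" (the positive-shift antiparallel
    family: residue i of p faces residue n + shift − i of q).
    """
    if orientation not in ("P", "A"):
        raise ValueError("orientation must be 'P' or 'A'")
    if not 0 <= shift < strand_len:
        raise ValueError("shift must satisfy 0 <= shift < strand_len")
    if gap <= 0:
        raise ValueError("inter-strand gap must be positive")
    n = strand_len - 1
    strands = []
    truth = []
    a, b = 0.0, 1.0  # x(j) = a + b * j * step for the current strand
    for t in range(n_strands):
        j = np.arange(strand_len)
        x = a + b * j * step
        pts = np.column_stack((x, np.full(strand_len, t * gap),
                               np.zeros(strand_len)))
        strands.append(pts)
        if t + 1 < n_strands:
            if orientation == "P":
                a, b = a - b * shift * step, b
                truth.append((t, t + 1, "P", shift))
            else:
                a, b = a + b * (n + shift) * step, -b
                truth.append((t, t + 1, "AP+", shift))
    if noise_sigma > 0:
        r = _rng(seed, rng)
        strands = [s + r.normal(0.0, noise_sigma, s.shape) for s in strands]
    return strands, truth


def make_coil(
    n: int,
    step: float = COIL_STEP,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    min_approach: float = COIL_MIN_APPROACH,
    max_tries: int = 200,
) -> np.ndarray:
    """Fixed-step self-avoiding random walk (resampled on close approach)."""
    if n < 2:
        raise ValueError("coil needs at least 2 residues")
    r = _rng(seed, rng)
    for _attempt in range(100):
        pts = [np.zeros(3)]
        ok = True
        while len(pts) < n:
            placed = False
            for _ in range(max_tries):
                v = r.normal(size=3)
                v *= step / np.linalg.norm(v)
                cand = pts[-1] + v
                prior = np.array(pts[:-1]) if len(pts) > 1 else None
                if prior is None or (
                    np.linalg.norm(prior - cand, axis=1) >= min_approach
                ).all():
                    pts.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(pts)
    raise RuntimeError("self-avoiding walk failed to place all residues")


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a synthetic multi-molecule system.

    ``motifs`` assigns each molecule a motif in {"helix", "strand",
    "coil"}; ``sheet_topology`` lists ``(p, q, orientation, shift)``
    for strand pairs (q is placed adjacent to p, which must itself be a
    strand already placed).  Molecules not in any sheet are laid out
    with ≥ 20 Å clearance.
    """

    n_molecules: int
    residues_per_molecule: int
    motifs: tuple[str, ...]
    sheet_topology: tuple[tuple[int, int, str, int], ...] = ()
    helix_radius: float = HELIX_RADIUS
    helix_rise: float = HELIX_RISE
    helix_twist: float = HELIX_TWIST
    sheet_step: float = SHEET_STEP
    sheet_gap: float = SHEET_GAP
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.motifs) != self.n_molecules:
            raise ValueError("one motif per molecule required")
        for p, q, orientation, shift in self.sheet_topology:
            if self.motifs[p] != "strand" or self.motifs[q] != "strand":
                raise ValueError("sheet topology refers to non-strand motifs")
            if not 0 <= shift < self.residues_per_molecule:
                raise ValueError("register shift exceeds strand length")
            if orientation not in ("P", "A"):
                raise ValueError("orientation must be 'P' or 'A'")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator built, for closed-loop verification."""

    motifs: tuple[str, ...]
    pair_labels: dict[tuple[int, int], tuple[str, int]] = field(
        default_factory=dict
    )


def make_system(spec: SynthSpec) -> tuple[SystemFrame, GroundTruth]:
    """Assemble one frame from a :class:`SynthSpec`.

    Sheet strands are positioned by the pair topology; all remaining
    molecules (and each disconnected sheet group) are translated apart
    along x with ≥ 20 Å clearance.
    """
    rng = np.random.default_rng(spec.seed)
    res = spec.residues_per_molecule
    n = res - 1
    coords: dict[int, np.ndarray] = {}
    pair_labels: dict[tuple[int, int], tuple[str, int]] = {}

    # affine x-maps (a, b) and row (y) per placed strand, per sheet group
    placed_sheet: dict[int, tuple[float, float, float]] = {}
    group_of: dict[int, int] = {}
    next_group = 0
    for p, q, orientation, shift in spec.sheet_topology:
        if p not in placed_sheet:
            placed_sheet[p] = (0.0, 1.0, 0.0)
            group_of[p] = next_group
            next_group += 1
        if q in placed_sheet:
            raise ValueError(f"strand {q} placed twice in sheet topology")
        a, b, y = placed_sheet[p]
        if orientation == "P":
            placed_sheet[q] = (a - b * shift * spec.sheet_step, b,
                               y + spec.sheet_gap)
            pair_labels[(p, q)] = ("P", shift)
        else:
            placed_sheet[q] = (a + b * (n + shift) * spec.sheet_step, -b,
                               y + spec.sheet_gap)
            pair_labels[(p, q)] = ("AP+", shift)
        group_of[q] = group_of[p]

    for m, (a, b, y) in placed_sheet.items():
        j = np.arange(res)
        coords[m] = np.column_stack(
            (a + b * j * spec.sheet_step, np.full(res, y), np.zeros(res))
        )

    # group sheet members so each group moves as one rigid unit
    groups: list[list[int]] = [[] for _ in range(next_group)]
    for m, g in group_of.items():
        groups[g].append(m)
    units: list[list[int]] = [sorted(g) for g in groups]
    for m in range(spec.n_molecules):
        if m in coords:
            continue
        motif = spec.motifs[m]
        if motif == "helix":
            coords[m] = make_helix(
                res, spec.helix_radius, spec.helix_rise, spec.helix_twist,
                rng=rng, noise_sigma=0.0,
            )
        elif motif == "strand":
            j = np.arange(res)
            coords[m] = np.column_stack(
                (j * spec.sheet_step, np.zeros(res), np.zeros(res))
            )
        elif motif == "coil":
            coords[m] = make_coil(res, rng=rng)
        else:
            raise ValueError(f"unknown motif {motif!r}")
        units.append([m])

    # lay units out along x with clearance
    x_cursor = 0.0
    for unit in units:
        pts = np.concatenate([coords[m] for m in unit])
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        offset = np.array([x_cursor - lo[0], -lo[1], -lo[2]])
        for m in unit:
            coords[m] = coords[m] + offset
        x_cursor += (hi[0] - lo[0]) + GROUP_SPACING

    if spec.noise_sigma > 0:
        for m in coords:
            coords[m] = coords[m] + rng.normal(
                0.0, spec.noise_sigma, coords[m].shape
            )

    frame = SystemFrame(
        frame_index=0,
        coordinates=tuple(coords[m] for m in range(spec.n_molecules)),
    )
    return frame, GroundTruth(motifs=spec.motifs, pair_labels=pair_labels)


def morph_frames(start: SystemFrame, end: SystemFrame,
                 n_frames: int) -> list[SystemFrame]:
    """Linear interpolation between two conformations of one system."""
    if start.molecule_lengths != end.molecule_lengths:
        raise ValueError("morph endpoints must share the molecule layout")
    if n_frames < 2:
        raise ValueError("a morph needs at least 2 frames")
    frames = []
    a = start.stacked()
    b = end.stacked()
    offsets = start.index_offsets()
    for t in range(n_frames):
        w = t / (n_frames - 1)
        flat = (1 - w) * a + w * b
        coords = tuple(
            flat[offsets[m]:offsets[m + 1]]
            for m in range(start.n_molecules)
        )
        frames.append(SystemFrame(frame_index=t, coordinates=coords))
    return frames


def write_system(
    frames: list[SystemFrame],
    truth: GroundTruth,
    pdb_path: str | Path,
    truth_path: str | Path | None = None,
) -> None:
    """Write frames as (multi-model) PDB plus a JSON ground-truth sidecar."""
    write_frames_pdb(frames, pdb_path)
    if truth_path is not None:
        payload = {
            "motifs": list(truth.motifs),
            "pair_labels": [
                {"p": p, "q": q, "orientation": cls, "shift": shift}
                for (p, q), (cls, shift) in sorted(truth.pair_labels.items())
            ],
        }
        Path(truth_path).write_text(json.dumps(payload, indent=2, sort_keys=True))
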