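"""Trajectory loading, backbone-point selection and frame sampling.

Structure/trajectory parsing is delegated to MDAnalysis, which reads
PDB and GRO configurations and XTC/TRR/DCD/multi-model-PDB trajectories
and already reports coordinates in Å (nm-based formats are converted on
read).  One *molecule* is a chain/segment: a new molecule starts
whenever the segment id changes or the residue numbering restarts.
Each selected point is the centre of mass of the residue's selected
atoms — a single bead under the MARTINI "BB" default, the Cα under the
atomistic "CA" selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

logger = logging.getLogger(__name__)

DEFAULT_SELECTION = "BB"


class EmptySelectionError(ValueError):
    """The atom-name selection matched no atoms in the topology."""


class FormatError(ValueError):
    """A structure or trajectory file could not be parsed."""


@dataclass(frozen=True)
class SystemFrame:
    """Per-molecule ordered backbone-point coordinates for one frame (Å)."""

    frame_index: int
    coordinates: tuple[np.ndarray, ...]  # one (n_res, 3) array per molecule

    def __post_init__(self):
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    @property
    def molecule_lengths(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.coordinates)

    @property
    def n_molecules(self) -> int:
        return len(self.coordinates)

    def stacked(self) -> np.ndarray:
        """All points flattened in molecule order, shape (N, 3)."""
        return np.concatenate([np.asarray(c, dtype=float)
                               for c in self.coordinates], axis=0)

    def index_offsets(self) -> np.ndarray:
        """Start offset of each molecule in the flattened point order."""
        return np.concatenate(([0], np.cumsum(self.molecule_lengths)))


@dataclass(frozen=True)
class SystemSummary:
    """Composition report: per-molecule lengths, counts and sequences."""

    peptide_length_list: tuple[int, ...]
    len_dict: dict[int, int]
    sequences: tuple[tuple[str, ...], ...]

    @property
    def n_molecules(self) -> int:
        return len(self.peptide_length_list)


@dataclass
class TrajectorySession:
    """An opened system: topology + optional trajectory + selection."""

    config_path: Path
    traj_path: Path | None
    selection: str
    universe: mda.Universe = field(repr=False)
    atoms: mda.AtomGroup = field(repr=False)
    # per molecule: list of AtomGroups, one per residue, in residue order
    _residue_groups: list[list] = field(repr=False, default_factory=list)

    @property
    def number_of_frames(self) -> int:
        return len(self.universe.trajectory)

    @property
    def n_molecules(self) -> int:
        return len(self._residue_groups)


def _selection_string(selection: str) -> str:
    names = selection.replace(",", " ").split()
    return "name " + " ".join(names)


def load_session(
    config_path: str | Path,
    traj_path: str | Path | None = None,
    selection: str = DEFAULT_SELECTION,
) -> TrajectorySession:
    """Open a structure (PDB/GRO) and optional trajectory.

    Parameters
    ----------
    config_path : path
        Initial configuration; defines the topology.
    traj_path : path, optional
        Trajectory (XTC/TRR/DCD/multi-model PDB) with the same atom count.
    selection : str
        Whitespace/comma-separated atom-name list, e.g. ``"BB"`` or ``"CA"``.

    Raises
    ------
    FormatError
        If a file cannot be parsed.
    EmptySelectionError
        If the selection matches no atoms.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise FormatError(f"configuration file not found: {config_path}")
    if traj_path is not None:
        traj_path = Path(traj_path)
        if not traj_path.exists():
            raise FormatError(f"trajectory file not found: {traj_path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if traj_path is None:
                universe = mda.Universe(str(config_path))
            else:
                universe = mda.Universe(str(config_path), str(traj_path))
    except EmptySelectionError:
        raise
    except Exception as exc:  # MDAnalysis raises a zoo of parse errors
        raise FormatError(
            f"could not parse {config_path}"
            + (f" with trajectory {traj_path}" if traj_path else "")
            + f": {exc}"
        ) from exc

    atoms = universe.select_atoms(_selection_string(selection))
    if len(atoms) == 0:
        raise EmptySelectionError(
            f"selection {selection!r} matched no atoms in {config_path}"
        )

    session = TrajectorySession(
        config_path=config_path,
        traj_path=traj_path,
        selection=selection,
        universe=universe,
        atoms=atoms,
        _residue_groups=_partition_molecules(atoms),
    )
    logger.info(
        "loaded %s (%d frames, %d molecules, selection %r)",
        config_path.name, session.number_of_frames, session.n_molecules,
        selection,
    )
    return session


def _partition_molecules(atoms: mda.AtomGroup) -> list[list]:
    """Split selected residues into molecules.

    A new molecule starts when the segid changes or the residue number
    does not increase (chain-id alphabets recycle in large multi-copy
    PDB systems, so a resid restart is also a molecule boundary).
    """
    molecules: list[list] = []
    current: list = []
    prev_segid = None
    prev_resid = None
    for res in atoms.residues:
        sel = res.atoms & atoms
        if len(sel) == 0:
            logger.warning("residue %s has no selected atoms; skipped", res)
            continue
        boundary = (
            prev_segid is not None
            and (res.segid != prev_segid or res.resid <= prev_resid)
        )
        if boundary and current:
            molecules.append(current)
            current = []
        current.append(sel)
        prev_segid = res.segid
        prev_resid = res.resid
    if current:
        molecules.append(current)
    return molecules


def explore(session: TrajectorySession) -> SystemSummary:
    """Report system composition: molecule lengths, counts, sequences."""
    lengths = []
    sequences = []
    for groups in session._residue_groups:
        lengths.append(len(groups))
        sequences.append(tuple(g.residues[0].resname for g in groups))
    len_dict: dict[int, int] = {}
    for ln in lengths:
        len_dict[ln] = len_dict.get(ln, 0) + 1
    return SystemSummary(
        peptide_length_list=tuple(lengths),
        len_dict=len_dict,
        sequences=tuple(sequences),
    )


def frame_at(session: TrajectorySession, index: int) -> SystemFrame:
    """Extract the selected points of trajectory frame ``index``."""
    session.universe.trajectory[index]
    coords = tuple(
        np.array([g.center_of_mass() for g in groups], dtype=float)
        for groups in session._residue_groups
    )
    return SystemFrame(frame_index=index, coordinates=coords)


def sample_frames(session: TrajectorySession, interval: int = 1) -> list[SystemFrame]:
    """Frames 0, interval, 2·interval, …; frame 0 is always included."""
    if interval <= 0:
        raise ValueError(f"sampling interval must be positive, got {interval}")
    nf = session.number_of_frames
    indices = range(0, nf, interval)
    return [frame_at(session, i) for i in indices]


def write_frames_pdb(
    frames: list[SystemFrame],
    path: str | Path,
    resnames: list[list[str]] | None = None,
) -> None:
    """Write frames as a (multi-model) PDB via MDAnalysis.

    All frames must share the molecule layout of ``frames[0]``.  Atoms
    are named ``BB`` so a round trip through :func:`load_session` with
    the default selection reproduces the points to PDB precision.
    """
    first = frames[0]
    lengths = first.molecule_lengths
    n_atoms = sum(lengths)
    resindex = np.arange(n_atoms)
    segindex = np.repeat(np.arange(len(lengths)), lengths)
    u = mda.Universe.empty(
        n_atoms,
        n_residues=n_atoms,
        n_segments=len(lengths),
        atom_resindex=resindex,
        residue_segindex=segindex,
        trajectory=True,
    )
    u.add_TopologyAttr("name", ["BB"] * n_atoms)
    if resnames is None:
        flat_resnames = ["ALA"] * n_atoms
    else:
        flat_resnames = [rn for mol in resnames for rn in mol]
    u.add_TopologyAttr("resname", flat_resnames)
    resids = np.concatenate([np.arange(1, ln + 1) for ln in lengths])
    u.add_TopologyAttr("resid", resids)
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    u.add_TopologyAttr(
        "segid", [alphabet[m % len(alphabet)] for m in range(len(lengths))]
    )
    u.add_TopologyAttr("chainID",
                       [alphabet[m % len(alphabet)] for m in segindex])
    coords = np.stack([f.stacked() for f in frames]).astype(np.float32)
    u.load_new(coords, order="fac")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms, multiframe=len(frames) > 1) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
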