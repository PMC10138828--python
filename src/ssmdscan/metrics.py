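"""Time-series metrics over per-frame structural assignments.

Given per-frame secondary-structure contents this module computes:

* **stability** — the percentage of frames whose content exceeds the
  trajectory mean, ``100 · N_frames(Fold) / N_frames``;
* **transition entropy** — the relative entropy (Kullback–Leibler
  divergence, bits) between the β-turn and α-helix content series,
  each first normalized into an empirical distribution over frames;
  high values mark improbable α→β transitions;
* **mutual information** — between two content series after equal-width
  binning, quantifying the dependence between structural domains;
* **organizational index** — the antiparallel/parallel and
  antiparallel/total β-contact ratios per frame, the computational
  analogue of ATR-FTIR sheet-organization indices;
* **shift profiles** — per-frame histograms of register shift by
  orientation class, tracking strand displacement within sheets.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ssmdscan.alignment import AlignmentMatrix
from ssmdscan.contact_maps import ContactCriterion, contact_map, distance_map
from ssmdscan.kernels import KernelLibrary
from ssmdscan.secstruct import find_alpha_and_turn, helix_content, turn_content
from ssmdscan.traj_io import SystemFrame

MI_BINS_DEFAULT = 10
KL_EPS = 1e-12

ORIENTATION_CLASSES = ("P", "AP+", "AP-")


@dataclass(frozen=True)
class StructuralTimeSeries:
    """Per-frame secondary-structure series for one trajectory.

    Contents are percentages in [0, 100]; ``beta_sheet_fraction`` is in
    [0, 1].  Per-molecule matrices have shape (n_frames, n_molecules).
    β-sheet fields are None when only the α analysis was run.
    """

    frames: tuple[int, ...]
    alpha_content: np.ndarray = field(repr=False)  # system mean, per frame
    beta_turn_content: np.ndarray = field(repr=False)
    per_molecule_alpha: np.ndarray = field(repr=False)
    per_molecule_turn: np.ndarray = field(repr=False)
    beta_sheet_fraction: np.ndarray | None = field(default=None, repr=False)
    contact_tallies: tuple[dict[str, int], ...] | None = None
    shift_histograms: tuple[dict[str, dict[int, int]], ...] | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def helix_score_series(
    frames: list[SystemFrame],
    criterion: ContactCriterion | None = None,
) -> StructuralTimeSeries:
    """α-helix / β-turn content per molecule and frame.

    Runs the helix/turn assignment on the α contact map of every frame.
    """
    if not frames:
        raise ValueError("need at least one frame")
    if criterion is None:
        criterion = ContactCriterion.alpha()
    nmol = frames[0].n_molecules
    alpha = np.zeros((len(frames), nmol))
    turn = np.zeros((len(frames), nmol))
    for t, frame in enumerate(frames):
        cm = contact_map(distance_map(frame), criterion)
        for m in range(nmol):
            a = find_alpha_and_turn(cm, m)
            res = frame.molecule_lengths[m]
            alpha[t, m] = helix_content(a, res)
            turn[t, m] = turn_content(a, res)
    return StructuralTimeSeries(
        frames=tuple(f.frame_index for f in frames),
        alpha_content=alpha.mean(axis=1),
        beta_turn_content=turn.mean(axis=1),
        per_molecule_alpha=alpha,
        per_molecule_turn=turn,
    )


def stability(series) -> float:
    """Percentage of frames with content strictly above the series mean."""
    x = np.asarray(series, dtype=float)
    if x.size < 1:
        raise ValueError("empty series")
    return 100.0 * float(np.count_nonzero(x > x.mean())) / x.size


def transition_entropy(
    beta_series,
    alpha_series,
    normalize: bool = True,
    eps: float = KL_EPS,
) -> float:
    """Relative entropy (bits) from the α series to the β-turn series.

    Both series are normalized to empirical distributions over frames
    (disable with ``normalize=False`` to evaluate raw contents); terms
    with β(t) = 0 contribute nothing, and α(t) = 0 under positive β is
    floored at ``eps``.  An all-zero β series gives 0.
    """
    b = np.asarray(beta_series, dtype=float)
    a = np.asarray(alpha_series, dtype=float)
    if b.shape != a.shape:
        raise ValueError("series must have equal length")
    if (b < 0).any() or (a < 0).any():
        raise ValueError("contents must be non-negative")
    if b.sum() == 0:
        return 0.0
    if normalize:
        b = b / b.sum()
        a = a / a.sum() if a.sum() > 0 else a
    mask = b > 0
    return float(np.sum(b[mask] * np.log2(b[mask] / np.maximum(a[mask], eps))))


def mutual_information(series_a, series_b, n_bins: int = MI_BINS_DEFAULT) -> float:
    """Mutual information (bits) between two series after binning.

    Each series is discretized into ``n_bins`` equal-width bins over
    its own observed range; MI is computed from the joint empirical
    histogram.  Constant series occupy a single bin and give 0.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least two observations")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    joint, _, _ = np.histogram2d(a, b, bins=n_bins)
    joint /= joint.sum()
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    denom = np.outer(pa, pb)
    return float(np.sum(joint[nz] * np.log2(joint[nz] / denom[nz])))


def entropy_bits(series, n_bins: int = MI_BINS_DEFAULT) -> float:
    """Shannon entropy (bits) of a binned series (marginal of the MI)."""
    x = np.asarray(series, dtype=float)
    hist, _ = np.histogram(x, bins=n_bins)
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def organizational_index(tallies) -> dict[str, np.ndarray]:
    """Antiparallel/parallel and antiparallel/total ratios per frame.

    ``tallies`` is a sequence of per-frame contact counts by class
    (mappings with keys "P", "AP+", "AP-"; missing keys count 0).
    ``ap_over_p`` is NaN where no parallel contacts exist, and both
    ratios are NaN for frames without any classified contact.
    """
    n = len(tallies)
    ap_over_p = np.full(n, np.nan)
    ap_over_total = np.full(n, np.nan)
    for t, tally in enumerate(tallies):
        p = float(tally.get("P", 0))
        ap = float(tally.get("AP+", 0)) + float(tally.get("AP-", 0))
        total = p + ap
        if total > 0:
            ap_over_total[t] = ap / total
            if p > 0:
                ap_over_p[t] = ap / p
    return {"ap_over_p": ap_over_p, "ap_over_total": ap_over_total}


def contact_tally(P: AlignmentMatrix, cm=None) -> dict[str, int]:
    """Per-frame contact counts by orientation class over classified pairs.

    With a contact map the tally weights each pair by its contact
    count (edge thickness semantics); without, each pair counts once.
    """
    from ssmdscan.contact_maps import molecule_block

    tally = Counter({c: 0 for c in ORIENTATION_CLASSES})
    for p, q in P.classified_pairs():
        cls, _shift = P.classify(p, q)
        w = int(molecule_block(cm, p, q).sum()) if cm is not None else 1
        tally[cls] += w
    return dict(tally)


def shift_profile(
    alignment_matrices: list[AlignmentMatrix],
    lib: KernelLibrary | None = None,
) -> list[dict[str, dict[int, int]]]:
    """Per-frame histogram of register shift for each orientation class."""
    profiles = []
    for P in alignment_matrices:
        hist: dict[str, Counter] = {c: Counter() for c in ORIENTATION_CLASSES}
        for p, q in P.classified_pairs():
            cls, shift = P.classify(p, q)
            hist[cls][shift] += 1
        profiles.append({c: dict(hist[c]) for c in ORIENTATION_CLASSES})
    return profiles


def summarize(series) -> dict[str, float]:
    """Max content, frames at max, mean content and stability of a series."""
    x = np.asarray(series, dtype=float)
    if x.size < 1:
        raise ValueError("empty series")
    mx = float(x.max())
    return {
        "max": mx,
        "frames_at_max": int(np.count_nonzero(x == mx)),
        "mean": float(x.mean()),
        "stability": stability(x),
    }


def summarize_per_molecule(per_molecule: np.ndarray):
    """Summary table over molecules: one row per molecule.

    Columns mirror the per-peptide trajectory reports: max content,
    frames at max, mean and stability.
    """
    import pandas as pd

    rows = []
    for m in range(per_molecule.shape[1]):
        s = summarize(per_molecule[:, m])
        s["molecule"] = m
        rows.append(s)
    return pd.DataFrame(rows)[
        ["molecule", "max", "frames_at_max", "mean", "stability"]
    ]
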