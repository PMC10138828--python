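"""Static plots rendered from an analysis bundle's CSV/TSV files.

Plotting is a thin view layer: every number drawn here is read back
from files that :mod:`ssmdscan.pipeline` already wrote, so plots carry
no computation of their own.  Antiparallel contacts are drawn blue,
parallel ones red.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import networkx as nx  # noqa: E402
import pandas as pd  # noqa: E402

PLOT_KINDS = ("graph", "frame_aggregates", "contacts", "peptides_in_beta",
              "shift3d")

AP_COLOR = "tab:blue"
P_COLOR = "tab:red"


def plot(bundle_dir: str | Path, which: str, out_path: str | Path | None = None):
    """Render one plot kind from a bundle directory; returns the PNG path."""
    bundle = Path(bundle_dir)
    if which not in PLOT_KINDS:
        raise ValueError(f"unknown plot {which!r}; choose from {PLOT_KINDS}")
    out_path = Path(out_path) if out_path else bundle / f"plot_{which}.png"
    fig = _RENDERERS[which](bundle)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def _first_graph_tsv(bundle: Path) -> Path:
    candidates = sorted(bundle.glob("graph_*.tsv"))
    if not candidates:
        raise FileNotFoundError(f"no graph_*.tsv in {bundle}")
    return candidates[0]


def _plot_graph(bundle: Path):
    edges = pd.read_csv(_first_graph_tsv(bundle), sep="\t")
    summary = pd.read_csv(bundle / "frames.csv")
    n_mol = pd.read_csv(bundle / "secstruct.csv")["molecule"].max() + 1
    g = nx.Graph()
    g.add_nodes_from(range(int(n_mol)))
    for _, row in edges.iterrows():
        g.add_edge(int(row["p"]), int(row["q"]),
                   n_contacts=int(row["n_contacts"]),
                   orientation=row["orientation"])
    fig, ax = plt.subplots(figsize=(6, 6))
    pos = nx.spring_layout(g, seed=0)
    colors = [
        AP_COLOR if d["orientation"].startswith("AP") else P_COLOR
        for _, _, d in g.edges(data=True)
    ]
    widths = [0.5 + 0.3 * d["n_contacts"] for _, _, d in g.edges(data=True)]
    nx.draw_networkx(g, pos, ax=ax, node_size=120, font_size=6,
                     edge_color=colors, width=widths, node_color="lightgray")
    ax.set_title(f"interaction graph (frame {summary['frame'].iloc[0]})")
    ax.set_axis_off()
    return fig


def _plot_frame_aggregates(bundle: Path):
    clusters = pd.read_csv(bundle / "clusters.csv")
    fig, ax = plt.subplots(figsize=(7, 4))
    color_map = {"AP": AP_COLOR, "P": P_COLOR, "mixed": "tab:purple",
                 "none": "lightgray"}
    if len(clusters):
        for label, sub in clusters.groupby("orientation"):
            ax.scatter(sub["frame"], sub["size"], s=30,
                       color=color_map.get(label, "black"), label=label)
        ax.legend(title="majority sense")
    ax.set_xlabel("frame")
    ax.set_ylabel("cluster size (molecules)")
    ax.set_title("aggregates per frame")
    return fig


def _plot_contacts(bundle: Path):
    frames = pd.read_csv(bundle / "frames.csv")
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(frames["frame"], frames["ap_over_total"], marker="o",
            color=AP_COLOR)
    ax.set_xlabel("frame")
    ax.set_ylabel("antiparallel / total contacts")
    ax.set_ylim(-0.05, 1.05)
    ax.set_title("β-contact organization over time")
    return fig


def _plot_peptides_in_beta(bundle: Path):
    frames = pd.read_csv(bundle / "frames.csv")
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(frames["frame"], frames["beta_sheet_fraction"], marker="o",
            color="tab:green")
    ax.set_xlabel("frame")
    ax.set_ylabel("fraction of peptides in β-sheets")
    ax.set_ylim(-0.05, 1.05)
    ax.set_title("peptides in β-sheet structures")
    return fig


def _plot_shift3d(bundle: Path):
    shifts = pd.read_csv(bundle / "shift_profile.tsv", sep="\t")
    fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharey=True)
    for ax, cls in zip(axes, ("P", "AP+", "AP-")):
        sub = shifts[shifts["class"] == cls]
        if len(sub):
            pivot = sub.pivot_table(index="shift", columns="frame",
                                    values="count", fill_value=0)
            ax.imshow(pivot.to_numpy(), aspect="auto", origin="lower",
                      cmap="viridis",
                      extent=(pivot.columns.min() - 0.5,
                              pivot.columns.max() + 0.5,
                              pivot.index.min() - 0.5,
                              pivot.index.max() + 0.5))
        ax.set_title(cls)
        ax.set_xlabel("frame")
    axes[0].set_ylabel("register shift")
    fig.suptitle("shift profiles by orientation class")
    return fig


_RENDERERS = {
    "graph": _plot_graph,
    "frame_aggregates": _plot_frame_aggregates,
    "contacts": _plot_contacts,
    "peptides_in_beta": _plot_peptides_in_beta,
    "shift3d": _plot_shift3d,
}
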