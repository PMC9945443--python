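"""Optional matplotlib figures mirroring the standard panel shapes:
length profiles, 5'-end coverage metaplots and mismatch heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .guide_coords import METAPLOT


def plot_length_profile(profile: pd.DataFrame, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(profile["length"], profile["rpm"], color="#4878a8", width=0.8)
    ax.set_xlabel("read length (nt)")
    ax.set_ylabel("rpm")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_end_coverage(
    coverage: pd.DataFrame, path: str | Path, cleavage_position: int = -9
) -> None:
    """5'-end metaplot with the expected slicer cut marked."""
    meta = coverage[coverage.site_id == METAPLOT]
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(meta["position"], meta["rpm"], color="#555555", width=0.8)
    ax.axvline(cleavage_position, color="red", ls="--", lw=1)
    ax.set_xlabel("distance from 5' nt of targeting piRNA (nt)")
    ax.set_ylabel("5'-end rpm")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_mismatch_heatmap(table: pd.DataFrame, path: str | Path) -> None:
    """Mismatch-position heatmap with an abundance bar per piRNA."""
    if table.empty:
        fig, ax = plt.subplots(figsize=(4, 2))
        ax.text(0.5, 0.5, "no profiles", ha="center")
        ax.axis("off")
        fig.savefig(path)
        plt.close(fig)
        return
    names = list(dict.fromkeys(table["piRNA"]))
    positions = sorted(table["position"].unique())
    state_code = {"match": 0, "mismatch": 1, "overhang": 2}
    mat = np.zeros((len(names), len(positions)))
    for r in table.itertuples():
        mat[names.index(r.piRNA), positions.index(r.position)] = state_code[r.state]
    abund = table.drop_duplicates("piRNA").set_index("piRNA")["abundance"]
    fig, (ax, axb) = plt.subplots(
        1, 2, figsize=(8, 0.3 * len(names) + 1.5),
        gridspec_kw={"width_ratios": [4, 1]}, sharey=True,
    )
    ax.imshow(
        mat, aspect="auto", cmap=matplotlib.colors.ListedColormap(
            ["#f0f0f0", "#c03030", "#b0b0d0"]
        ), vmin=0, vmax=2,
    )
    ax.set_yticks(range(len(names)), names, fontsize=6)
    ax.set_xticks(range(0, len(positions), 5), positions[::5])
    ax.set_xlabel("piRNA position (nt from 5' end)")
    axb.barh(range(len(names)), [abund[n] for n in names], color="#4878a8")
    axb.set_xlabel("abundance")
    axb.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
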