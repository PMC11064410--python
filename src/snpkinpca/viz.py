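"""Publication-style 2D/3D scatter plots of PC coordinates.

Point color encodes the inferred cluster; marker shape encodes the prior
group label when one was supplied.  Axes are annotated with the percent
variance explained by each PC.  Output is vector (SVG/PDF) and
deterministic: SVG date metadata is suppressed and view angles are fixed.
"""

from __future__ import annotations

import itertools

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "snpkinpca"  # deterministic SVG ids

import matplotlib.pyplot as plt
import numpy as np

from .clustering import ClusterResult
from .pca import PCAResult
from .vcf_io import SamplePanel

__all__ = ["plot_scatter_2d", "plot_scatter_3d"]

_MARKERS = ["o", "s", "^", "D", "v", "P", "X", "*", "<", ">"]


def _style_iterators(res: PCAResult, clusters: ClusterResult, panel: SamplePanel):
    ids = panel.included_ids
    groups = np.array([panel.group_of(s) for s in ids], dtype=object)
    has_groups = panel.group_labels is not None
    cluster_ids = np.unique(clusters.labels)
    cmap = plt.get_cmap("tab10" if cluster_ids.size <= 10 else "tab20")
    colors = {c: cmap(i % cmap.N) for i, c in enumerate(cluster_ids)}
    group_ids = sorted(set(groups)) if has_groups else ["NA"]
    markers = dict(zip(group_ids, itertools.cycle(_MARKERS)))
    return groups, has_groups, cluster_ids, colors, group_ids, markers


def _axis_label(res: PCAResult, i: int) -> str:
    return f"PC{i + 1} ({100.0 * res.var_explained[i]:.2f}%)"


def _scatter(ax, res, clusters, panel, dims):
    groups, has_groups, cluster_ids, colors, group_ids, markers = _style_iterators(
        res, clusters, panel
    )
    for c in cluster_ids:
        for g in group_ids:
            sel = clusters.labels == c
            if has_groups:
                sel = sel & (groups == g)
            if not sel.any():
                continue
            coords = [res.scores[sel, d] for d in dims]
            name = f"cluster {c}" if c >= 0 else "noise"
            label = f"{name} / {g}" if has_groups else name
            ax.scatter(*coords, c=[colors[c]], marker=markers[g], s=18,
                       edgecolors="none", label=label)
    return has_groups


def plot_scatter_2d(res: PCAResult, clusters: ClusterResult,
                    panel: SamplePanel, path: str) -> str:
    if res.k < 2:
        raise ValueError("2D plot requires at least 2 retained PCs")
    fig, ax = plt.subplots(figsize=(6, 5))
    _scatter(ax, res, clusters, panel, dims=(0, 1))
    ax.set_xlabel(_axis_label(res, 0))
    ax.set_ylabel(_axis_label(res, 1))
    ax.legend(fontsize=7, loc="best", frameon=False)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
    return path


def plot_scatter_3d(res: PCAResult, clusters: ClusterResult,
                    panel: SamplePanel, path: str) -> str:
    if res.k < 3:
        raise ValueError("3D plot requires at least 3 retained PCs")
    fig = plt.figure(figsize=(6.5, 5.5))
    ax = fig.add_subplot(projection="3d")
    _scatter(ax, res, clusters, panel, dims=(0, 1, 2))
    ax.set_xlabel(_axis_label(res, 0))
    ax.set_ylabel(_axis_label(res, 1))
    ax.set_zlabel(_axis_label(res, 2))
    ax.view_init(elev=20.0, azim=-60.0)
    ax.legend(fontsize=7, loc="upper left", frameon=False)
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
    return path
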