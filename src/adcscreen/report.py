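"""Heat-map rendering and result tables.

Two figures summarize a candidate panel: a continuous heat map of quasi
H-scores (fixed 0-300 color scale) over genes x tumor types, and a
discrete four-color heat map of ordinal staining levels over genes x the 45
normal tissues (each tissue aggregated as the maximum over its cell types).
Every figure is written together with a TSV "sidecar" holding the exact
plotted matrix (``NA`` for undefined cells), so figure content is
reproducible and testable without pixel comparison.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import BoundaryNorm, ListedColormap

from .errors import ValidationError
from .screening import QuasiHScoreMatrix
from .types import NormalTissueProfile
from .vocab import NORMAL_TISSUES

_LEVEL_COLORS = ("#f0f0f0", "#fdd49e", "#fc8d59", "#b30000")  # nd, low, medium, high


def sidecar_path(out_path: str | Path) -> Path:
    return Path(out_path).with_suffix(".tsv")


def render_score_heatmap(
    matrix: QuasiHScoreMatrix,
    gene_order: Sequence[str] | None = None,
    tumor_order: Sequence[str] | None = None,
    out_path: str | Path = "score_heatmap.png",
) -> Path:
    """Render the quasi H-score heat map and its TSV sidecar.

    Undefined (unassayed) cells are drawn in a distinct hatch-free grey and
    exported as ``NA``.
    """
    genes = list(gene_order) if gene_order is not None else sorted(matrix.genes())
    tumors = list(tumor_order) if tumor_order is not None else list(matrix.tumor_types)
    if not genes or not tumors:
        raise ValidationError("cannot render an empty score matrix")
    grid = pd.DataFrame(index=genes, columns=tumors, dtype=float)
    for g in genes:
        for t in tumors:
            s = matrix.get(g, t)
            grid.loc[g, t] = np.nan if s is None else s

    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(tumors)), max(3, 0.3 * len(genes))))
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("#d9d9d9")
    im = ax.imshow(grid.to_numpy(dtype=float), aspect="auto", cmap=cmap, vmin=0, vmax=300)
    ax.set_xticks(range(len(tumors)), tumors, rotation=90, fontsize=7)
    ax.set_yticks(range(len(genes)), genes, fontsize=7)
    fig.colorbar(im, ax=ax, label="quasi H-score")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)

    grid.to_csv(sidecar_path(out_path), sep="\t", na_rep="NA", index_label="gene_id")
    return Path(out_path)


def render_normal_heatmap(
    profiles: Mapping[str, NormalTissueProfile],
    gene_order: Sequence[str] | None = None,
    tissue_order: Sequence[str] | None = None,
    out_path: str | Path = "normal_heatmap.png",
) -> Path:
    """Render the discrete normal-tissue expression heat map with sidecar."""
    genes = list(gene_order) if gene_order is not None else sorted(profiles)
    tissues = list(tissue_order) if tissue_order is not None else list(NORMAL_TISSUES)
    if not genes or not tissues:
        raise ValidationError("cannot render an empty normal-tissue panel")
    grid = pd.DataFrame(index=genes, columns=tissues, dtype=float)
    for g in genes:
        profile = profiles.get(g)
        for t in tissues:
            lvl = profile.tissue_level(t) if profile is not None else None
            grid.loc[g, t] = np.nan if lvl is None else int(lvl)

    cmap = ListedColormap(_LEVEL_COLORS)
    cmap.set_bad("#ffffff")
    norm = BoundaryNorm([-0.5, 0.5, 1.5, 2.5, 3.5], cmap.N)
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(tissues)), max(3, 0.3 * len(genes))))
    im = ax.imshow(grid.to_numpy(dtype=float), aspect="auto", cmap=cmap, norm=norm)
    ax.set_xticks(range(len(tissues)), tissues, rotation=90, fontsize=6)
    ax.set_yticks(range(len(genes)), genes, fontsize=7)
    cbar = fig.colorbar(im, ax=ax, ticks=[0, 1, 2, 3])
    cbar.ax.set_yticklabels(["Not detected", "Low", "Medium", "High"])
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)

    grid.to_csv(sidecar_path(out_path), sep="\t", na_rep="NA",
                index_label="gene_id", float_format="%.0f")
    return Path(out_path)
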