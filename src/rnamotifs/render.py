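"""Rendering of the RNA splicing map figure.

One track per tetramer (at most ``top_k_render``, ranked by maximum ES)
over the four exon-intron junction windows.  Bars show the ES normalised
to the global maximum of the matrix; colour encodes the contribution of
the enhanced (red), silenced (blue) or both (yellow) exon sets.  Exonic
parts of each window are shaded, and the left margin lists the tetramer
together with the regions where it passed the retention thresholds.
"""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap

#: silenced (0) -> both (0.5) -> enhanced (1)
CONTRIBUTION_CMAP = LinearSegmentedColormap.from_list(
    "contribution", [(0.0, "#2166ac"), (0.5, "#ffd700"), (1.0, "#b2182b")]
)

_JUNCTION_LABELS = ["upstream exon 5'ss", "CE 3'ss", "CE 5'ss", "downstream exon 3'ss"]


def _region_flags(enrichment: pd.DataFrame, tet: str) -> str:
    """Compact per-set indicator of regions passing both thresholds."""
    sub = enrichment[(enrichment["tetramer"] == tet) & enrichment["passes"]]
    parts = []
    for set_name, tag in (("enhanced", "E"), ("silenced", "S")):
        regs = sorted(sub.loc[sub["exon_set"] == set_name, "region"].unique())
        if regs:
            parts.append(f"{tag}:{'/'.join(regs)}")
    return " ".join(parts)


def render_map(es_matrix, groups, enrichment: pd.DataFrame, cfg, path) -> None:
    """Write the splicing-map figure (format taken from the file suffix)."""
    span = cfg.map_intronic + cfg.map_exonic
    P = 4 * span
    tets = list(es_matrix.tetramers)
    if not tets:
        fig, ax = plt.subplots(figsize=(10, 2))
        ax.text(0.5, 0.5, "no tetramers retained", ha="center", va="center")
        ax.set_axis_off()
        fig.savefig(path)
        plt.close(fig)
        return

    # group-ordered list, trimmed to the top_k by maximum ES
    ordered = [t for g in groups for t in g.members]
    max_es = {t.pattern: es_matrix.max_es[i] for i, t in enumerate(tets)}
    if len(ordered) > cfg.top_k_render:
        keep = set(
            sorted(max_es, key=lambda n: -max_es[n])[: cfg.top_k_render]
        )
        ordered = [t for t in ordered if t.pattern in keep]
    norm = es_matrix.global_max or 1.0
    name_to_col = {t.pattern: i for i, t in enumerate(tets)}

    n = len(ordered)
    fig, axes = plt.subplots(
        n, 1, figsize=(12, 0.9 * n + 1.2), sharex=True, squeeze=False
    )
    x = np.arange(P)
    # exonic stretches: donor windows start exonic, acceptor windows end exonic
    exon_spans = [
        (0, cfg.map_exonic),
        (2 * span - cfg.map_exonic, 2 * span),
        (2 * span, 2 * span + cfg.map_exonic),
        (4 * span - cfg.map_exonic, 4 * span),
    ]
    for ax, tet in zip(axes[:, 0], ordered):
        col = name_to_col[tet.pattern]
        es = es_matrix.es[:, col] / norm
        frac = es_matrix.contribution[:, col]
        colors = CONTRIBUTION_CMAP(np.nan_to_num(frac, nan=0.5))
        nz = es > 0
        if nz.any():
            ax.bar(x[nz], es[nz], width=1.0, color=colors[nz])
        for a, b in exon_spans:
            ax.axvspan(a, b, color="0.85", zorder=0)
        for sep in (span, 2 * span, 3 * span):
            ax.axvline(sep, color="0.4", lw=0.6, ls="--")
        ax.set_ylim(0, 1.05)
        ax.set_yticks([])
        label = tet.pattern
        flags = _region_flags(enrichment, tet.pattern)
        if flags:
            label += f"\n{flags}"
        ax.set_ylabel(label, rotation=0, ha="right", va="center", fontsize=9)
    axes[-1, 0].set_xticks([span // 2 + i * span for i in range(4)])
    axes[-1, 0].set_xticklabels(_JUNCTION_LABELS, fontsize=8)
    axes[0, 0].set_title(
        f"RNA splicing map (max ES = {es_matrix.global_max:.1f}; "
        "red = enhanced, blue = silenced, yellow = both)",
        fontsize=10,
    )
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
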