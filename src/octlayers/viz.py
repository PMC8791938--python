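"""Overlay and thickness-map rendering."""
from __future__ import annotations

from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .core import BOUNDARY_ORDER, BScan
from .evaluate import ThicknessMap
from .identify import Segmentation


def render_overlay(
    bscan: BScan, seg: Segmentation, path: Union[str, Path], dpi: int = 120
) -> None:
    """The B-scan with the eleven boundary curves superimposed."""
    fig, ax = plt.subplots(figsize=(8, 6))
    ax.imshow(bscan.pixels, cmap="gray", aspect="auto", vmin=0, vmax=1)
    cmap = plt.get_cmap("tab10")
    x = np.arange(bscan.shape[1])
    for k, name in enumerate(BOUNDARY_ORDER):
        ax.plot(x, seg.curves[name], lw=0.8, color=cmap(k % 10), label=name)
    ax.legend(loc="lower right", fontsize=6, ncol=4)
    ax.set_xlabel("column (lateral)")
    ax.set_ylabel("row (axial)")
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)


def render_thickness_map(tm: ThicknessMap, path: Union[str, Path], dpi: int = 120) -> None:
    """Heat map of a thickness surface with a micrometre colourbar."""
    fig, ax = plt.subplots(figsize=(7, 5))
    im = ax.imshow(tm.values, cmap="turbo", aspect="auto")
    fig.colorbar(im, ax=ax, label="thickness (μm)")
    ax.set_title(f"{tm.layer_span[0]} → {tm.layer_span[1]}")
    ax.set_xlabel("column (lateral)")
    ax.set_ylabel("slice")
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
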