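"""Saliency-vs-ground-truth explainability maps.

For a stack of ``Nsl`` slices, the ground-truth density map is the
pixel-wise sum of the binary masks, and the feature-map density map is
the pixel-wise sum of the (per-frame normalized) saliency maps; both live
on the ``[0, Nsl]`` scale.  Their absolute pixel-wise difference map
(DMap) localizes where a model's attention diverges from the anatomy, and
the mean squared error between the two density maps summarizes it in one
number: near-zero means the pixels a model relies on match the
ground-truth density.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .volio import MaskStack, SaliencyStack


@dataclass
class DensityMap:
    """Pixel-wise aggregation of a mask or saliency stack."""

    cells: np.ndarray
    nsl: int
    source: str  # "GT" | "FM" | "DIFF"

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        if self.cells.ndim != 2:
            raise ValueError("DensityMap.cells must be 2D")
        if self.nsl < 1:
            raise ValueError("nsl must be >= 1")
        if self.cells.min() < 0 or self.cells.max() > self.nsl:
            raise ValueError("density cells must lie in [0, Nsl]")


def density_map_from_masks(stack: MaskStack) -> DensityMap:
    """GT density map: cell (i,j) = number of slices whose mask covers (i,j)."""
    cells = stack.as_array().sum(axis=0).astype(float)
    return DensityMap(cells=cells, nsl=stack.nsl, source="GT")


def density_map_from_saliency(stack: SaliencyStack) -> DensityMap:
    """FM density map: pixel-wise sum of normalized saliency frames."""
    cells = stack.as_array().sum(axis=0)
    return DensityMap(cells=cells, nsl=stack.nsl, source="FM")


def _check_compatible(fm: DensityMap, gt: DensityMap, check_nsl: bool = True) -> None:
    if fm.cells.shape != gt.cells.shape:
        raise ValueError("density maps must share one shape")
    if check_nsl and fm.nsl != gt.nsl:
        raise ValueError("density maps must aggregate the same number of slices")


def absolute_difference_map(fm: DensityMap, gt: DensityMap) -> DensityMap:
    """DMap: |FM density - GT density| per pixel."""
    _check_compatible(fm, gt)
    return DensityMap(cells=np.abs(fm.cells - gt.cells), nsl=fm.nsl, source="DIFF")


def density_mse(fm: DensityMap, gt: DensityMap) -> float:
    """Mean over pixels of the squared density difference."""
    _check_compatible(fm, gt, check_nsl=False)
    return float(np.mean((fm.cells - gt.cells) ** 2))


def render_density_map(dmap: DensityMap, path: str | Path, cmap: str = "viridis") -> Path:
    """Save a colormapped PNG rendering of a density or difference map."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(dmap.cells, cmap=cmap)
    ax.set_axis_off()
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
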