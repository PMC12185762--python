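"""Rendering of meshes and tessellations (matplotlib / label images)."""

from __future__ import annotations

import numpy as np

from .mesh import Mesh

__all__ = ["plot_mesh", "render_label_image"]


def plot_mesh(mesh: Mesh, values=None, ax=None, cmap="coolwarm", mark_mccs=True,
              label=None):
    """Draw the monolayer, optionally coloured by a per-cell quantity.

    Returns the matplotlib axes.  MCCs are outlined in black when
    ``mark_mccs`` is set.
    """
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 7))
    polys = [mesh.cell_polygon(ci) for ci in range(mesh.n_cells)]
    pc = PolyCollection(polys, edgecolors="0.3", linewidths=0.4)
    if values is not None:
        pc.set_array(np.asarray(values, dtype=float))
        pc.set_cmap(cmap)
        cb = plt.colorbar(pc, ax=ax, shrink=0.8)
        if label:
            cb.set_label(label)
    else:
        pc.set_facecolor("0.9")
    ax.add_collection(pc)
    if mark_mccs:
        mcc_polys = [mesh.cell_polygon(ci) for ci, c in enumerate(mesh.cells) if c.is_mcc]
        if mcc_polys:
            ax.add_collection(
                PolyCollection(mcc_polys, facecolors="none", edgecolors="k", linewidths=1.5)
            )
    ax.autoscale_view()
    ax.set_aspect("equal")
    return ax


def render_label_image(tissue, px: int = 512) -> np.ndarray:
    """Rasterise a synthetic tessellation into a uint16 label image (cell id + 1)."""
    from matplotlib.path import Path as MplPath

    pts = np.concatenate(tissue.polygons)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = float(max(hi - lo))
    xs = np.linspace(lo[0], lo[0] + span, px)
    ys = np.linspace(lo[1], lo[1] + span, px)
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    img = np.zeros(px * px, dtype=np.uint16)
    for ci, poly in enumerate(tissue.polygons):
        mask = MplPath(poly).contains_points(grid)
        img[mask] = ci + 1
    return img.reshape(px, px)
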