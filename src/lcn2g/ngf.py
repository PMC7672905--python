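"""Nutritional-geometry response surfaces.

A gene's expression is rendered as a colour-coded surface over two nutrient
axes: a thin-plate spline is fitted to the observed (nutrient1, nutrient2,
expression) triples and evaluated on a regular lattice, masked to the convex
hull of the observed points so the surface is never extrapolated.  With zero
smoothing the spline interpolates the data exactly.  Axes are displayed in
raw nutrient units (standardization matters only for LC computation, not for
display).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.spatial import QhullError, Delaunay

__all__ = ["SurfaceModel", "fit_ngf_surface", "render_ngf"]


@dataclass
class SurfaceModel:
    """Fitted thin-plate-spline surface on a g x g lattice.

    ``grid_values`` is NaN outside ``hull_mask``; ``grid_x``/``grid_y`` are
    the lattice coordinates spanning the observed range of each axis.
    """

    interpolator: RBFInterpolator
    grid_x: np.ndarray  # (g,)
    grid_y: np.ndarray  # (g,)
    grid_values: np.ndarray  # (g, g), indexed [iy, ix]
    hull_mask: np.ndarray  # (g, g) bool
    points: np.ndarray  # (n, 2) observed nutrient coordinates
    values: np.ndarray  # (n,) observed response
    x_name: str = "x"
    y_name: str = "y"

    def predict(self, points) -> np.ndarray:
        """Evaluate the spline at arbitrary (x, y) points (no hull masking)."""
        return self.interpolator(np.atleast_2d(points))


def fit_ngf_surface(
    X2,
    G,
    grid_size: int = 100,
    smoothing: float = 0.0,
    x_name: str = "x",
    y_name: str = "y",
) -> SurfaceModel:
    """Fit a thin-plate-spline response surface over two nutrient axes.

    Parameters
    ----------
    X2 : (n, 2) array of the two selected nutrient variables (raw units).
    G : length-n response.
    grid_size : lattice resolution per axis (>= 10).
    smoothing : thin-plate smoothing parameter; 0 interpolates exactly.
    """
    X2 = np.asarray(X2, dtype=float)
    G = np.asarray(G, dtype=float).ravel()
    if X2.ndim != 2 or X2.shape[1] != 2:
        raise ValueError("X2 must have exactly 2 columns")
    if X2.shape[0] != G.shape[0]:
        raise ValueError("X2 and G must have the same number of samples")
    if X2.shape[0] < 4:
        raise ValueError("need at least 4 points to fit a surface")
    if grid_size < 10:
        raise ValueError("grid_size must be >= 10")
    if not (np.all(np.isfinite(X2)) and np.all(np.isfinite(G))):
        raise ValueError("inputs contain non-finite values")
    try:
        tri = Delaunay(X2)
        interp = RBFInterpolator(X2, G, kernel="thin_plate_spline", smoothing=smoothing)
    except (QhullError, np.linalg.LinAlgError) as exc:
        raise ValueError(
            "cannot fit a surface: the points are collinear or degenerate "
            f"({exc})"
        ) from None
    gx = np.linspace(X2[:, 0].min(), X2[:, 0].max(), grid_size)
    gy = np.linspace(X2[:, 1].min(), X2[:, 1].max(), grid_size)
    mx, my = np.meshgrid(gx, gy)
    lattice = np.column_stack([mx.ravel(), my.ravel()])
    mask = tri.find_simplex(lattice) >= 0
    vals = np.full(lattice.shape[0], np.nan)
    vals[mask] = interp(lattice[mask])
    return SurfaceModel(
        interpolator=interp,
        grid_x=gx,
        grid_y=gy,
        grid_values=vals.reshape(grid_size, grid_size),
        hull_mask=mask.reshape(grid_size, grid_size),
        points=X2,
        values=G,
        x_name=x_name,
        y_name=y_name,
    )


def render_ngf(
    model: SurfaceModel,
    out_path,
    title: str = "",
    xlabel: str | None = None,
    ylabel: str | None = None,
    cmap: str = "viridis",
    show_points: bool = True,
    dpi: int = 150,
):
    """Write the fitted surface as a heat map with a colour bar.

    The first selected variable is on x, the second on y, in the order the
    caller supplied them.  Returns the output path.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    pm = ax.pcolormesh(
        model.grid_x, model.grid_y, model.grid_values, cmap=cmap, shading="auto"
    )
    fig.colorbar(pm, ax=ax, label="response")
    if show_points:
        ax.scatter(model.points[:, 0], model.points[:, 1], s=12, c="k", alpha=0.6)
    ax.set_xlabel(xlabel or model.x_name)
    ax.set_ylabel(ylabel or model.y_name)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=dpi, metadata={"Software": None})
    plt.close(fig)
    return out_path
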