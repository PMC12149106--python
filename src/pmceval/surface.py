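"""PMC surface: the 3x3 arrangement of first-level values and its plot.

For a nine-dimension framework the first-level values are laid out
row-major into a 3x3 matrix —

    [[X1, X2, X3],
     [X4, X5, X6],
     [X7, X8, X9]]

— and rendered as a 3-D surface whose concavity and colour depth show,
dimension by dimension, where a policy is strong or weak.  Smoothing
upsamples the grid with an interpolating tensor spline that passes
exactly through the nine anchor heights; it never alters them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .pmc import PolicyScore

__all__ = ["SurfaceMatrix", "build_surface", "flatten", "smooth_grid", "render_surface"]


@dataclass(frozen=True)
class SurfaceMatrix:
    """A policy's nine first-level values arranged 3x3, row-major."""

    policy_id: str
    cells: np.ndarray

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=float)
        if cells.shape != (3, 3):
            raise ValueError(f"surface cells must be 3x3, got {cells.shape}")
        if ((cells < 0) | (cells > 1)).any():
            raise ValueError("surface cells must lie in [0, 1]")
        object.__setattr__(self, "cells", cells)

    @property
    def pmc_full_precision(self) -> float:
        """Mean of the cells times nine: the unrounded PMC index."""
        return float(self.cells.mean() * 9)


def build_surface(score: Union[PolicyScore, Sequence[float]]) -> SurfaceMatrix:
    """Arrange nine first-level values row-major into a surface matrix."""
    if isinstance(score, PolicyScore):
        values = list(score.first_level_values)
        policy_id = score.policy_id
    else:
        values = [float(v) for v in score]
        policy_id = ""
    if len(values) != 9:
        raise ValueError(
            f"PMC surface is defined for nine-dimension frameworks; got {len(values)} values"
        )
    return SurfaceMatrix(policy_id=policy_id, cells=np.array(values).reshape(3, 3))


def flatten(surface: SurfaceMatrix) -> tuple[float, ...]:
    """Row-major flattening; inverse of :func:`build_surface`."""
    return tuple(float(v) for v in surface.cells.ravel())


def smooth_grid(
    cells: np.ndarray, factor: int = 25
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upsample a 3x3 grid with an interpolating tensor spline.

    Returns ``(X, Y, Z)`` mesh arrays with ``2 * factor + 1`` points per
    axis.  The spline is degree 2 per axis (the interpolating degree a
    three-knot axis supports) and reproduces the anchor heights exactly;
    off-knot values are clipped to [0, 1] to tame overshoot.
    """
    from scipy.interpolate import RectBivariateSpline

    cells = np.asarray(cells, dtype=float)
    knots = np.array([1.0, 2.0, 3.0])
    spline = RectBivariateSpline(knots, knots, cells, kx=2, ky=2, s=0)
    fine = np.linspace(1.0, 3.0, 2 * factor + 1)
    Z = spline(fine, fine)
    np.clip(Z, 0.0, 1.0, out=Z)
    X, Y = np.meshgrid(fine, fine, indexing="ij")
    return X, Y, Z


def render_surface(
    matrix: SurfaceMatrix,
    out: Union[str, Path],
    interpolation: str = "smooth",
    factor: int = 25,
    annotate: bool = True,
    cmap: str = "viridis",
) -> Path:
    """Render the PMC surface to an image file (PNG or SVG by suffix).

    ``interpolation='none'`` plots the raw 3x3 grid; ``'smooth'``
    upsamples with the interpolating spline.  Anchor heights are always
    the matrix cells; with ``annotate`` they are printed at the anchors.
    Deterministic given inputs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if interpolation not in ("none", "smooth"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if interpolation == "smooth":
        X, Y, Z = smooth_grid(matrix.cells, factor=factor)
    else:
        knots = np.array([1.0, 2.0, 3.0])
        X, Y = np.meshgrid(knots, knots, indexing="ij")
        Z = matrix.cells.copy()

    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    ax.plot_surface(
        X, Y, Z, cmap=cmap, vmin=0.0, vmax=1.0, linewidth=0, antialiased=True
    )
    ax.set_zlim(0.0, 1.0)
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    ax.set_zlabel("first-level value")
    title = f"PMC surface{' — ' + matrix.policy_id if matrix.policy_id else ''}"
    ax.set_title(title)
    if annotate:
        for i in range(3):
            for j in range(3):
                ax.text(i + 1, j + 1, float(matrix.cells[i, j]),
                        f"{matrix.cells[i, j]:.2f}", fontsize=8)
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
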