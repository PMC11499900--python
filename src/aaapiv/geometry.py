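"""Idealized axisymmetric AAA lumen geometry.

The fusiform aneurysm bulge is described by two dimensionless shape
parameters: the aspect ratio L/d (bulge length over parent-vessel inner
diameter) and the dilation ratio D/d (maximum bulge diameter over parent
diameter).  The lumen radius along the axis is a raised-cosine bulge

    Gamma(x) = d* cos(pi x / (2 x*)) + d/2   for |x| <= x*,
    Gamma(x) = d/2                           otherwise,

with half-length x* = (L/d) d / 2 and amplitude d* = (D/d - 1) d / 2, so
that the diameter is D at the bulge center (x = 0) and d in the parent
vessel.  Axial coordinate x is in mm, origin at the bulge center, positive
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["IdealizedAAAGeometry", "bulge_radius", "lumen_mask"]


@dataclass(frozen=True)
class IdealizedAAAGeometry:
    """Axisymmetric fusiform-aneurysm lumen.

    Parameters
    ----------
    d : float
        Parent-vessel inner diameter, mm.
    aspect_ratio : float
        Bulge length over parent diameter, L/d (dimensionless).
    dilation_ratio : float
        Maximum bulge diameter over parent diameter, D/d (>= 1).
    total_length : float
        Total model length, mm.
    wall_thickness : float
        Phantom wall thickness, mm (used only for rendering wall
        reflections, never by the flow analysis).
    """

    d: float = 20.0
    aspect_ratio: float = 2.9
    dilation_ratio: float = 1.9
    total_length: float = 250.0
    wall_thickness: float = 1.8

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError(f"parent diameter must be positive, got {self.d}")
        if self.aspect_ratio <= 0:
            raise ValueError("aspect_ratio must be positive")
        if self.dilation_ratio < 1:
            raise ValueError("dilation_ratio must be >= 1")
        if self.total_length < self.aspect_ratio * self.d:
            raise ValueError(
                "total_length must accommodate the bulge "
                f"({self.aspect_ratio * self.d:.1f} mm)"
            )
        if self.wall_thickness < 0:
            raise ValueError("wall_thickness must be non-negative")

    @property
    def bulge_half_length(self) -> float:
        """x* = (L/d)·d/2, mm."""
        return 0.5 * self.aspect_ratio * self.d

    @property
    def bulge_amplitude(self) -> float:
        """d* = (D/d − 1)·d/2, mm."""
        return 0.5 * (self.dilation_ratio - 1.0) * self.d

    @property
    def max_diameter(self) -> float:
        """D = dilation_ratio·d, mm."""
        return self.dilation_ratio * self.d


def bulge_radius(geom: IdealizedAAAGeometry, x):
    """Lumen radius Gamma(x) at axial position(s) ``x`` (mm from bulge center).

    Returns the raised-cosine bulge radius inside |x| <= x* and the parent
    radius d/2 outside; continuous at +-x*.  Raises for x outside the model.
    """
    x = np.asarray(x, dtype=float)
    half = geom.total_length / 2.0
    if np.any(np.abs(x) > half + 1e-9):
        raise ValueError(
            f"axial position outside model (+-{half:g} mm): "
            f"max |x| = {np.max(np.abs(x)):g}"
        )
    xs = geom.bulge_half_length
    r = np.where(
        np.abs(x) <= xs,
        geom.bulge_amplitude * np.cos(np.pi * x / (2.0 * xs)) + geom.d / 2.0,
        geom.d / 2.0,
    )
    return r if r.ndim else float(r)


def lumen_mask(
    geom: IdealizedAAAGeometry,
    window: tuple[float, float],
    scale: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """Rasterize the mid-plane lumen as a boolean mask.

    Parameters
    ----------
    geom : IdealizedAAAGeometry
    window : (x_min, x_max)
        Axial range covered by the image, mm (bulge-centered coordinates).
    scale : float
        Magnification, px/mm.
    shape : (n_rows, n_cols)
        Output image size; columns map to the axial coordinate, rows to the
        transverse one, the lumen axis on the central row.  Pixel centers
        sit at half-integer positions.

    Returns
    -------
    mask : bool ndarray of ``shape``
        True inside the lumen.  Local mask width at each column matches
        2·Gamma(x)·scale within one pixel.
    """
    if scale <= 0:
        raise ValueError("scale must be positive, px/mm")
    n_rows, n_cols = shape
    if n_rows < 1 or n_cols < 1:
        raise ValueError("mask shape must be at least 1x1")
    x_min, x_max = window
    if x_max <= x_min:
        raise ValueError("window must satisfy x_max > x_min")
    if (x_max - x_min) * scale < 1.0:
        raise ValueError("window and scale produce an empty image")

    cols = (np.arange(n_cols) + 0.5) / scale + x_min  # mm at pixel centers
    radii = bulge_radius(geom, cols)  # mm
    rows = (np.arange(n_rows) + 0.5) - n_rows / 2.0  # px from axis row
    y_mm = rows[:, None] / scale
    return np.abs(y_mm) <= radii[None, :]
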