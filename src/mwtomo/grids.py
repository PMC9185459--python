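"""Square imaging grids for 2D tomographic reconstruction.

The domain of interest D is a square of side ``extent`` centred on the
origin, discretised into M x M equal square pixels.  Pixel centres are
enumerated row-major: x varies fastest (left to right), then y (bottom to
top).  Each pixel is assigned an equivalent circular cell of the same area,
whose radius enters the pulse-basis method-of-moments coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImagingGrid", "build_grid"]


@dataclass(frozen=True)
class ImagingGrid:
    """Uniform square discretisation of the imaging domain.

    Attributes
    ----------
    extent : float
        Side length of the square domain (m).
    pixels : int
        Number of pixels per side, M.  The grid has N = M**2 cells.
    """

    extent: float
    pixels: int
    dx: float = field(init=False)
    dy: float = field(init=False)
    centers: np.ndarray = field(init=False, repr=False)
    a_eq: float = field(init=False)

    def __post_init__(self) -> None:
        if self.extent <= 0:
            raise ValueError(f"extent must be positive, got {self.extent}")
        if self.pixels < 2:
            raise ValueError(f"pixels must be >= 2, got {self.pixels}")
        d = self.extent / self.pixels
        object.__setattr__(self, "dx", d)
        object.__setattr__(self, "dy", d)
        # cell midpoints, row-major, x fastest, origin at domain centre
        coords = (np.arange(self.pixels) + 0.5) * d - self.extent / 2.0
        xx, yy = np.meshgrid(coords, coords, indexing="xy")
        centers = np.column_stack([xx.ravel(), yy.ravel()])
        centers.setflags(write=False)
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "a_eq", math.sqrt(d * d / math.pi))

    @property
    def n_pixels(self) -> int:
        """Total number of cells N = M**2."""
        return self.pixels * self.pixels

    @property
    def x(self) -> np.ndarray:
        """Pixel-centre x coordinates, shape (N,)."""
        return self.centers[:, 0]

    @property
    def y(self) -> np.ndarray:
        """Pixel-centre y coordinates, shape (N,)."""
        return self.centers[:, 1]

    def reshape(self, values: np.ndarray) -> np.ndarray:
        """View a flat per-pixel vector as an (M, M) image (row 0 = bottom)."""
        return np.asarray(values).reshape(self.pixels, self.pixels)


def build_grid(extent: float, pixels: int) -> ImagingGrid:
    """Build a square imaging grid of ``pixels`` x ``pixels`` cells.

    Parameters
    ----------
    extent : float
        Side length of the square domain (m); must be positive.
    pixels : int
        Pixels per side; must be at least 2.

    Returns
    -------
    ImagingGrid
        Grid with cell pitch ``extent / pixels`` and equivalent cell
        radius ``sqrt(dx*dy/pi)``.
    """
    return ImagingGrid(extent=float(extent), pixels=int(pixels))
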