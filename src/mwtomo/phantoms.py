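"""Dielectric phantoms: the concentric-circle validation model and
procedural breast-class phantoms with implanted tumors.

Phantoms are per-pixel maps of relative permittivity and conductivity over
an :class:`~mwtomo.grids.ImagingGrid`, plus an integer region label per
pixel.  The complex contrast against the immersion background,

    chi_n = (eps_r(r_n) - eps_rb)/eps_rb - j (sigma(r_n) - sigma_b)/(omega eps_b),

is what the scattering operators act on; it is exactly zero wherever the
map equals the background.

The breast-class generator produces layered 2D maps emulating MRI-derived
breast slices of four ACR-style density classes (almost entirely fatty to
extremely dense): an outer skin ring, a fatty interior, and a smooth random
fibroglandular distribution whose area fraction increases with class.  One
fixed anatomy per (class, seed) is reused across tumor placements, so a
training sweep varies only the tumor, as a repeated clinical acquisition
of one patient would.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .grids import ImagingGrid, build_grid
from .medium import BackgroundMedium

__all__ = [
    "PhantomMap",
    "TumorSpec",
    "circular_phantom",
    "synthetic_breast_phantom",
    "contrast_map",
    "permittivity_from_contrast",
    "box_resample",
    "TUMOR_POSITIONS_M",
    "TUMOR_DIAMETERS_M",
    "EPS_R_RANGE",
]

LABEL_BACKGROUND = 0
LABEL_FAT = 1
LABEL_GLAND = 2
LABEL_SKIN = 3
LABEL_TUMOR = 4

# Permittivity range assumed for breast tissue over the measurement band.
EPS_R_RANGE = (2.5, 67.0)

# Tumor sweep used for training-set assembly: three diameters at nine sites.
TUMOR_DIAMETERS_M = (0.003, 0.005, 0.008)
_P = 0.019  # 1.9 cm offset
TUMOR_POSITIONS_M = (
    (0.0, 0.0),
    (0.0, _P), (0.0, -_P), (_P, 0.0), (-_P, 0.0),
    (_P, _P), (-_P, _P), (_P, -_P), (-_P, -_P),
)

# Tissue permittivities for the procedural breast classes (dimensionless).
_EPS_SKIN = 36.0
_EPS_FAT = 5.5
_EPS_GLAND = 42.0
_EPS_TUMOR = 62.0

# Interior area fraction occupied by fibroglandular tissue per density class.
_GLAND_FRACTION = {1: 0.10, 2: 0.25, 3: 0.45, 4: 0.65}

_BREAST_RADIUS_M = 0.06
_SKIN_THICKNESS_M = 0.002
_GLAND_CORRELATION_M = 0.012  # smoothing length of the fibroglandular field


@dataclass(frozen=True)
class TumorSpec:
    """A circular tumor inclusion: diameter and centre position (m)."""

    diameter: float
    center: tuple[float, float]

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("tumor diameter must be positive")


@dataclass
class PhantomMap:
    """Per-pixel dielectric map over an imaging grid.

    Attributes
    ----------
    grid : ImagingGrid
    eps_r : ndarray, shape (N,)
        Relative permittivity per pixel, real, >= 1.
    sigma : ndarray, shape (N,)
        Conductivity per pixel (S/m), >= 0.
    labels : ndarray of int, shape (N,), optional
        Region tag per pixel (0 background, 1 fat, 2 gland, 3 skin, 4 tumor).
    """

    grid: ImagingGrid
    eps_r: np.ndarray
    sigma: np.ndarray
    labels: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.grid.n_pixels
        self.eps_r = np.asarray(self.eps_r, dtype=float).ravel()
        self.sigma = np.asarray(self.sigma, dtype=float).ravel()
        if self.eps_r.size != n or self.sigma.size != n:
            raise ValueError("eps_r and sigma must have exactly N entries")
        if np.any(self.eps_r < 1):
            raise ValueError("relative permittivity must be >= 1 everywhere")
        if np.any(self.sigma < 0):
            raise ValueError("conductivity must be non-negative")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8).ravel()
            if self.labels.size != n:
                raise ValueError("labels must have exactly N entries")

    @property
    def support(self) -> np.ndarray:
        """Boolean mask of pixels belonging to the scatterer."""
        if self.labels is not None:
            return self.labels != LABEL_BACKGROUND
        return np.zeros(self.grid.n_pixels, dtype=bool)

    def eps_image(self) -> np.ndarray:
        return self.grid.reshape(self.eps_r)

    def sigma_image(self) -> np.ndarray:
        return self.grid.reshape(self.sigma)


def circular_phantom(
    grid: ImagingGrid,
    background_eps: float = 10.0,
    tumor_center: tuple[float, float] = (0.0, 0.015),
    sigma_b: float = 0.0,
) -> PhantomMap:
    """Concentric-circle validation phantom.

    An 8 cm diameter disc of eps_r = 40 containing a 6 cm disc of
    eps_r = 4.5, with a 1 cm tumor disc of eps_r = 57 placed inside the
    inner disc; everywhere else the immersion background (default
    eps_r = 10).  The conductivity map is uniform at ``sigma_b``: this
    phantom is used to retrieve permittivity only.

    Raises
    ------
    ValueError
        If the tumor disc is not fully inside the 6 cm inner disc.
    """
    cx, cy = tumor_center
    if np.hypot(cx, cy) + 0.005 > 0.03 + 1e-12:
        raise ValueError(
            f"tumor at {tumor_center} does not fit inside the 6 cm inner disc"
        )
    r = np.hypot(grid.x, grid.y)
    eps = np.full(grid.n_pixels, float(background_eps))
    labels = np.full(grid.n_pixels, LABEL_BACKGROUND, dtype=np.int8)
    outer = r <= 0.04
    eps[outer] = 40.0
    labels[outer] = LABEL_GLAND
    inner = r <= 0.03
    eps[inner] = 4.5
    labels[inner] = LABEL_FAT
    tum = np.hypot(grid.x - cx, grid.y - cy) <= 0.005
    eps[tum] = 57.0
    labels[tum] = LABEL_TUMOR
    sigma = np.full(grid.n_pixels, float(sigma_b))
    return PhantomMap(
        grid, eps, sigma, labels,
        meta={"kind": "circular", "background_eps": background_eps,
              "tumor_center": list(tumor_center)},
    )


def _random_smooth_field(rng, x, y, corr_len: float, n_modes: int = 64):
    """Stationary Gaussian random field via random Fourier features.

    A continuous function of position (resolution independent): the same
    seed evaluated on a finer grid samples the same underlying field.
    """
    k = rng.standard_normal((n_modes, 2)) / corr_len
    phase = rng.uniform(0.0, 2.0 * np.pi, n_modes)
    amp = np.sqrt(2.0 / n_modes)
    return amp * np.sum(
        np.cos(x[:, None] * k[None, :, 0] + y[:, None] * k[None, :, 1]
               + phase[None, :]),
        axis=1,
    )


def _breast_anatomy(grid: ImagingGrid, class_id: int, seed: int):
    """Deterministic skin/fat/gland anatomy for one density class.

    Returns (eps_r, labels) before tumor implantation.  All random
    structure is a continuous function of position, so the same anatomy
    renders consistently at any grid resolution.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(class_id)]))
    x = grid.x
    y = grid.y

    # Slightly eccentric breast outline, fixed by the rng draw.
    ecc = 1.0 + 0.08 * rng.uniform(-1.0, 1.0)
    theta0 = rng.uniform(0.0, np.pi)
    ct, st = np.cos(theta0), np.sin(theta0)
    u = ct * x + st * y
    v = -st * x + ct * y
    rho = np.hypot(u / ecc, v * ecc)
    breast = rho <= _BREAST_RADIUS_M
    interior = rho <= _BREAST_RADIUS_M - _SKIN_THICKNESS_M
    skin = breast & ~interior

    # Smooth fibroglandular field, denser toward the breast centre,
    # thresholded at the class area fraction.
    smooth = _random_smooth_field(rng, x, y, _GLAND_CORRELATION_M)
    smooth = smooth - 1.5 * (rho / _BREAST_RADIUS_M)  # central tendency
    frac = _GLAND_FRACTION[class_id]
    vals = smooth[interior]
    thresh = np.quantile(vals, 1.0 - frac)
    gland = interior & (smooth > thresh)

    # Mild smooth heterogeneity within each tissue.
    het = _random_smooth_field(rng, x, y, _GLAND_CORRELATION_M)
    het = np.clip(het, -2.5, 2.5) / 2.5  # unit-variance field, pointwise scaled

    eps = np.full(grid.n_pixels, 10.0)  # immersion background
    labels = np.full(grid.n_pixels, LABEL_BACKGROUND, dtype=np.int8)
    eps[interior] = _EPS_FAT * (1.0 + 0.10 * het[interior])
    labels[interior] = LABEL_FAT
    eps[gland] = _EPS_GLAND * (1.0 + 0.10 * het[gland])
    labels[gland] = LABEL_GLAND
    eps[skin] = _EPS_SKIN
    labels[skin] = LABEL_SKIN
    return eps, labels


def synthetic_breast_phantom(
    class_id: int,
    tumor: TumorSpec,
    seed: int,
    grid: Optional[ImagingGrid] = None,
    background_eps: float = 10.0,
) -> PhantomMap:
    """Procedural 2D breast phantom of one density class with a tumor.

    Parameters
    ----------
    class_id : int
        Density class 1 (almost entirely fatty) through 4 (extremely
        dense); the fibroglandular area fraction increases with class.
    tumor : TumorSpec
        Diameter in {3, 5, 8} mm, centre at one of the nine sweep
        positions (0, 0), (0, +-1.9), (+-1.9, 0), (+-1.9, +-1.9) cm.
    seed : int
        Fixes the anatomy; same (class_id, tumor, seed) gives a
        bit-identical map.
    grid : ImagingGrid, optional
        Defaults to an 18 cm, 64 x 64 grid.

    Notes
    -----
    All permittivities lie in [2.5, 67].  Conductivity inside the breast
    follows the linear tissue model sigma = 0.019 eps_r - 0.047 (floored
    at 0); outside it equals the background exactly.
    """
    if class_id not in _GLAND_FRACTION:
        raise ValueError(f"class_id must be in 1..4, got {class_id}")
    pos_ok = any(
        abs(tumor.center[0] - px) < 1e-9 and abs(tumor.center[1] - py) < 1e-9
        for px, py in TUMOR_POSITIONS_M
    )
    if not pos_ok:
        raise ValueError(
            f"tumor centre {tumor.center} is not one of the sweep positions"
        )
    if grid is None:
        grid = build_grid(0.18, 64)

    eps, labels = _breast_anatomy(grid, class_id, seed)
    cx, cy = tumor.center
    tum = np.hypot(grid.x - cx, grid.y - cy) <= tumor.diameter / 2.0
    # implant only inside the breast (all sweep positions are interior)
    tum &= labels != LABEL_BACKGROUND
    eps[tum] = _EPS_TUMOR
    labels[tum] = LABEL_TUMOR

    lo, hi = EPS_R_RANGE
    inside = labels != LABEL_BACKGROUND
    eps[inside] = np.clip(eps[inside], lo, hi)

    from .metrics import conductivity_from_permittivity

    sigma = np.zeros(grid.n_pixels)
    sigma[inside] = conductivity_from_permittivity(eps[inside])
    return PhantomMap(
        grid, eps, sigma, labels,
        meta={"kind": "breast", "class_id": class_id, "seed": int(seed),
              "tumor_diameter": tumor.diameter, "tumor_center": list(tumor.center),
              "background_eps": background_eps},
    )


def contrast_map(
    phantom: PhantomMap,
    medium: BackgroundMedium,
    frequency_index: int,
) -> np.ndarray:
    """Complex contrast chi_n of a phantom at one sweep frequency.

    chi = (eps_r - eps_rb)/eps_rb - j (sigma - sigma_b)/(omega eps_b).
    Background pixels have exactly zero contrast.
    """
    omega = medium.omega[frequency_index]
    if omega == 0:
        raise ValueError("zero angular frequency: conductivity term undefined")
    chi = (phantom.eps_r - medium.eps_rb) / medium.eps_rb - 1j * (
        phantom.sigma - medium.sigma_b
    ) / (omega * medium.eps_b)
    return chi


def permittivity_from_contrast(
    chi: np.ndarray, medium: BackgroundMedium, frequency_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the contrast definition: (eps_r, sigma) from complex chi."""
    omega = medium.omega[frequency_index]
    eps_r = medium.eps_rb * (1.0 + np.real(chi))
    sigma = medium.sigma_b - np.imag(chi) * omega * medium.eps_b
    return eps_r, sigma


def _overlap_matrix(m_fine: int, m_coarse: int) -> np.ndarray:
    """1D area-weighted binning matrix W (m_coarse x m_fine), rows sum to 1."""
    w = np.zeros((m_coarse, m_fine))
    ratio = m_fine / m_coarse
    for i in range(m_coarse):
        lo, hi = i * ratio, (i + 1) * ratio
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        for j in range(j0, min(j1, m_fine)):
            w[i, j] = min(hi, j + 1) - max(lo, j)
    return w / ratio


def box_resample(image: np.ndarray, m_coarse: int) -> np.ndarray:
    """Area-weighted box average of a square image to m_coarse x m_coarse.

    Exact for any fine/coarse ratio; each coarse pixel is the mean of the
    fine image over its footprint.
    """
    image = np.asarray(image, dtype=float)
    m_fine = image.shape[0]
    if image.shape != (m_fine, m_fine):
        raise ValueError("image must be square")
    if m_coarse > m_fine:
        raise ValueError("box_resample only coarsens")
    w = _overlap_matrix(m_fine, m_coarse)
    return w @ image @ w.T
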