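"""Cross-section density templates for planted filaments.

Four families are provided, mirroring the fibril types seen in tissue
tomograms of Alzheimer's disease pathology:

``phf_like``
    A pair of C-shaped protofilaments related by an exact in-plane C2
    (paired-helical-filament geometry), ~15 nm maximum caliper diameter.
``sf_like``
    The same two C-shaped protofilaments packed asymmetrically (straight
    filament geometry), no C2, similar overall diameter.
``abeta_fibril``
    A compact two-lobed cross-section, ~6 nm diameter.
``protofilament_rod``
    A single round lobe, ~4 nm diameter.

Templates are sampled onto a square grid at a stated pitch (default 2.38
angstrom per pixel, one quarter of the 9.52 angstrom tomogram voxel) and are
non-negative everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

TEMPLATE_IDS = ("phf_like", "sf_like", "abeta_fibril", "protofilament_rod")

DEFAULT_PITCH_A = 2.38
#: nominal maximum caliper diameters (nm) by template family
NOMINAL_DIAMETER_NM = {
    "phf_like": 15.0,
    "sf_like": 15.0,
    "abeta_fibril": 6.0,
    "protofilament_rod": 4.0,
}
SYMMETRY_ORDER = {
    "phf_like": 2,
    "sf_like": 1,
    "abeta_fibril": 1,
    "protofilament_rod": 1,
}


@dataclass(frozen=True)
class CrossSectionTemplate:
    """A 2D cross-section density sampled at a stated pitch."""

    template_id: str
    density: np.ndarray  # 2D, non-negative, indexed [y, x]
    pitch_a: float  # angstrom per pixel
    nominal_max_diameter_nm: float
    symmetry_order: int = 1

    def __post_init__(self):
        if self.template_id not in TEMPLATE_IDS:
            raise ValueError(
                f"unknown template_id {self.template_id!r}; known: {TEMPLATE_IDS}"
            )
        if np.any(self.density < 0):
            raise ValueError("template density must be non-negative")

    @property
    def pitch_nm(self) -> float:
        return self.pitch_a / 10.0

    @property
    def radius_nm(self) -> float:
        """Support radius: half the grid extent."""
        return self.density.shape[0] / 2.0 * self.pitch_nm

    def sample(self, x_nm: np.ndarray, y_nm: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of the density at in-plane points (nm)."""
        from scipy.ndimage import map_coordinates

        n = self.density.shape[0]
        c = (n - 1) / 2.0
        px = np.asarray(x_nm) / self.pitch_nm + c
        py = np.asarray(y_nm) / self.pitch_nm + c
        return map_coordinates(
            self.density, np.stack([py, px]), order=1, mode="constant", cval=0.0
        )


def _c_shape(
    x: np.ndarray,
    y: np.ndarray,
    center: tuple[float, float],
    radius_nm: float,
    opening_deg: float,
    gap_half_deg: float,
    sigma_nm: float,
    hook: bool = False,
) -> np.ndarray:
    """Gaussian tube around a circular arc (a C-shaped protofilament).

    The arc is a circle of ``radius_nm`` about ``center`` with an angular gap
    of ``2 * gap_half_deg`` centred on direction ``opening_deg``.
    """
    dx = x - center[0]
    dy = y - center[1]
    r = np.hypot(dx, dy)
    ang = np.degrees(np.arctan2(dy, dx))
    # smallest signed angular distance to the opening direction
    dopen = (ang - opening_deg + 180.0) % 360.0 - 180.0
    on_arc = np.abs(dopen) >= gap_half_deg
    # distance to arc: radial where the angle is on the arc, else to endpoints
    d_radial = np.abs(r - radius_nm)
    end1 = np.radians(opening_deg + gap_half_deg)
    end2 = np.radians(opening_deg - gap_half_deg)
    p1 = center[0] + radius_nm * np.cos(end1), center[1] + radius_nm * np.sin(end1)
    p2 = center[0] + radius_nm * np.cos(end2), center[1] + radius_nm * np.sin(end2)
    d_end = np.minimum(np.hypot(x - p1[0], y - p1[1]), np.hypot(x - p2[0], y - p2[1]))
    dist = np.where(on_arc, d_radial, d_end)
    dens = np.exp(-0.5 * (dist / sigma_nm) ** 2)
    if hook:
        # thicker lobe at one arc end only: makes the C chiral, as the two
        # ends of a real protofilament cross-section are inequivalent
        dens = dens + 0.9 * np.exp(
            -0.5 * (np.hypot(x - p1[0], y - p1[1]) / (1.6 * sigma_nm)) ** 2
        )
    return dens


def _gaussian_lobe(x, y, center, sigma_nm):
    return np.exp(-0.5 * ((x - center[0]) ** 2 + (y - center[1]) ** 2) / sigma_nm**2)


def _density_grid(template_id: str, pitch_a: float) -> np.ndarray:
    extent_nm = 11.0 if template_id in ("phf_like", "sf_like") else 6.0
    pitch_nm = pitch_a / 10.0
    n = int(round(2 * extent_nm / pitch_nm))
    ax = (np.arange(n) - (n - 1) / 2.0) * pitch_nm
    x, y = np.meshgrid(ax, ax, indexing="xy")

    if template_id == "phf_like":
        # one C; the C2 partner is the same field evaluated at -x, -y,
        # so the template is exactly two-fold symmetric on the grid centre
        half = _c_shape(x, y, (4.2, 0.0), 2.8, 180.0, 55.0, 0.85, hook=True)
        other = _c_shape(-x, -y, (4.2, 0.0), 2.8, 180.0, 55.0, 0.85, hook=True)
        dens = half + other
    elif template_id == "sf_like":
        # asymmetric packing of the two protofilaments: offset + re-oriented
        dens = _c_shape(x, y, (3.9, 0.6), 2.8, 0.0, 55.0, 0.85, hook=True) + _c_shape(
            x, y, (-3.6, -0.9), 2.8, 115.0, 55.0, 0.85, hook=True
        )
    elif template_id == "abeta_fibril":
        dens = _gaussian_lobe(x, y, (1.35, 0.35), 1.05) + _gaussian_lobe(
            x, y, (-1.35, -0.35), 1.05
        )
    elif template_id == "protofilament_rod":
        dens = _gaussian_lobe(x, y, (0.0, 0.0), 1.7)
    else:  # pragma: no cover
        raise ValueError(template_id)
    return dens


@lru_cache(maxsize=None)
def get_template(template_id: str, pitch_a: float = DEFAULT_PITCH_A) -> CrossSectionTemplate:
    """Build (and cache) the named cross-section template."""
    if template_id not in TEMPLATE_IDS:
        raise ValueError(f"unknown template_id {template_id!r}; known: {TEMPLATE_IDS}")
    dens = _density_grid(template_id, pitch_a)
    return CrossSectionTemplate(
        template_id=template_id,
        density=dens,
        pitch_a=pitch_a,
        nominal_max_diameter_nm=NOMINAL_DIAMETER_NM[template_id],
        symmetry_order=SYMMETRY_ORDER[template_id],
    )
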