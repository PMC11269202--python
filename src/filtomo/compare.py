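"""Model-to-map agreement: simulated density, real-space CC, masked FSC.

An atomic model (PDB, parsed with gemmi) is turned into a density map as a
sum of per-atom Gaussians weighted by atomic number; agreement with an
averaged map is quantified by the Pearson real-space correlation
coefficient over a mask and by the model-map Fourier shell correlation
restricted to a soft-edged central sphere (default radius 80 angstrom),
which avoids artefacts at the edges of the averaged volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

from .fsc import FscCurve, fsc, soft_sphere_mask

__all__ = [
    "AtomicModel",
    "FitScore",
    "load_pdb",
    "simulate_density",
    "real_space_cc",
    "masked_model_map_fsc",
    "fit_helical_rigid",
    "synthetic_filament_model",
    "write_model_pdb",
]


@dataclass
class AtomicModel:
    """Atom positions (angstrom), elements and per-atom Gaussian spread."""

    positions_a: np.ndarray  # (n, 3) x, y, z
    elements: list
    spread_a: np.ndarray  # isotropic sigma per atom, angstrom

    def __post_init__(self):
        self.positions_a = np.atleast_2d(np.asarray(self.positions_a, float))
        if len(self.positions_a) < 1:
            raise ValueError("model needs at least one atom")
        if not np.all(np.isfinite(self.positions_a)):
            raise ValueError("non-finite atom coordinates")
        self.spread_a = np.broadcast_to(
            np.asarray(self.spread_a, float), (len(self.positions_a),)
        ).copy()

    @property
    def weights(self) -> np.ndarray:
        return np.array([gemmi.Element(e).atomic_number or 6 for e in self.elements], float)


def load_pdb(path, default_spread_a: float = 1.5) -> AtomicModel:
    """Read a PDB file into an AtomicModel (all atoms, all chains)."""
    st = gemmi.read_structure(str(path))
    pos, els = [], []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    pos.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    els.append(atom.element.name)
    return AtomicModel(np.asarray(pos), els, np.full(len(pos), default_spread_a))


def simulate_density(
    model: AtomicModel,
    voxel_size_a: float,
    box: tuple[int, int, int] | int,
    allow_outside: bool = False,
) -> np.ndarray:
    """Gaussian-atom density on a grid, normalised to unit peak.

    Atom positions are interpreted in the volume frame (angstrom, voxel
    centre at index * voxel size).  Atoms outside the box raise unless
    ``allow_outside``.
    """
    if np.isscalar(box):
        box = (box, box, box)
    nz, ny, nx = box
    extent = np.array([nx - 1, ny - 1, nz - 1]) * voxel_size_a
    if not allow_outside and (
        np.any(model.positions_a < -0.5 * voxel_size_a)
        or np.any(model.positions_a > extent + 0.5 * voxel_size_a)
    ):
        raise ValueError("atom outside the requested box")
    out = np.zeros(box, dtype=np.float64)
    w = model.weights
    for (x, y, z), wt, sig in zip(model.positions_a, w, model.spread_a):
        r = 3.5 * sig
        lo = np.maximum(np.floor((np.array([x, y, z]) - r) / voxel_size_a).astype(int), 0)
        hi = np.minimum(
            np.ceil((np.array([x, y, z]) + r) / voxel_size_a).astype(int),
            [nx - 1, ny - 1, nz - 1],
        )
        if np.any(hi < lo):
            continue
        gz, gy, gx = np.meshgrid(
            np.arange(lo[2], hi[2] + 1) * voxel_size_a,
            np.arange(lo[1], hi[1] + 1) * voxel_size_a,
            np.arange(lo[0], hi[0] + 1) * voxel_size_a,
            indexing="ij",
        )
        d2 = (gx - x) ** 2 + (gy - y) ** 2 + (gz - z) ** 2
        out[lo[2] : hi[2] + 1, lo[1] : hi[1] + 1, lo[0] : hi[0] + 1] += wt * np.exp(
            -0.5 * d2 / sig**2
        )
    peak = out.max()
    if peak > 0:
        out /= peak
    return out


def synthetic_filament_model(
    template_id: str = "phf_like",
    box: int = 24,
    voxel_size_a: float = 9.52,
    twist_deg_per_nm: float = 2.5,
    stride: int = 6,
    spread_a: float = 6.0,
    density_threshold: float = 0.4,
) -> AtomicModel:
    """Synthetic pseudo-atomic filament model (not a real structure).

    Carbon pseudo-atoms are placed on the suprathreshold pixels of the named
    cross-section template and extruded helically along z through the box
    centre, giving a stand-in atomic model whose simulated density matches a
    rendered filament of the same family.
    """
    from .templates import get_template

    t = get_template(template_id)
    ys, xs = np.nonzero(t.density >= density_threshold * t.density.max())
    sel = np.arange(len(ys))[::stride]
    cn = (box - 1) / 2.0 * voxel_size_a
    pts = []
    for z in range(box):
        th = np.radians(twist_deg_per_nm * (z * voxel_size_a / 10.0))
        x = (xs[sel] - (t.density.shape[1] - 1) / 2.0) * t.pitch_a
        y = (ys[sel] - (t.density.shape[0] - 1) / 2.0) * t.pitch_a
        xr = np.cos(th) * x - np.sin(th) * y
        yr = np.sin(th) * x + np.cos(th) * y
        for a, b in zip(xr, yr):
            pts.append([cn + a, cn + b, z * voxel_size_a])
    n = len(pts)
    return AtomicModel(np.asarray(pts), ["C"] * n, np.full(n, spread_a))


def write_model_pdb(model: AtomicModel, path) -> None:
    """Write an AtomicModel as a minimal PDB file (CA pseudo-atoms)."""
    st = gemmi.Structure()
    st.name = "synthetic"
    md = gemmi.Model("1")
    ch = gemmi.Chain("A")
    for i, (p, el) in enumerate(zip(model.positions_a, model.elements)):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(i + 1, " ")
        at = gemmi.Atom()
        at.name = "CA"
        at.element = gemmi.Element(el)
        at.pos = gemmi.Position(*p)
        res.add_atom(at)
        ch.add_residue(res)
    md.add_chain(ch)
    st.add_model(md)
    st.write_pdb(str(path))


@dataclass
class FitScore:
    cc: float
    mask_description: str
    resolution_a: float | None = None

    def __post_init__(self):
        if not -1.0 - 1e-9 <= self.cc <= 1.0 + 1e-9:
            raise ValueError("correlation coefficient outside [-1, 1]")


def real_space_cc(
    map_a: np.ndarray,
    map_b: np.ndarray,
    mask: np.ndarray | None = None,
    resolution_a: float | None = None,
) -> FitScore:
    """Pearson correlation between two maps over the mask voxels."""
    if map_a.shape != map_b.shape:
        raise ValueError("maps must have equal shapes")
    if mask is None:
        sel = np.ones(map_a.shape, bool)
        desc = "none"
    else:
        sel = mask > 0.5
        desc = "binary mask"
    a = map_a[sel].astype(float)
    b = map_b[sel].astype(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined: constant map within the mask")
    cc = float(np.corrcoef(a, b)[0, 1])
    return FitScore(cc=cc, mask_description=desc, resolution_a=resolution_a)


def masked_model_map_fsc(
    model_map: np.ndarray,
    average_map: np.ndarray,
    voxel_size_a: float,
    sphere_radius_a: float = 80.0,
    edge_width_vox: float = 3.0,
) -> FscCurve:
    """Model-map FSC after a soft central-sphere mask (default 80 angstrom)."""
    if model_map.shape != average_map.shape:
        raise ValueError("maps must have equal shapes")
    radius_vox = sphere_radius_a / voxel_size_a
    half = min(model_map.shape) / 2.0
    if radius_vox > half:
        raise ValueError(
            f"sphere radius {sphere_radius_a} A ({radius_vox:.1f} vox) exceeds half-box {half}"
        )
    mask = soft_sphere_mask(model_map.shape, radius_vox, edge_width_vox)
    return fsc(model_map, average_map, mask=mask, voxel_size_a=voxel_size_a)


def fit_helical_rigid(
    model_map: np.ndarray,
    target_map: np.ndarray,
    mask: np.ndarray | None = None,
    angle_step_deg: float = 5.0,
    max_shift_vox: int = 3,
) -> tuple[FitScore, float, int]:
    """Local rigid fit exploiting helical geometry (filament along z).

    Grid search over in-plane rotations about z and integer axial shifts;
    returns the best score with its rotation (deg) and shift (voxels).
    """
    from scipy import ndimage

    from .align import _affine_rotate
    from .geometry import rotz

    best = (-2.0, 0.0, 0)
    for ang in np.arange(0.0, 360.0, angle_step_deg):
        rotated = _affine_rotate(model_map, rotz(ang))
        for dz in range(-max_shift_vox, max_shift_vox + 1):
            cand = ndimage.shift(rotated, (dz, 0, 0), order=1, mode="constant")
            try:
                score = real_space_cc(cand, target_map, mask=mask).cc
            except ValueError:
                continue
            if score > best[0]:
                best = (score, float(ang), dz)
    return FitScore(cc=best[0], mask_description="helical rigid fit"), best[1], best[2]
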