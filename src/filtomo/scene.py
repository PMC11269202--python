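"""Synthetic tissue-like tomograms with planted ground truth.

A :class:`SceneSpec` describes a volume (default 9.52 angstrom voxels), a set
of helically twisted filaments (optionally branched), and striated cuboidal
particles.  :func:`build_scene` renders the scene, imposes the missing-wedge
Fourier support implied by a +/-60 degree tilt scheme, adds seeded white
Gaussian noise, and returns the volume together with an exact per-segment
ground-truth table.  Every downstream stage of the package is testable
against these planted scenes.

Conventions
-----------
* Volumes are numpy arrays indexed ``[z, y, x]``; coordinates are ``(x, y, z)``.
* Voxel centres sit at integer indices; physical position = index * voxel size.
* Negative ``twist_rate`` is left-handed (the amyloid convention); public
  statistics report unsigned twist and positive crossover.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry
from .templates import TEMPLATE_IDS, CrossSectionTemplate, get_template

__all__ = [
    "FilamentSpec",
    "CuboidParticleSpec",
    "TiltScheme",
    "SceneSpec",
    "SimulatedTomogram",
    "render_filament",
    "render_cuboid",
    "apply_missing_wedge",
    "wedge_mask",
    "add_noise",
    "build_scene",
    "make_branch",
    "render_template_reference",
    "standard_test_scene",
    "mixed_class_scene",
]


class OutOfBoundsError(ValueError):
    """A planted object does not fit inside the volume."""


class AliasingError(ValueError):
    """Layer spacing too fine for the voxel grid."""


class SaturationError(ValueError):
    """Summed density exceeds the overlap saturation bound."""


@dataclass
class FilamentSpec:
    """A straight helical filament between two axis points (nm, volume frame).

    ``polarity`` is the unit vector from tail to head (derived from the axis);
    ``phase0`` is the in-plane rotation of the cross-section at ``axis_start``
    and ``twist_rate`` its rate of change in degrees per nm of arc length.
    ``branches`` holds ``(arc_nm, angle_deg, child FilamentSpec)`` tuples and
    is only allowed for the beta-amyloid-like templates.
    """

    axis_start: tuple[float, float, float]
    axis_end: tuple[float, float, float]
    template_id: str = "phf_like"
    twist_rate: float = -2.5  # degrees per nm, negative = left-handed
    phase0: float = 0.0
    branches: list = field(default_factory=list)

    def __post_init__(self):
        if self.template_id not in TEMPLATE_IDS:
            raise ValueError(f"unknown template_id {self.template_id!r}")
        if self.length_nm == 0:
            raise ValueError("filament axis has zero length")
        if self.branches and self.template_id not in ("abeta_fibril", "protofilament_rod"):
            raise ValueError(
                f"branches are only allowed for beta-amyloid-like templates, "
                f"not {self.template_id!r}"
            )

    @property
    def axis_vector(self) -> np.ndarray:
        return np.asarray(self.axis_end, float) - np.asarray(self.axis_start, float)

    @property
    def length_nm(self) -> float:
        return float(np.linalg.norm(self.axis_vector))

    @property
    def polarity(self) -> np.ndarray:
        """Unit vector from tail (axis_start) to head (axis_end)."""
        return self.axis_vector / self.length_nm


def make_branch(
    parent: FilamentSpec,
    arc_nm: float,
    angle_deg: float,
    length_nm: float,
    azimuth_deg: float = 0.0,
    **child_kwargs,
) -> FilamentSpec:
    """Construct a child filament branching off ``parent`` at ``arc_nm``.

    The child axis leaves the branch point at ``angle_deg`` from the parent
    direction; ``azimuth_deg`` selects the in-plane direction of departure.
    """
    d = parent.polarity
    e1, e2 = geometry.perpendicular_frame(d)
    az = np.radians(azimuth_deg)
    perp = np.cos(az) * e1 + np.sin(az) * e2
    a = np.radians(angle_deg)
    child_dir = np.cos(a) * d + np.sin(a) * perp
    start = np.asarray(parent.axis_start, float) + arc_nm * d
    end = start + length_nm * child_dir
    kwargs = dict(
        template_id=parent.template_id,
        twist_rate=parent.twist_rate,
        phase0=parent.phase0,
    )
    kwargs.update(child_kwargs)
    return FilamentSpec(tuple(start), tuple(end), **kwargs)


@dataclass
class CuboidParticleSpec:
    """An axis-aligned cuboid with internal planar striations.

    ``layer_spacing`` (nm) is the period of density layers along
    ``layer_normal``; ``layer_contrast`` the modulation depth as a fraction
    of the base density.  Edge lengths follow the 27-200 nm range observed
    for extracellular cuboidal particles.
    """

    center: tuple[float, float, float]
    edge_lengths: tuple[float, float, float] = (40.0, 40.0, 40.0)
    layer_normal: tuple[float, float, float] = (0.0, 0.0, 1.0)
    layer_spacing: float = 2.5
    layer_contrast: float = 0.8

    def __post_init__(self):
        for e in self.edge_lengths:
            if not (27.0 <= e <= 200.0):
                raise ValueError(f"edge length {e} nm outside the valid 27-200 nm range")
        n = np.linalg.norm(self.layer_normal)
        if n == 0:
            raise ValueError("layer_normal must be a nonzero vector")
        if not (0.0 <= self.layer_contrast <= 1.0):
            raise ValueError("layer_contrast must lie in [0, 1]")

    @property
    def unit_normal(self) -> np.ndarray:
        v = np.asarray(self.layer_normal, float)
        return v / np.linalg.norm(v)


@dataclass(frozen=True)
class TiltScheme:
    """Tilt-series geometry: default -60..+60 degrees in 2-degree steps."""

    min_angle: float = -60.0
    max_angle: float = 60.0
    step: float = 2.0
    tilt_axis: tuple[float, float] = (0.0, 1.0)  # unit vector in the x-y plane

    def __post_init__(self):
        if not self.min_angle < self.max_angle:
            raise ValueError("min_angle must be < max_angle")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def n_tilts(self) -> int:
        return int(round((self.max_angle - self.min_angle) / self.step)) + 1


@dataclass
class SceneSpec:
    """Full description of a synthetic tomogram."""

    volume_shape: tuple[int, int, int] = (96, 96, 96)  # (nz, ny, nx)
    voxel_size: float = 9.52  # angstrom
    filaments: list = field(default_factory=list)
    particles: list = field(default_factory=list)
    tilts: TiltScheme = field(default_factory=TiltScheme)
    snr: float = 1.0
    seed: int = 0
    saturation_factor: float = 3.0

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def voxel_nm(self) -> float:
        return self.voxel_size / 10.0

    @property
    def extent_nm(self) -> np.ndarray:
        """Physical extent (x, y, z) in nm."""
        nz, ny, nx = self.volume_shape
        return (np.array([nx, ny, nz]) - 1) * self.voxel_nm

    def to_dict(self) -> dict:
        def plain(x):
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [plain(v) for v in x]
            if isinstance(x, np.floating):
                return float(x)
            if isinstance(x, np.integer):
                return int(x)
            return x

        def fil_to_dict(f: FilamentSpec) -> dict:
            d = dataclasses.asdict(f)
            d["branches"] = [
                {"arc_nm": a, "angle_deg": ang, "child": fil_to_dict(c)}
                for (a, ang, c) in f.branches
            ]
            return d

        return plain({
            "volume_shape": list(self.volume_shape),
            "voxel_size": self.voxel_size,
            "filaments": [fil_to_dict(f) for f in self.filaments],
            "particles": [dataclasses.asdict(p) for p in self.particles],
            "tilts": dataclasses.asdict(self.tilts),
            "snr": self.snr,
            "seed": self.seed,
            "saturation_factor": self.saturation_factor,
        })

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        def fil_from_dict(fd: dict) -> FilamentSpec:
            branches = [
                (b["arc_nm"], b["angle_deg"], fil_from_dict(b["child"]))
                for b in fd.get("branches", [])
            ]
            return FilamentSpec(
                tuple(fd["axis_start"]),
                tuple(fd["axis_end"]),
                template_id=fd.get("template_id", "phf_like"),
                twist_rate=fd.get("twist_rate", -2.5),
                phase0=fd.get("phase0", 0.0),
                branches=branches,
            )

        tilts = TiltScheme(**{k: tuple(v) if k == "tilt_axis" else v
                              for k, v in d.get("tilts", {}).items()})
        return cls(
            volume_shape=tuple(d["volume_shape"]),
            voxel_size=d.get("voxel_size", 9.52),
            filaments=[fil_from_dict(f) for f in d.get("filaments", [])],
            particles=[
                CuboidParticleSpec(
                    center=tuple(p["center"]),
                    edge_lengths=tuple(p["edge_lengths"]),
                    layer_normal=tuple(p["layer_normal"]),
                    layer_spacing=p["layer_spacing"],
                    layer_contrast=p["layer_contrast"],
                )
                for p in d.get("particles", [])
            ],
            snr=d.get("snr", 1.0),
            seed=d.get("seed", 0),
            saturation_factor=d.get("saturation_factor", 3.0),
        )


@dataclass
class SimulatedTomogram:
    """Rendered noisy volume, its Fourier support mask and ground truth."""

    volume: np.ndarray
    wedge_mask: np.ndarray
    ground_truth: pd.DataFrame  # per-segment filament table
    particle_truth: pd.DataFrame  # per-cuboid table
    scene: SceneSpec


# ---------------------------------------------------------------------------
# rendering


def _check_filament_bounds(spec: FilamentSpec, scene: SceneSpec, template) -> None:
    lo = -0.5 * scene.voxel_nm
    hi = scene.extent_nm + 0.5 * scene.voxel_nm
    r = template.radius_nm
    # the cross-section disk extends r * sqrt(1 - d_i^2) along axis i
    d = spec.polarity
    reach = r * np.sqrt(np.clip(1.0 - d * d, 0.0, 1.0))
    for p in (np.asarray(spec.axis_start, float), np.asarray(spec.axis_end, float)):
        if np.any(p - reach < lo) or np.any(p + reach > hi):
            raise OutOfBoundsError(
                f"filament {spec.template_id} from {spec.axis_start} to "
                f"{spec.axis_end} (template radius {r:.1f} nm) extends outside "
                f"the {scene.extent_nm.round(1)} nm volume"
            )


def _render_filament_into(
    out: np.ndarray, spec: FilamentSpec, scene: SceneSpec, template=None
) -> None:
    template = template or get_template(spec.template_id)
    if template.pitch_a > scene.voxel_size:
        raise ValueError("template pitch must not exceed the scene voxel size")
    vox = scene.voxel_nm
    start = np.asarray(spec.axis_start, float)
    d = spec.polarity
    length = spec.length_nm
    e1, e2 = geometry.perpendicular_frame(d)
    r_nm = template.radius_nm

    # bounding box of the capsule, in voxel indices
    pts = np.array([start, start + length * d])
    lo = np.floor((pts.min(axis=0) - r_nm) / vox).astype(int)
    hi = np.ceil((pts.max(axis=0) + r_nm) / vox).astype(int)
    nz, ny, nx = out.shape
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, [nx - 1, ny - 1, nz - 1])
    if np.any(hi < lo):
        return

    xs = np.arange(lo[0], hi[0] + 1) * vox
    ys = np.arange(lo[1], hi[1] + 1) * vox
    zs = np.arange(lo[2], hi[2] + 1) * vox
    gz, gy, gx = np.meshgrid(zs, ys, xs, indexing="ij")
    rel = np.stack([gx - start[0], gy - start[1], gz - start[2]], axis=-1)
    t = rel @ d
    u = rel @ e1
    v = rel @ e2
    inside = (t >= 0) & (t <= length) & (u * u + v * v <= r_nm * r_nm)
    if not inside.any():
        return
    theta = np.radians(spec.phase0 + spec.twist_rate * t[inside])
    ut = np.cos(theta) * u[inside] + np.sin(theta) * v[inside]
    vt = -np.sin(theta) * u[inside] + np.cos(theta) * v[inside]
    vals = template.sample(ut, vt)
    sub = out[lo[2] : hi[2] + 1, lo[1] : hi[1] + 1, lo[0] : hi[0] + 1]
    np.add.at(sub, np.nonzero(inside), vals)

    for arc_nm, angle_deg, child in spec.branches:
        _render_filament_into(out, child, scene)


def render_filament(
    spec: FilamentSpec, scene: SceneSpec, allow_clip: bool = False
) -> np.ndarray:
    """Render one filament (recursively including branches) into a full grid.

    The template cross-section is swept along the axis, rotated in-plane by
    ``phase0 + twist_rate * arc``.  Raises :class:`OutOfBoundsError` if the
    filament leaves the volume, unless ``allow_clip``.
    """
    template = get_template(spec.template_id)
    if not allow_clip:
        _check_filament_bounds(spec, scene, template)
        for _, _, child in spec.branches:
            _check_filament_bounds(child, scene, get_template(child.template_id))
    out = np.zeros(scene.volume_shape, dtype=np.float64)
    _render_filament_into(out, spec, scene, template)
    return out


def render_cuboid(
    spec: CuboidParticleSpec, scene: SceneSpec, allow_clip: bool = False
) -> np.ndarray:
    """Render a striated cuboidal particle: a uniform block modulated by
    planar layers of period ``layer_spacing`` along ``layer_normal``."""
    vox = scene.voxel_nm
    if spec.layer_spacing <= 2.0 * vox:
        raise AliasingError(
            f"layer spacing {spec.layer_spacing} nm must exceed two voxels "
            f"({2 * vox:.2f} nm) to be representable"
        )
    c = np.asarray(spec.center, float)
    half = np.asarray(spec.edge_lengths, float) / 2.0
    if not allow_clip and (np.any(c - half < -0.5 * vox) or np.any(c + half > scene.extent_nm + 0.5 * vox)):
        raise OutOfBoundsError(f"cuboid at {spec.center} extends outside the volume")

    out = np.zeros(scene.volume_shape, dtype=np.float64)
    lo = np.maximum(np.floor((c - half) / vox).astype(int), 0)
    nz, ny, nx = scene.volume_shape
    hi = np.minimum(np.ceil((c + half) / vox).astype(int), [nx - 1, ny - 1, nz - 1])
    if np.any(hi < lo):
        return out
    xs = np.arange(lo[0], hi[0] + 1) * vox
    ys = np.arange(lo[1], hi[1] + 1) * vox
    zs = np.arange(lo[2], hi[2] + 1) * vox
    gz, gy, gx = np.meshgrid(zs, ys, xs, indexing="ij")
    rel = np.stack([gx - c[0], gy - c[1], gz - c[2]], axis=-1)
    inside = np.all(np.abs(rel) <= half, axis=-1)
    n = spec.unit_normal
    phase = 2.0 * np.pi * (rel @ n) / spec.layer_spacing
    block = 0.5 * inside * (1.0 + spec.layer_contrast * np.cos(phase))
    out[lo[2] : hi[2] + 1, lo[1] : hi[1] + 1, lo[0] : hi[0] + 1] = block
    return out


# ---------------------------------------------------------------------------
# missing wedge and noise


def wedge_mask(
    shape: tuple[int, int, int],
    tilts: TiltScheme = TiltScheme(),
    rotation: np.ndarray | None = None,
) -> np.ndarray:
    """Binary Fourier support implied by the tilt scheme.

    A tilt series about an axis in the x-y plane samples, for each tilt
    ``alpha``, the central plane perpendicular to the rotated beam; the union
    over ``alpha in [min, max]`` is the double wedge of frequencies whose
    in-plane angle ``atan2(k_perp, k_z)`` (``k_perp`` measured perpendicular
    to the tilt axis) lies within the tilt range.  If ``rotation`` is given
    (reference-to-volume matrix of a subvolume), the mask is evaluated on
    frequencies rotated into the volume frame, i.e. the wedge as seen by a
    subvolume that has been rotated into the reference frame.
    """
    if tilts.max_angle - tilts.min_angle >= 180.0:
        return np.ones(shape, dtype=bool)
    nz, ny, nx = shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    ky = np.fft.fftfreq(ny)[None, :, None]
    kx = np.fft.fftfreq(nx)[None, None, :]
    if rotation is not None:
        # frequency vector in the volume frame = R @ k_reference
        r = np.asarray(rotation, float)
        kx, ky, kz = (
            r[0, 0] * kx + r[0, 1] * ky + r[0, 2] * kz,
            r[1, 0] * kx + r[1, 1] * ky + r[1, 2] * kz,
            r[2, 0] * kx + r[2, 1] * ky + r[2, 2] * kz,
        )
    ax, ay = tilts.tilt_axis
    norm = np.hypot(ax, ay)
    bx, by = -ay / norm, ax / norm  # in-plane direction perpendicular to tilt axis
    k_perp = bx * kx + by * ky
    # the tilt-alpha projection samples the central plane rotated alpha away
    # from the k_z = 0 plane; the un-sampled double wedge surrounds the beam
    # (k_z) axis
    ang = np.degrees(np.arctan2(kz, k_perp))
    ang = (ang + 90.0) % 180.0 - 90.0  # fold to a line angle in (-90, 90]
    mask = (ang >= tilts.min_angle) & (ang <= tilts.max_angle)
    mask = np.broadcast_to(mask, shape).copy()
    mask[0, 0, 0] = True
    return mask


def apply_missing_wedge(
    volume: np.ndarray, tilts: TiltScheme = TiltScheme()
) -> tuple[np.ndarray, np.ndarray]:
    """Zero Fourier coefficients outside the tilt-range double wedge.

    Returns ``(filtered_volume, mask)``.  A total range >= 180 degrees
    degenerates to the identity.
    """
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume must be finite")
    mask = wedge_mask(volume.shape, tilts)
    if mask.all():
        return volume.astype(np.float64, copy=True), mask
    f = np.fft.rfftn(volume)
    nx = volume.shape[2]
    f *= mask[..., : nx // 2 + 1]
    out = np.fft.irfftn(f, s=volume.shape, axes=(0, 1, 2))
    return out, mask


def add_noise(volume: np.ndarray, snr: float, seed: int) -> np.ndarray:
    """Add zero-mean white Gaussian noise at the requested power ratio.

    ``snr`` is (signal power)/(noise power) with signal power taken as the
    mean square of ``volume``.  ``snr = inf`` returns the input unchanged.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    if np.isinf(snr):
        return volume.copy()
    power = float(np.mean(np.square(volume)))
    sigma = np.sqrt(power / snr) if power > 0 else 1.0
    rng = np.random.default_rng(seed)
    return volume + rng.normal(0.0, sigma, size=volume.shape)


# ---------------------------------------------------------------------------
# ground truth and scene assembly

GROUND_TRUTH_COLUMNS = [
    "tube_id", "template_id", "segment_index",
    "x_vox", "y_vox", "z_vox", "x_nm", "y_nm", "z_nm",
    "rot_deg", "tilt_deg", "psi_deg",
    "twist_deg_per_nm", "phase0_deg",
    "polarity_x", "polarity_y", "polarity_z",
    "track_length_vox", "length_nm", "is_branch_child", "parent_tube_id",
]


def _filament_segments(
    spec: FilamentSpec, tube_id: int, scene: SceneSpec,
    is_branch: bool = False, parent: int = -1,
) -> list[dict]:
    """Segment rows every 1 voxel along the axis (endpoint-inclusive)."""
    vox = scene.voxel_nm
    d = spec.polarity
    rot, tilt, _ = geometry.axis_to_euler(d)
    n_seg = int(np.floor(spec.length_nm / vox + 1e-9)) + 1
    rows = []
    start = np.asarray(spec.axis_start, float)
    for k in range(n_seg):
        arc = k * vox
        pos = start + arc * d
        psi = spec.phase0 + spec.twist_rate * arc
        rows.append({
            "tube_id": tube_id,
            "template_id": spec.template_id,
            "segment_index": k,
            "x_vox": pos[0] / vox, "y_vox": pos[1] / vox, "z_vox": pos[2] / vox,
            "x_nm": pos[0], "y_nm": pos[1], "z_nm": pos[2],
            "rot_deg": rot, "tilt_deg": tilt, "psi_deg": psi,
            "twist_deg_per_nm": spec.twist_rate,
            "phase0_deg": spec.phase0,
            "polarity_x": d[0], "polarity_y": d[1], "polarity_z": d[2],
            "track_length_vox": arc / vox,
            "length_nm": spec.length_nm,
            "is_branch_child": is_branch,
            "parent_tube_id": parent,
        })
    return rows


def build_scene(scene: SceneSpec) -> SimulatedTomogram:
    """Render all planted objects, apply the missing wedge, add noise.

    The ground-truth table holds one row per filament segment (centres every
    1 voxel along each axis) with true positions in voxels and nm and true
    ZYZ Euler angles; branch children get their own tube ids.
    """
    signal = np.zeros(scene.volume_shape, dtype=np.float64)
    rows: list[dict] = []
    tube_id = 1
    peak = 1.0
    for spec in scene.filaments:
        template = get_template(spec.template_id)
        peak = max(peak, float(template.density.max()))
        _check_filament_bounds(spec, scene, template)
        _render_filament_into(signal, spec, scene, template)
        rows.extend(_filament_segments(spec, tube_id, scene))
        parent_id = tube_id
        tube_id += 1
        for arc_nm, angle_deg, child in spec.branches:
            rows.extend(
                _filament_segments(child, tube_id, scene, is_branch=True, parent=parent_id)
            )
            tube_id += 1

    prows = []
    for i, p in enumerate(scene.particles):
        signal += render_cuboid(p, scene)
        prows.append({
            "particle_id": i + 1,
            "cx_nm": p.center[0], "cy_nm": p.center[1], "cz_nm": p.center[2],
            "edge_x_nm": p.edge_lengths[0], "edge_y_nm": p.edge_lengths[1],
            "edge_z_nm": p.edge_lengths[2],
            "normal_x": p.unit_normal[0], "normal_y": p.unit_normal[1],
            "normal_z": p.unit_normal[2],
            "layer_spacing_nm": p.layer_spacing,
            "layer_contrast": p.layer_contrast,
        })

    if signal.size and float(signal.max()) > scene.saturation_factor * peak:
        raise SaturationError(
            f"summed density {signal.max():.2f} exceeds the saturation bound "
            f"({scene.saturation_factor} x single-template peak {peak:.2f}); "
            "planted objects overlap too strongly"
        )

    volume, mask = apply_missing_wedge(signal, scene.tilts)
    volume = add_noise(volume, scene.snr, scene.seed)

    gt = pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)
    pt = pd.DataFrame(prows)
    return SimulatedTomogram(
        volume=volume.astype(np.float32),
        wedge_mask=mask,
        ground_truth=gt,
        particle_truth=pt,
        scene=scene,
    )


def render_template_reference(
    template_id: str,
    box: int,
    voxel_size_a: float = 9.52,
    twist_rate: float = 0.0,
    phase0: float = 0.0,
) -> np.ndarray:
    """Noiseless template filament along +z through the box centre.

    Used as the initial alignment reference and for two-reference
    classification.  An untwisted sweep is the default: over a 24-voxel box
    the twist within the box is secondary to the cross-section shape.
    """
    ref_scene = SceneSpec(volume_shape=(box, box, box), voxel_size=voxel_size_a)
    c = (box - 1) / 2.0 * ref_scene.voxel_nm
    spec = FilamentSpec(
        (c, c, 0.0),
        (c, c, (box - 1) * ref_scene.voxel_nm),
        template_id=template_id,
        twist_rate=twist_rate,
        phase0=phase0,
    )
    return render_filament(spec, ref_scene, allow_clip=True)


# ---------------------------------------------------------------------------
# canned study scenes


def _parallel_cluster(
    rng: np.random.Generator,
    n_filaments: int,
    n_opposite: int,
    template_id: str,
    twist_rate: float,
    extent_nm: np.ndarray,
    margin_nm: float,
    length_range_nm: tuple[float, float],
    jitter_deg: float = 8.0,
) -> list[FilamentSpec]:
    """Roughly parallel filament cluster with a planted polarity split.

    Filaments share a common direction up to ``jitter_deg`` of angular jitter;
    ``n_opposite`` of them run antiparallel.  Lateral positions are laid out
    on a jittered grid so that filaments do not overlap.
    """
    base = np.array([0.35, 0.25, 1.0])
    base /= np.linalg.norm(base)
    e1, e2 = geometry.perpendicular_frame(base)

    n_side = int(np.ceil(np.sqrt(n_filaments)))
    lateral_extent = min(extent_nm.min() - 2 * margin_nm, extent_nm.min() * 0.8)
    pitch = lateral_extent / max(n_side - 1, 1)
    slots = [(i, j) for i in range(n_side) for j in range(n_side)]
    rng.shuffle(slots)
    center = extent_nm / 2.0

    flipped = np.zeros(n_filaments, dtype=bool)
    flipped[rng.choice(n_filaments, size=n_opposite, replace=False)] = True

    specs = []
    for k in range(n_filaments):
        i, j = slots[k]
        off1 = (i - (n_side - 1) / 2.0) * pitch + rng.uniform(-0.15, 0.15) * pitch
        off2 = (j - (n_side - 1) / 2.0) * pitch + rng.uniform(-0.15, 0.15) * pitch
        mid = center + off1 * e1 + off2 * e2
        # keep at least ~6 nm of axial room so every filament has real length
        mid = np.clip(mid, margin_nm + 6.0, extent_nm - margin_nm - 6.0)
        # small angular jitter about the cluster direction
        tilt = np.radians(rng.uniform(0, jitter_deg))
        az = rng.uniform(0, 2 * np.pi)
        d = (
            np.cos(tilt) * base
            + np.sin(tilt) * (np.cos(az) * e1 + np.sin(az) * e2)
        )
        if flipped[k]:
            d = -d
        length = rng.uniform(*length_range_nm)
        # clip the half-length so the capsule stays inside the volume
        half = length / 2.0
        half_max = half
        for ax in range(3):
            if abs(d[ax]) > 1e-9:
                room = min(mid[ax] - margin_nm, extent_nm[ax] - margin_nm - mid[ax])
                half_max = min(half_max, room / abs(d[ax]))
        half = max(min(half, half_max), min(12.0, half_max))
        specs.append(
            FilamentSpec(
                tuple(mid - half * d),
                tuple(mid + half * d),
                template_id=template_id,
                twist_rate=twist_rate,
                phase0=float(rng.uniform(0, 360)),
            )
        )
    return specs


def standard_test_scene(
    seed: int = 7,
    n_filaments: int = 40,
    n_opposite: int = 6,
    shape: tuple[int, int, int] = (200, 200, 200),
    voxel_size: float = 9.52,
    twist_rate: float = -2.5,
    snr: float = 1.0,
    template_id: str = "phf_like",
) -> SceneSpec:
    """The standard parameter-recovery scene: a parallel cluster of 40
    PHF-like filaments with a 34/6 polarity split, 2.5 degree/nm twist,
    snr 1, in a 200^3 volume of 9.52 angstrom voxels."""
    rng = np.random.default_rng(seed)
    scene = SceneSpec(volume_shape=shape, voxel_size=voxel_size, snr=snr, seed=seed)
    scene.filaments = _parallel_cluster(
        rng,
        n_filaments,
        n_opposite,
        template_id,
        twist_rate,
        scene.extent_nm,
        margin_nm=get_template(template_id).radius_nm + 1.0,
        length_range_nm=(60.0, 110.0),
    )
    return scene


def mixed_class_scene(
    seed: int = 0,
    n_each: int = 6,
    shape: tuple[int, int, int] = (128, 128, 128),
    snr: float = 0.5,
) -> SceneSpec:
    """A mixed PHF-like / SF-like cluster for two-reference classification."""
    rng = np.random.default_rng(seed)
    scene = SceneSpec(volume_shape=shape, voxel_size=9.52, snr=snr, seed=seed)
    margin = get_template("phf_like").radius_nm + 1.0
    specs = _parallel_cluster(
        rng, 2 * n_each, 0, "phf_like", -2.5, scene.extent_nm,
        margin_nm=margin, length_range_nm=(50.0, 80.0),
    )
    order = rng.permutation(2 * n_each)
    for idx in order[n_each:]:
        f = specs[idx]
        specs[idx] = FilamentSpec(
            f.axis_start, f.axis_end, template_id="sf_like",
            twist_rate=-2.2, phase0=f.phase0,
        )
    scene.filaments = specs
    return scene
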