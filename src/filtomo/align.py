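"""Missing-wedge-aware subvolume alignment and averaging.

The alignment score is wedge-constrained normalized cross-correlation:
Fourier coefficients outside the subvolume's (rotated) double-wedge support
are excluded from both the numerator and the normalisation, so a subvolume
is never rewarded for matching the reference inside the region Fourier
space never sampled.

``align_iterate`` implements the two search modes used for filament
subtomogram averaging:

* ``restricted`` — only the spin about the filament axis (plus the
  head/tail flip resolving unknown polarity) and translations along the
  axis are searched.  This is the standard first stage for filaments, which
  avoids aligning to the missing wedge.
* ``full`` — all three Euler angles within a local search range and
  translations within a box.

Each segment is rotated once per iteration into the reference frame; search
candidates are then realised by rotating the (single) reference, so the
cost is ``O(n_segments + n_candidates)`` volume interpolations per
iteration, with all correlation scores computed in Fourier space.
Averaging is wedge-weighted: Fourier components are accumulated with their
per-segment wedge coverage and divided by the summed coverage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import geometry
from .fsc import soft_cylinder_mask
from .helix import HelicalParams
from .picking import ParticleTable, SegmentRecord
from .scene import TiltScheme, wedge_mask

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentParams",
    "AverageMap",
    "SubvolumeStack",
    "extract_subvolumes",
    "constrained_cc",
    "align_iterate",
    "average_map",
    "helical_symmetrize",
    "classify_two_references",
]


@dataclass
class AlignmentParams:
    """Search-space and schedule parameters for iterative alignment.

    The box/voxel schedules default to the 24^3 @ 9.52 A -> 48^3 @ 4.76 A
    -> 96^3 @ 2.38 A ladder; a single ``align_iterate`` call runs one stage.
    """

    box_sizes: tuple = (24, 48, 96)
    voxel_sizes: tuple = (9.52, 4.76, 2.38)
    psi_step_deg: float = 12.0  # spin grid step (restricted mode)
    full_step_deg: float = 6.0  # per-angle step (full mode)
    full_range_deg: float = 6.0  # per-angle half-range (full mode)
    translation_limit_vox: float = 3.0
    mask_radius_vox: float = 9.0
    mask_edge_vox: float = 2.0
    max_iterations: int = 6
    tol: float = 0.25  # mean parameter change (deg + vox)
    search_flips: bool = True
    # decide the polarity flip per filament (summing score evidence over its
    # segments) rather than per segment: polarity is a per-filament property
    tube_flip_consistency: bool = True
    half_set_split: str = "tube_parity"  # or "random"
    split_seed: int = 0

    def __post_init__(self):
        if len(self.box_sizes) != len(self.voxel_sizes):
            raise ValueError("box_sizes and voxel_sizes schedules must have equal length")
        if self.psi_step_deg <= 0 or self.full_step_deg <= 0:
            raise ValueError("angular steps must be positive")
        if self.mask_edge_vox < 1:
            raise ValueError("mask soft-edge width must be >= 1 voxel")


@dataclass
class AverageMap:
    """Aligned average with its two independently averaged half-maps."""

    map: np.ndarray
    half_map_a: np.ndarray
    half_map_b: np.ndarray
    n_contributing: int
    mask: np.ndarray | None = None
    voxel_size_a: float = 9.52


@dataclass
class SubvolumeStack:
    data: np.ndarray  # (n, box, box, box)
    kept_indices: np.ndarray  # indices into the source table
    n_skipped: int

    def __len__(self):
        return len(self.data)


def extract_subvolumes(volume: np.ndarray, table: ParticleTable, box: int) -> SubvolumeStack:
    """Extract box^3 subvolumes centred on each record position.

    Records whose box would leave the volume are skipped (counted and
    logged); positions are rounded to the nearest voxel.
    """
    if any(box > s for s in volume.shape):
        raise ValueError(f"box {box} larger than volume {volume.shape}")
    half = box // 2
    subs, kept = [], []
    n_skip = 0
    nz, ny, nx = volume.shape
    for i, rec in enumerate(table.records):
        cx, cy, cz = (int(round(c)) for c in rec.position)
        if (
            cx - half < 0 or cx - half + box > nx
            or cy - half < 0 or cy - half + box > ny
            or cz - half < 0 or cz - half + box > nz
        ):
            n_skip += 1
            continue
        subs.append(
            volume[cz - half : cz - half + box,
                   cy - half : cy - half + box,
                   cx - half : cx - half + box]
        )
        kept.append(i)
    if n_skip:
        logger.info("extract_subvolumes: skipped %d of %d records at the volume edge",
                    n_skip, len(table.records))
    data = np.stack(subs) if subs else np.zeros((0, box, box, box))
    return SubvolumeStack(
        data=np.ascontiguousarray(data, dtype=np.float64),
        kept_indices=np.asarray(kept, dtype=int),
        n_skipped=n_skip,
    )


# ---------------------------------------------------------------------------
# wedge-constrained correlation


def constrained_cc(a: np.ndarray, b: np.ndarray, wedge: np.ndarray | None = None) -> float:
    """Normalized cross-correlation over the shared Fourier wedge support.

    The DC term is excluded (equivalent to mean subtraction); with a full
    wedge this reduces to plain centred normalized cross-correlation.
    """
    if a.shape != b.shape:
        raise ValueError("volumes must have equal shapes")
    fa = np.fft.fftn(a)
    fb = np.fft.fftn(b)
    if wedge is not None:
        if wedge.shape != a.shape:
            raise ValueError("wedge mask must match volume shape")
        m = wedge.astype(bool).copy()
    else:
        m = np.ones(a.shape, dtype=bool)
    m.flat[0] = False  # drop DC
    if not m.any():
        raise ValueError("empty shared wedge support: score undefined")
    num = float(np.sum(np.real(fa[m] * np.conj(fb[m]))))
    na = float(np.sum(np.abs(fa[m]) ** 2))
    nb = float(np.sum(np.abs(fb[m]) ** 2))
    if na == 0 or nb == 0:
        raise ValueError("zero-power volume inside the wedge support")
    return num / np.sqrt(na * nb)


# ---------------------------------------------------------------------------
# rotation helpers (volumes are indexed [z, y, x]; rotations act on (x, y, z))


def _affine_rotate(vol: np.ndarray, rot: np.ndarray, order: int = 1) -> np.ndarray:
    """Resample ``vol`` so that ``out(x) = vol(R x)`` about the box centre.

    ``rot`` maps (x, y, z) output coordinates to input coordinates.
    """
    # convert the xyz matrix to zyx index convention: index i <-> axis (2 - i)
    m = rot[::-1, ::-1]
    center = (np.asarray(vol.shape) - 1) / 2.0
    offset = center - m @ center
    return ndimage.affine_transform(
        vol, m, offset=offset, order=order, mode="constant", cval=0.0
    )


def _fourier_shift(f: np.ndarray, shift_xyz: np.ndarray) -> np.ndarray:
    """Apply a real-space shift (x, y, z voxels) as a Fourier phase ramp."""
    nz, ny, nx = f.shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    ky = np.fft.fftfreq(ny)[None, :, None]
    kx = np.fft.fftfreq(nx)[None, None, :]
    sx, sy, sz = shift_xyz
    return f * np.exp(-2j * np.pi * (kx * sx + ky * sy + kz * sz))


def _shift_index_grid(box: int) -> np.ndarray:
    """Signed integer shifts corresponding to fft layout indices."""
    s = np.fft.fftfreq(box, d=1.0 / box).astype(int)
    return s


def _allowed_shift_mask(box: int, limit: float, axis_only: bool) -> np.ndarray:
    s = _shift_index_grid(box)
    sz = s[:, None, None]
    sy = s[None, :, None]
    sx = s[None, None, :]
    if axis_only:
        return (np.abs(sz) <= limit) & (sy == 0) & (sx == 0)
    return (np.abs(sz) <= limit) & (np.abs(sy) <= limit) & (np.abs(sx) <= limit)


def _best_shift_refined(
    corr: np.ndarray, shift_ok: np.ndarray, sgrid: np.ndarray
) -> tuple[float, np.ndarray]:
    """Best translation of one correlation map, with sub-voxel refinement.

    Returns the parabolically refined peak value and the fractional (x, y, z)
    shift.  Integer-only scoring systematically favours candidates whose
    residual centring happens to be near-integer; the separable quadratic
    fit around the peak removes that bias.
    """
    box = corr.shape[0]
    masked = np.where(shift_ok, corr, -np.inf)
    k = np.unravel_index(int(np.argmax(masked)), corr.shape)
    v0 = float(corr[k])
    value = v0
    frac = np.zeros(3)
    for ax in range(3):
        km = list(k)
        kp = list(k)
        km[ax] = (k[ax] - 1) % box
        kp[ax] = (k[ax] + 1) % box
        ym, yp = float(corr[tuple(km)]), float(corr[tuple(kp)])
        den = ym - 2.0 * v0 + yp
        # refine only where the peak is a genuine local maximum along the
        # axis; on a constrained ridge the parabola would extrapolate wildly
        if den < 0 and ym <= v0 and yp <= v0:
            value += -((ym - yp) ** 2) / (8.0 * den)
            frac[ax] = 0.5 * (ym - yp) / den
    # frac is in (z, y, x) index order; convert to (x, y, z)
    delta = np.array([
        sgrid[k[2]] + frac[2], sgrid[k[1]] + frac[1], sgrid[k[0]] + frac[0]
    ])
    return value, delta


def _candidate_offsets(params: AlignmentParams, mode: str) -> tuple[list[np.ndarray], list[dict]]:
    """Rotation-offset candidates (reference-frame) and their descriptors."""
    offsets, meta = [], []
    flips = (False, True) if params.search_flips else (False,)
    if mode == "restricted":
        psis = np.arange(0.0, 360.0, params.psi_step_deg)
        for flip in flips:
            for psi in psis:
                m = geometry.rotz(psi)
                if flip:
                    m = geometry.FLIP_MATRIX @ m
                offsets.append(m)
                meta.append({"flip": flip, "psi": psi, "rot": 0.0, "tilt": 0.0})
    elif mode == "full":
        grid = np.arange(-params.full_range_deg, params.full_range_deg + 1e-9,
                         params.full_step_deg)
        for flip in flips:
            for rot in grid:
                for tilt in grid:
                    for psi in grid:
                        m = (
                            geometry.euler_to_matrix(rot, tilt, psi)
                        )
                        if flip:
                            m = geometry.FLIP_MATRIX @ m
                        offsets.append(m)
                        meta.append({"flip": flip, "psi": psi, "rot": rot, "tilt": tilt})
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'restricted' or 'full'")
    return offsets, meta


def _segment_frames(table: ParticleTable, kept: np.ndarray):
    return [geometry.euler_to_matrix(*table.records[i].euler) for i in kept]


def average_map(
    stack: SubvolumeStack,
    table: ParticleTable,
    tilts: TiltScheme | None = None,
    params: AlignmentParams | None = None,
    shifts_vox: np.ndarray | None = None,
) -> AverageMap:
    """Wedge-weighted average of the stack under the table's orientations.

    Half sets are whole filaments (tubes), never split within a filament, so
    the half-map FSC is not inflated by intra-filament correlation; the
    default split is odd/even tube id.
    """
    params = params or AlignmentParams()
    box = stack.data.shape[1]
    rots = _segment_frames(table, stack.kept_indices)
    tube_ids = np.array([table.records[i].tube_id for i in stack.kept_indices])
    if params.half_set_split == "random":
        rng = np.random.default_rng(params.split_seed)
        tubes = np.unique(tube_ids)
        half_a_tubes = set(rng.choice(tubes, size=len(tubes) // 2, replace=False).tolist())
        in_a = np.array([t in half_a_tubes for t in tube_ids])
    else:
        in_a = tube_ids % 2 == 1
    f_sum = {True: np.zeros((box,) * 3, np.complex128), False: np.zeros((box,) * 3, np.complex128)}
    w_sum = {True: np.zeros((box,) * 3), False: np.zeros((box,) * 3)}
    for i, (vol, rot) in enumerate(zip(stack.data, rots)):
        v = vol
        if shifts_vox is not None and np.any(shifts_vox[i]):
            f = _fourier_shift(np.fft.fftn(vol), -shifts_vox[i])
            v = np.real(np.fft.ifftn(f))
        aligned = _affine_rotate(v, rot)
        w = wedge_mask((box,) * 3, tilts, rotation=rot) if tilts is not None \
            else np.ones((box,) * 3, bool)
        f_sum[bool(in_a[i])] += np.fft.fftn(aligned) * w
        w_sum[bool(in_a[i])] += w
    halves = {}
    for key in (True, False):
        denom = np.maximum(w_sum[key], 1.0)
        halves[key] = np.real(np.fft.ifftn(f_sum[key] / denom))
    avg = 0.5 * (halves[True] + halves[False])
    if not in_a.any() or in_a.all():  # degenerate split: single half
        avg = halves[bool(in_a.any())]
    return AverageMap(
        map=avg,
        half_map_a=halves[True],
        half_map_b=halves[False],
        n_contributing=len(stack),
        mask=None,
        voxel_size_a=table.voxel_size_a,
    )


def align_iterate(
    stack: SubvolumeStack,
    table: ParticleTable,
    params: AlignmentParams | None = None,
    mode: str = "restricted",
    tilts: TiltScheme | None = None,
    reference: np.ndarray | None = None,
) -> tuple[ParticleTable, AverageMap]:
    """Iteratively refine orientations/positions and re-average.

    ``reference`` seeds the first iteration (e.g. a rendered template or a
    previous-stage average); afterwards the reference is always the current
    wedge-weighted average with the soft cylindrical mask applied.  Returns
    the refined table (all records; skipped ones untouched) and the final
    average.  With ``max_iterations = 0`` the input table is returned
    unchanged alongside the average under the current parameters.
    """
    import dataclasses as _dc

    params = params or AlignmentParams()
    if len(stack) == 0:
        raise ValueError("empty subvolume stack")
    box = stack.data.shape[1]
    cyl = soft_cylinder_mask((box,) * 3, params.mask_radius_vox, params.mask_edge_vox)

    work = ParticleTable(
        records=[_dc.replace(r) for r in table.records],
        voxel_size_a=table.voxel_size_a,
        volume_shape=table.volume_shape,
    )
    kept = stack.kept_indices
    # displacement of each particle centre from its extraction centre (x, y, z)
    ext_center = np.array(
        [np.round(np.asarray(table.records[i].position)) for i in kept]
    )
    shifts = np.array(
        [np.asarray(table.records[i].position) for i in kept]
    ) - ext_center

    offsets, meta = _candidate_offsets(params, mode)
    shift_ok = _allowed_shift_mask(box, params.translation_limit_vox,
                                   axis_only=(mode == "restricted"))
    sgrid = _shift_index_grid(box)

    if params.max_iterations == 0:
        avg = average_map(stack, work, tilts, params, shifts)
        avg.mask = cyl
        return work, avg

    prev_change = np.inf
    grow_count = 0
    best_state = None
    for iteration in range(params.max_iterations):
        if iteration == 0 and reference is not None:
            ref = reference
        else:
            ref = average_map(stack, work, tilts, params, shifts).map
        ref = ref * cyl
        # candidate c hypothesises particle orientation R_seg @ offsets[c]; the
        # z-aligned segment then matches the reference resampled through the
        # inverse offset rotation
        f_refs = np.stack([np.fft.fftn(_affine_rotate(ref, m.T)) for m in offsets])
        f_refs[:, 0, 0, 0] = 0.0
        ref_pow = np.abs(f_refs) ** 2

        rots = _segment_frames(work, kept)
        flip_flags = np.array([m["flip"] for m in meta])
        classes = [False, True] if params.search_flips else [False]
        # per segment and flip class: (score, candidate index, shift)
        seg_best: list[dict] = []
        for i, rot in enumerate(rots):
            vol = stack.data[i]
            aligned = _affine_rotate(vol, rot)
            w = (
                wedge_mask((box,) * 3, tilts, rotation=rot).astype(np.float64)
                if tilts is not None else np.ones((box,) * 3)
            )
            f_seg = np.fft.fftn(aligned)
            f_seg.flat[0] = 0.0
            f_seg *= w
            seg_norm = np.sqrt(np.sum(np.abs(f_seg) ** 2))
            if seg_norm == 0:
                seg_best.append({})
                continue
            # cross-correlation maps over all candidates at once
            g = np.conj(f_refs) * f_seg[None]
            corr = np.fft.ifftn(g, axes=(1, 2, 3)).real * (box**3)
            ref_norms = np.sqrt(np.einsum("cijk,ijk->c", ref_pow, w))
            ref_norms = np.maximum(ref_norms, 1e-30)
            corr /= (ref_norms[:, None, None, None] * seg_norm)
            refined = np.empty(len(offsets))
            deltas = np.empty((len(offsets), 3))
            for c in range(len(offsets)):
                refined[c], deltas[c] = _best_shift_refined(corr[c], shift_ok, sgrid)
            entry = {}
            for cls in classes:
                sel = np.nonzero(flip_flags == cls)[0]
                c = sel[int(np.argmax(refined[sel]))]
                entry[cls] = (float(refined[c]), int(c), deltas[c])
            seg_best.append(entry)

        # choose the flip class: per filament (summed evidence) or per segment
        tube_ids_kept = np.array([work.records[i].tube_id for i in kept])
        chosen_cls = np.zeros(len(kept), dtype=bool)
        if params.search_flips:
            if params.tube_flip_consistency:
                for tube in np.unique(tube_ids_kept):
                    idx = np.nonzero(tube_ids_kept == tube)[0]
                    evidence = {
                        cls: sum(seg_best[i][cls][0] for i in idx if seg_best[i])
                        for cls in classes
                    }
                    chosen_cls[idx] = evidence[True] > evidence[False]
            else:
                for i in range(len(kept)):
                    if seg_best[i]:
                        chosen_cls[i] = seg_best[i][True][0] > seg_best[i][False][0]

        changes = []
        for i, rot in enumerate(rots):
            if not seg_best[i]:
                changes.append(0.0)
                continue
            _, best_c, delta_seg = seg_best[i][bool(chosen_cls[i])]
            rec = work.records[kept[i]]
            new_rot = rot @ offsets[best_c]
            delta_vol = rot @ delta_seg
            ang_change = geometry.angular_distance_deg(rot, new_rot)
            # a pure polarity flip is not 'movement' for convergence purposes
            if meta[best_c]["flip"]:
                ang_change = geometry.angular_distance_deg(
                    rot @ geometry.FLIP_MATRIX, new_rot
                )
            changes.append(ang_change + float(np.linalg.norm(delta_vol - shifts[i])))
            rec.euler = geometry.matrix_to_euler(new_rot)
            rec.position = tuple(ext_center[i] + delta_vol)
            shifts[i] = delta_vol

        mean_change = float(np.mean(changes)) if changes else 0.0
        logger.info("align_iterate[%s] iter %d: mean parameter change %.3f",
                    mode, iteration, mean_change)
        if mean_change > prev_change:
            grow_count += 1
            if grow_count >= 3:
                warnings.warn("alignment diverging; returning best-so-far result")
                eulers, positions, shifts = best_state
                for j, i in enumerate(kept):
                    work.records[i].euler = eulers[j]
                    work.records[i].position = positions[j]
                break
        else:
            grow_count = 0
            best_state = (
                [work.records[i].euler for i in kept],
                [work.records[i].position for i in kept],
                shifts.copy(),
            )
        prev_change = mean_change
        if mean_change < params.tol:
            break

    avg = average_map(stack, work, tilts, params, shifts)
    avg.mask = cyl
    return work, avg


# ---------------------------------------------------------------------------
# helical symmetrisation


def helical_symmetrize(
    vol: np.ndarray,
    helix: HelicalParams,
    n_copies: int = 2,
    voxel_size_a: float = 9.52,
) -> np.ndarray:
    """Average the map over helical symmetry copies.

    Copies ``j = -n..n`` are rotated about z by ``j * twist_per_subunit``
    degrees and shifted along z by ``j * rise`` angstrom; if the helix has
    in-plane symmetry (e.g. C2), those rotations are averaged in as well.
    The filament axis must be the map z axis.
    """
    if helix.twist_per_subunit is None or helix.rise is None:
        raise ValueError("helix must define twist_per_subunit and rise")
    if helix.rise < voxel_size_a / 4.0:
        warnings.warn(
            f"rise {helix.rise} A is below a quarter voxel ({voxel_size_a} A): "
            "symmetrisation is resampling-limited"
        )
    out = np.zeros_like(vol, dtype=np.float64)
    count = 0
    rise_vox = helix.rise / voxel_size_a
    for j in range(-n_copies, n_copies + 1):
        rot = geometry.rotz(j * helix.twist_per_subunit)
        shifted = ndimage.shift(vol, (j * rise_vox, 0, 0), order=3, mode="nearest")
        out += _affine_rotate(shifted, rot, order=3)
        count += 1
    out /= count
    if helix.symmetry_order > 1:
        sym = np.zeros_like(out)
        for s in range(helix.symmetry_order):
            sym += _affine_rotate(
                out, geometry.rotz(360.0 * s / helix.symmetry_order), order=3
            )
        out = sym / helix.symmetry_order
    return out


# ---------------------------------------------------------------------------
# two-reference classification


def classify_two_references(
    stack: SubvolumeStack,
    table: ParticleTable,
    refs: dict,
    params: AlignmentParams | None = None,
    tilts: TiltScheme | None = None,
):
    """Assign each filament to the best-matching of two references.

    Each segment is locally aligned (spin + flip + axial shift) against each
    reference; the per-segment label is the reference with the higher
    wedge-constrained correlation, and the per-filament label the majority
    of its segments ('ambiguous' on an exact tie).  Returns
    ``(per_filament: dict, per_segment: np.ndarray of labels)``.
    """
    params = params or AlignmentParams()
    names = list(refs)
    if len(names) != 2:
        raise ValueError("exactly two references required")
    if np.allclose(refs[names[0]], refs[names[1]]):
        raise ValueError("degenerate classification: references are identical")
    box = stack.data.shape[1]
    cyl = soft_cylinder_mask((box,) * 3, params.mask_radius_vox, params.mask_edge_vox)
    offsets, _ = _candidate_offsets(params, "restricted")
    shift_ok = _allowed_shift_mask(box, params.translation_limit_vox, axis_only=True)

    f_refs_by_name = {}
    pow_by_name = {}
    for name in names:
        fr = np.stack(
            [np.fft.fftn(_affine_rotate(refs[name] * cyl, m.T)) for m in offsets]
        )
        fr[:, 0, 0, 0] = 0.0
        f_refs_by_name[name] = fr
        pow_by_name[name] = np.abs(fr) ** 2

    rots = _segment_frames(table, stack.kept_indices)
    seg_labels = []
    for i, rot in enumerate(rots):
        aligned = _affine_rotate(stack.data[i], rot)
        w = (
            wedge_mask((box,) * 3, tilts, rotation=rot).astype(np.float64)
            if tilts is not None else np.ones((box,) * 3)
        )
        f_seg = np.fft.fftn(aligned)
        f_seg.flat[0] = 0.0
        f_seg *= w
        seg_norm = max(np.sqrt(np.sum(np.abs(f_seg) ** 2)), 1e-30)
        scores = {}
        sgrid = _shift_index_grid(box)
        for name in names:
            g = np.conj(f_refs_by_name[name]) * f_seg[None]
            corr = np.fft.ifftn(g, axes=(1, 2, 3)).real * (box**3)
            ref_norms = np.maximum(
                np.sqrt(np.einsum("cijk,ijk->c", pow_by_name[name], w)), 1e-30
            )
            corr /= (ref_norms[:, None, None, None] * seg_norm)
            scores[name] = max(
                _best_shift_refined(corr[c], shift_ok, sgrid)[0]
                for c in range(corr.shape[0])
            )
        seg_labels.append(max(names, key=lambda n: scores[n]))
    seg_labels = np.asarray(seg_labels)

    per_filament = {}
    tube_ids = np.array([table.records[i].tube_id for i in stack.kept_indices])
    for tube in np.unique(tube_ids):
        labels = seg_labels[tube_ids == tube]
        c0 = int(np.sum(labels == names[0]))
        c1 = int(np.sum(labels == names[1]))
        if c0 > c1:
            per_filament[int(tube)] = names[0]
        elif c1 > c0:
            per_filament[int(tube)] = names[1]
        else:
            per_filament[int(tube)] = "ambiguous"
    return per_filament, seg_labels
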