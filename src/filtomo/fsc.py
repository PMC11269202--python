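"""Fourier shell correlation between two half-maps.

The global resolution is read off at the first downward crossing of the
0.143 threshold (gold-standard half-map convention), with linear
interpolation between shells.  If the curve never crosses, Nyquist (twice
the voxel size) is reported and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FSC_THRESHOLD = 0.143


@dataclass
class FscCurve:
    shell_freq: np.ndarray  # shell centres, 1/angstrom
    values: np.ndarray  # per-shell correlation
    voxel_size_a: float
    threshold: float = FSC_THRESHOLD
    resolution_a: float = np.nan  # at the threshold
    crossed: bool = True  # False when the curve never drops below threshold

    def resolution_at(self, threshold: float) -> tuple[float, bool]:
        return _threshold_resolution(self.shell_freq, self.values, threshold,
                                     self.voxel_size_a)


def _threshold_resolution(freq, values, threshold, voxel_size_a):
    nyquist_res = 2.0 * voxel_size_a
    below = np.nonzero(values < threshold)[0]
    # ignore a sub-threshold first shell (pathological); look for the first
    # downward crossing after a super-threshold shell
    for i in below:
        if i == 0:
            continue
        v0, v1 = values[i - 1], values[i]
        if v0 >= threshold:
            f0, f1 = freq[i - 1], freq[i]
            f = f0 + (v0 - threshold) / (v0 - v1) * (f1 - f0)
            return float(1.0 / f), True
    return nyquist_res, False


def fsc(
    half_a: np.ndarray,
    half_b: np.ndarray,
    mask: np.ndarray | None = None,
    voxel_size_a: float = 1.0,
    threshold: float = FSC_THRESHOLD,
) -> FscCurve:
    """Per-shell correlation between two maps (optionally masked first)."""
    if half_a.shape != half_b.shape:
        raise ValueError("half maps must have equal shapes")
    if not half_a.any() or not half_b.any():
        raise ValueError("FSC undefined for an all-zero half map")
    a = np.asarray(half_a, np.float64)
    b = np.asarray(half_b, np.float64)
    if mask is not None:
        a = a * mask
        b = b * mask
    fa = np.fft.fftn(a)
    fb = np.fft.fftn(b)
    shape = a.shape
    grids = np.meshgrid(*[np.fft.fftfreq(n) for n in shape], indexing="ij")
    kmag = np.sqrt(sum(g * g for g in grids))
    n_half = min(shape) // 2
    # shells of unit width in integer frequency of the smallest dimension
    shell_idx = np.minimum((kmag * min(shape)).astype(int), n_half)
    num = np.real(fa * np.conj(fb)).ravel()
    pa = np.abs(fa).ravel() ** 2
    pb = np.abs(fb).ravel() ** 2
    flat_idx = shell_idx.ravel()
    sums = np.bincount(flat_idx, weights=num, minlength=n_half + 1)
    sa = np.bincount(flat_idx, weights=pa, minlength=n_half + 1)
    sb = np.bincount(flat_idx, weights=pb, minlength=n_half + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = sums / np.sqrt(sa * sb)
    vals = np.nan_to_num(vals[: n_half + 1], nan=0.0)
    freq = np.arange(n_half + 1) / (min(shape) * voxel_size_a)
    res, crossed = _threshold_resolution(freq[1:], vals[1:], threshold, voxel_size_a)
    return FscCurve(
        shell_freq=freq[1:],
        values=vals[1:],
        voxel_size_a=voxel_size_a,
        threshold=threshold,
        resolution_a=res,
        crossed=crossed,
    )


def soft_sphere_mask(shape, radius_vox: float, edge_width_vox: float = 3.0) -> np.ndarray:
    """Soft-edged (raised-cosine) central sphere mask."""
    grids = np.meshgrid(*[np.arange(n) - (n - 1) / 2.0 for n in shape], indexing="ij")
    r = np.sqrt(sum(g * g for g in grids))
    m = np.clip((radius_vox + edge_width_vox - r) / edge_width_vox, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * m)


def soft_cylinder_mask(
    shape, radius_vox: float, edge_width_vox: float = 2.0,
    cap_vox: float | None = None,
) -> np.ndarray:
    """Soft-edged cylinder along z, used to mask filament references.

    ``cap_vox``: optional axial half-height before the soft cap; defaults to
    the full box.
    """
    nz = shape[0]
    grids = np.meshgrid(*[np.arange(n) - (n - 1) / 2.0 for n in shape], indexing="ij")
    r = np.sqrt(grids[1] ** 2 + grids[2] ** 2)
    m = np.clip((radius_vox + edge_width_vox - r) / edge_width_vox, 0.0, 1.0)
    mask = 0.5 - 0.5 * np.cos(np.pi * m)
    if cap_vox is not None:
        zm = np.clip((cap_vox + edge_width_vox - np.abs(grids[0])) / edge_width_vox, 0.0, 1.0)
        mask = mask * (0.5 - 0.5 * np.cos(np.pi * zm))
    return mask
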