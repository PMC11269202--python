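"""Helical twist algebra, twist measurement, polarity statistics.

Crossover convention: the crossover distance is the axial repeat of the
*apparent* (projected) cross-section, i.e. 180 degrees of twist, for every
template family; so ``crossover_nm * twist_deg_per_nm = 180``.  Printed
crossovers are unsigned and twists are reported as magnitudes (the sign
encodes handedness and is kept only in scene specifications).  Callers who
want the full-turn (360 degree) repeat for templates without in-plane C2
can ask for it explicitly.

The polarity test is the exact one-sided binomial tail on the majority
orientation count within a filament cluster, with p = 1/2 and no
multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from . import geometry

__all__ = [
    "HelicalParams",
    "TwistMeasurement",
    "ClusterPolaritySummary",
    "twist_from_crossover",
    "crossover_from_twist",
    "percent_twist_reduction",
    "measure_twist_from_average",
    "assign_polarity",
    "summarize_cluster_polarity",
    "binomial_tail",
]


@dataclass
class HelicalParams:
    """Helical symmetry description.

    ``twist_per_nm`` (degrees per nm) and ``crossover`` (nm) are linked by the
    half-turn convention ``crossover = 180 / twist_per_nm``; ``twist_per_subunit``
    (degrees) and ``rise`` (angstrom) describe the subunit lattice, with
    ``twist_per_nm = effective_twist_per_subunit * 10 / rise`` where the
    effective twist folds out the pseudo-2(1) screw of paired protofilaments
    (e.g. 179.44 degrees per 2.405 angstrom rise is an apparent twist of
    |180 - 179.44| ... handled by the caller; this container stores values
    as given).
    """

    twist_per_nm: float | None = None  # degrees per nm (unsigned)
    twist_per_subunit: float | None = None  # degrees
    rise: float | None = None  # angstrom
    symmetry_order: int = 1

    @property
    def crossover(self) -> float:
        """Crossover distance in nm (180-degree repeat)."""
        if self.twist_per_nm is None:
            raise ValueError("twist_per_nm not set")
        return crossover_from_twist(self.twist_per_nm)


@dataclass
class TwistMeasurement:
    crossover_nm: float
    twist_deg_per_nm: float
    method: str  # from_average_rotation_fit | from_crossover_distance
    fit_residual_deg: float = 0.0

    def __post_init__(self):
        if np.isfinite(self.crossover_nm) and self.twist_deg_per_nm > 0:
            prod = self.crossover_nm * self.twist_deg_per_nm
            assert abs(prod - 180.0) < 1e-6 * 180.0, prod


@dataclass
class ClusterPolaritySummary:
    cluster_id: str
    n: int  # all filaments in the cluster
    k_majority: int
    k_minority: int
    ambiguous_count: int
    reference_direction: tuple[float, float, float]
    p_value: float
    flagged: bool = False  # too few filaments for a meaningful test
    labels: pd.DataFrame | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# twist algebra

HALF_TURN_DEG = 180.0


def twist_from_crossover(crossover_nm: float, full_turn: bool = False) -> float:
    """Twist rate (degrees per nm) from a crossover distance (nm)."""
    if not crossover_nm > 0:
        raise ValueError("crossover must be positive")
    repeat = 360.0 if full_turn else HALF_TURN_DEG
    return repeat / crossover_nm


def crossover_from_twist(twist_deg_per_nm: float, full_turn: bool = False) -> float:
    """Crossover distance (nm) from a twist rate (degrees per nm).

    A zero twist gives an infinite crossover (untwisted filament).
    """
    if twist_deg_per_nm < 0:
        raise ValueError("twist must be unsigned (use magnitude)")
    if twist_deg_per_nm == 0:
        return np.inf
    repeat = 360.0 if full_turn else HALF_TURN_DEG
    return repeat / twist_deg_per_nm


def percent_twist_reduction(crossover_in_situ_nm: float, crossover_ex_vivo_nm: float) -> float:
    """How much less twisted an in-situ filament is than an ex vivo one.

    Longer crossover = less twist; returns
    ``100 * (1 - crossover_ex_vivo / crossover_in_situ)``.
    """
    if crossover_in_situ_nm <= 0 or crossover_ex_vivo_nm <= 0:
        raise ValueError("crossover distances must be positive")
    value = 100.0 * (1.0 - crossover_ex_vivo_nm / crossover_in_situ_nm)
    if value <= -100.0:
        raise ValueError("twist reduction below -100%: inputs are implausible")
    return value


# ---------------------------------------------------------------------------
# twist from an average map


class UnmeasurableTwistError(ValueError):
    """Cross-section has no principal axis (isotropic)."""


def _slice_orientation(sl: np.ndarray) -> tuple[float, float]:
    """In-plane orientation (deg, mod 180) of the principal second-moment
    axis of a 2D slice, and its anisotropy ratio."""
    w = np.clip(sl - 0.5 * sl.max(), 0.0, None) if sl.max() > 0 else sl * 0
    tot = w.sum()
    if tot <= 0:
        return np.nan, 0.0
    ny, nx = sl.shape
    ys, xs = np.mgrid[0:ny, 0:nx]
    cy = (w * ys).sum() / tot
    cx = (w * xs).sum() / tot
    mu20 = (w * (xs - cx) ** 2).sum() / tot
    mu02 = (w * (ys - cy) ** 2).sum() / tot
    mu11 = (w * (xs - cx) * (ys - cy)).sum() / tot
    theta = 0.5 * np.degrees(np.arctan2(2 * mu11, mu20 - mu02))
    common = np.sqrt(4 * mu11**2 + (mu20 - mu02) ** 2)
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    aniso = (lam1 - lam2) / max(lam1 + lam2, 1e-12)
    return float(theta), float(aniso)


def _polar_slices(vol: np.ndarray, zs: np.ndarray, n_phi: int = 180) -> np.ndarray:
    """Resample slices onto a polar (r, phi) grid, mean-subtracted per slice."""
    from scipy.ndimage import map_coordinates

    n = vol.shape[1]
    c = (n - 1) / 2.0
    radii = np.arange(1.5, n / 2.0 - 1.5, 0.5)
    phis = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
    rr, pp = np.meshgrid(radii, phis, indexing="ij")
    xs = c + rr * np.cos(pp)
    ys = c + rr * np.sin(pp)
    out = np.empty((len(zs), len(radii), n_phi))
    for i, z in enumerate(zs):
        p = map_coordinates(vol[z], np.stack([ys, xs]), order=1, mode="constant")
        out[i] = p - p.mean()
    return out


def measure_twist_from_average(
    average,
    voxel_size_a: float | None = None,
    symmetry_order: int = 2,
    central_fraction: float = 0.7,
    min_anisotropy: float = 0.02,
    zero_twist_tol_deg_per_nm: float = 0.05,
) -> TwistMeasurement:
    """Measure helical twist from a filament average aligned to the z axis.

    Each z slice is registered rotationally against the central slice (polar
    resampling + circular cross-correlation with sub-bin parabolic
    refinement); the relative in-plane angle theta(z), unwrapped modulo the
    180-degree apparent repeat, is fit linearly against z.  The twist rate
    is the magnitude of the slope, the crossover its 180-degree repeat, and
    the fit residual is reported in degrees RMS.  ``average`` may be an
    :class:`~filtomo.align.AverageMap` or a plain 3D array (then
    ``voxel_size_a`` is required).
    """
    vol = getattr(average, "map", average)
    if voxel_size_a is None:
        voxel_size_a = getattr(average, "voxel_size_a", None)
        if voxel_size_a is None:
            raise ValueError("voxel_size_a required for a plain array")
    nz = vol.shape[0]
    margin = int(round(nz * (1.0 - central_fraction) / 2.0))
    zs = np.arange(margin, nz - margin)

    anisos = np.array([_slice_orientation(vol[z])[1] for z in zs])
    good = anisos > min_anisotropy
    if good.sum() < max(4, len(zs) // 3):
        raise UnmeasurableTwistError(
            "cross-section too isotropic to define an in-plane orientation"
        )
    zs = zs[good]
    polar = _polar_slices(vol, zs)
    n_phi = polar.shape[2]
    f = np.fft.rfft(polar, axis=2)
    center = len(zs) // 2
    cross = np.fft.irfft(np.conj(f[center])[None] * f, n=n_phi, axis=2).sum(axis=1)
    deg_per_bin = 360.0 / n_phi
    thetas = np.empty(len(zs))
    for i, row in enumerate(cross):
        k = int(np.argmax(row))
        ym, y0, yp = row[(k - 1) % n_phi], row[k], row[(k + 1) % n_phi]
        denom = ym - 2 * y0 + yp
        frac = 0.5 * (ym - yp) / denom if denom != 0 else 0.0
        thetas[i] = -(k + frac) * deg_per_bin  # rotation of slice vs centre

    period = 360.0 / max(symmetry_order, 1)
    thetas = thetas % period
    unwrapped = [thetas[0]]
    for t in thetas[1:]:
        k = np.round((unwrapped[-1] - t) / period)
        unwrapped.append(t + period * k)
    unwrapped = np.asarray(unwrapped)
    z_nm = zs * voxel_size_a / 10.0
    slope, intercept = np.polyfit(z_nm, unwrapped, 1)
    residual = float(np.sqrt(np.mean((unwrapped - (slope * z_nm + intercept)) ** 2)))
    twist = abs(float(slope))
    if twist < zero_twist_tol_deg_per_nm:
        return TwistMeasurement(np.inf, 0.0, "from_average_rotation_fit", residual)
    return TwistMeasurement(
        crossover_nm=HALF_TURN_DEG / twist,
        twist_deg_per_nm=twist,
        method="from_average_rotation_fit",
        fit_residual_deg=residual,
    )


# ---------------------------------------------------------------------------
# polarity


def assign_polarity(
    table,
    consistency_threshold: float = 0.8,
    reference_direction: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-filament polarity orientation from refined segment orientations.

    Each segment's direction is its rotated +z axis.  The cluster reference
    direction is the first principal direction of all segment directions
    (sign fixed so that the majority of filaments align with it).  A filament
    whose fraction of segments pointing along the reference is >= the
    consistency threshold is labelled ``same``; <= (1 - threshold) is
    ``opposite``; anything between is ``ambiguous``.

    ``table`` is a :class:`~filtomo.picking.ParticleTable` or its DataFrame.
    Returns one row per filament: tube_id, label, consistency, direction.
    """
    df = table.to_dataframe() if hasattr(table, "to_dataframe") else table
    dirs = np.stack([
        geometry.direction_from_euler(r, t, p)
        for r, t, p in zip(df["rot"], df["tilt"], df["psi"])
    ])
    if reference_direction is None:
        # principal eigenvector of the orientation scatter matrix
        scatter = dirs.T @ dirs
        w, v = np.linalg.eigh(scatter)
        ref = v[:, -1]
    else:
        ref = np.asarray(reference_direction, float)
        ref = ref / np.linalg.norm(ref)
    dots = dirs @ ref
    rows = []
    for tube_id, idx in df.groupby("tube_id", sort=True).groups.items():
        d = dots[df.index.get_indexer(idx)]
        frac = float(np.mean(d > 0))
        mean_dir = dirs[df.index.get_indexer(idx)].mean(axis=0)
        norm = np.linalg.norm(mean_dir)
        mean_dir = mean_dir / norm if norm > 0 else mean_dir
        if frac >= consistency_threshold:
            label = "same"
        elif frac <= 1.0 - consistency_threshold:
            label = "opposite"
        else:
            label = "ambiguous"
        rows.append({
            "tube_id": tube_id,
            "label": label,
            "consistency": max(frac, 1 - frac),
            "fraction_along_reference": frac,
            "dir_x": mean_dir[0], "dir_y": mean_dir[1], "dir_z": mean_dir[2],
        })
    out = pd.DataFrame(rows)
    # for an auto-computed reference, fix its sign so 'same' is the majority;
    # an explicit reference is honoured as given (flipping it swaps labels)
    if (
        reference_direction is None
        and len(out)
        and (out.label == "opposite").sum() > (out.label == "same").sum()
    ):
        out["label"] = out["label"].map(
            {"same": "opposite", "opposite": "same", "ambiguous": "ambiguous"}
        )
        out["fraction_along_reference"] = 1.0 - out["fraction_along_reference"]
        ref = -ref
    out.attrs["reference_direction"] = tuple(ref)
    return out


def summarize_cluster_polarity(
    labels: pd.DataFrame, cluster_id: str = "cluster"
) -> ClusterPolaritySummary:
    """Exact binomial polarity test for one cluster.

    The test is one-sided on the majority count among unambiguous filaments
    (p = 1/2): with zero ambiguous filaments this is the per-cluster
    convention of the printed p-values.
    """
    n = len(labels)
    k_same = int((labels.label == "same").sum())
    k_opp = int((labels.label == "opposite").sum())
    amb = int((labels.label == "ambiguous").sum())
    k_maj, k_min = max(k_same, k_opp), min(k_same, k_opp)
    m = k_maj + k_min
    flagged = n < 2
    p = 1.0 if (flagged or m == 0) else binomial_tail(m, k_maj, 0.5)
    ref = labels.attrs.get("reference_direction", (0.0, 0.0, 1.0))
    return ClusterPolaritySummary(
        cluster_id=cluster_id,
        n=n,
        k_majority=k_maj,
        k_minority=k_min,
        ambiguous_count=amb,
        reference_direction=tuple(ref),
        p_value=float(p),
        flagged=flagged,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# exact binomial tail


def binomial_tail(n: int, k: int, p: float = 0.5) -> float:
    """Exact one-sided tail P(X >= k) for X ~ Binomial(n, p), in log space.

    Summing log-binomial terms through ``logsumexp`` keeps relative error
    ~1e-14 even for far tails such as P(X >= 114 | n = 136) ~ 1.8e-16.
    """
    n = int(n)
    k = int(k)
    if n < 0 or not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    if not (0.0 < p < 1.0):
        raise ValueError("require 0 < p < 1")
    if k == 0:
        return 1.0
    i = np.arange(k, n + 1)
    log_terms = (
        gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
        + i * np.log(p) + (n - i) * np.log1p(-p)
    )
    return float(np.exp(logsumexp(log_terms)))
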