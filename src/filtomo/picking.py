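"""Two-point filament picks -> densified, oriented segment records.

A filament pick is a two-point contour with a 'head' and a 'tail' model
point at the poles of the filament.  :func:`stalk_init` converts a contour
into head/centroid/tail records whose rotation takes the reference +z axis
onto the tail-to-head unit vector (the spin about the filament axis is a
free parameter, initialised to 0).  :func:`add_points_along_axis` densifies
a tube with centroids every ``spacing`` voxels along the axis.  Tables carry
the helical-prior bookkeeping columns (tube id, track length, tilt/psi
priors of 0 and a psi flip ratio of 0.5 encoding unknown polarity) and are
exported to a STAR dialect or CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from . import geometry

__all__ = [
    "TwoPointContour",
    "SegmentRecord",
    "ParticleTable",
    "stalk_init",
    "add_points_along_axis",
    "export_table",
    "import_table",
    "contours_from_ground_truth",
    "read_contours_csv",
    "write_contours_csv",
]

DEFAULT_PSI_FLIP_RATIO = 0.5


class DegenerateContourError(ValueError):
    pass


@dataclass(frozen=True)
class TwoPointContour:
    """Head and tail pole coordinates of one filament, in voxels."""

    head: tuple[float, float, float]
    tail: tuple[float, float, float]
    tomogram_id: str = "tomo"

    def __post_init__(self):
        if np.allclose(self.head, self.tail):
            raise DegenerateContourError("contour head and tail coincide")

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from tail to head."""
        v = np.asarray(self.head, float) - np.asarray(self.tail, float)
        return v / np.linalg.norm(v)

    @property
    def length(self) -> float:
        return float(
            np.linalg.norm(np.asarray(self.head, float) - np.asarray(self.tail, float))
        )


@dataclass
class SegmentRecord:
    """One subvolume position with orientation and helical priors."""

    position: tuple[float, float, float]  # voxels
    euler: tuple[float, float, float]  # (rot, tilt, psi) ZYZ intrinsic, degrees
    tube_id: int = 1
    track_length: float = 0.0  # distance from tube start, voxels
    tilt_prior: float = 0.0
    psi_prior: float = 0.0
    psi_flip_ratio: float = DEFAULT_PSI_FLIP_RATIO
    tomogram_id: str = "tomo"
    point_kind: str = "centroid"  # head | centroid | tail

    def __post_init__(self):
        if not np.all(np.isfinite(self.euler)):
            raise ValueError("euler angles must be finite")
        if not (0.0 <= self.psi_flip_ratio <= 1.0):
            raise ValueError("psi_flip_ratio must lie in [0, 1]")

    @property
    def rotation(self) -> np.ndarray:
        return geometry.euler_to_matrix(*self.euler)

    @property
    def direction(self) -> np.ndarray:
        """Filament direction: the rotated reference +z axis."""
        return geometry.direction_from_euler(*self.euler)


TABLE_COLUMNS = [
    "tomogram_id", "tube_id", "x", "y", "z",
    "rot", "tilt", "psi", "track_length",
    "tilt_prior", "psi_prior", "psi_flip_ratio",
]

# CSV/internal column -> RELION-style STAR tag
STAR_TAGS = {
    "tomogram_id": "_rlnTomoName",
    "tube_id": "_rlnHelicalTubeID",
    "x": "_rlnCoordinateX",
    "y": "_rlnCoordinateY",
    "z": "_rlnCoordinateZ",
    "rot": "_rlnAngleRot",
    "tilt": "_rlnAngleTilt",
    "psi": "_rlnAnglePsi",
    "track_length": "_rlnHelicalTrackLength",
    "tilt_prior": "_rlnAngleTiltPrior",
    "psi_prior": "_rlnAnglePsiPrior",
    "psi_flip_ratio": "_rlnAnglePsiFlipRatio",
}


@dataclass
class ParticleTable:
    """A set of segment records plus tomogram metadata."""

    records: list = field(default_factory=list)
    voxel_size_a: float = 9.52
    volume_shape: tuple[int, int, int] = (96, 96, 96)

    def __post_init__(self):
        seen = {}
        for r in self.records:
            key = (r.tomogram_id, r.tube_id)
            seen.setdefault(key, []).append(r.track_length)
        for (tomo, tube), tracks in seen.items():
            if any(t2 < t1 for t1, t2 in zip(tracks, tracks[1:])):
                raise ValueError(
                    f"track_length must be non-decreasing along tube {tube} of {tomo}"
                )

    def __len__(self):
        return len(self.records)

    def tube_ids(self) -> list[int]:
        out = []
        for r in self.records:
            if r.tube_id not in out:
                out.append(r.tube_id)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "tomogram_id": r.tomogram_id,
                "tube_id": r.tube_id,
                "x": r.position[0], "y": r.position[1], "z": r.position[2],
                "rot": r.euler[0], "tilt": r.euler[1], "psi": r.euler[2],
                "track_length": r.track_length,
                "tilt_prior": r.tilt_prior,
                "psi_prior": r.psi_prior,
                "psi_flip_ratio": r.psi_flip_ratio,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=TABLE_COLUMNS)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, voxel_size_a: float = 9.52,
        volume_shape: tuple[int, int, int] = (96, 96, 96),
    ) -> "ParticleTable":
        records = [
            SegmentRecord(
                position=(row.x, row.y, row.z),
                euler=(row.rot, row.tilt, row.psi),
                tube_id=int(row.tube_id),
                track_length=float(row.track_length),
                tilt_prior=float(row.tilt_prior),
                psi_prior=float(row.psi_prior),
                psi_flip_ratio=float(row.psi_flip_ratio),
                tomogram_id=str(row.tomogram_id),
            )
            for row in df.itertuples()
        ]
        return cls(records=records, voxel_size_a=voxel_size_a, volume_shape=volume_shape)


def stalk_init(contour: TwoPointContour, tube_id: int = 1) -> tuple[SegmentRecord, SegmentRecord, SegmentRecord]:
    """Head, centroid and tail records for a two-point contour.

    The centroid is the midpoint; all three records carry the rotation that
    maps the reference +z axis onto the tail-to-head unit vector, with the
    spin about the axis set to 0 for later refinement.
    """
    head = np.asarray(contour.head, float)
    tail = np.asarray(contour.tail, float)
    centroid = (head + tail) / 2.0
    euler = geometry.axis_to_euler(contour.axis)
    length = contour.length

    def rec(pos, kind, track):
        return SegmentRecord(
            position=tuple(pos), euler=euler, tube_id=tube_id,
            track_length=track, tomogram_id=contour.tomogram_id, point_kind=kind,
        )

    return (
        rec(head, "head", length),
        rec(centroid, "centroid", length / 2.0),
        rec(tail, "tail", 0.0),
    )


def add_points_along_axis(
    records: tuple[SegmentRecord, SegmentRecord, SegmentRecord] | list,
    spacing: float = 1.0,
) -> list[SegmentRecord]:
    """Densify a tube with centroids every ``spacing`` voxels along its axis.

    Points are placed at arc lengths 0, spacing, 2*spacing, ... measured from
    the tail; the far endpoint is included when it falls on the lattice, else
    the last point is the last multiple of spacing strictly inside.  All
    points inherit the tube orientation and get ``track_length`` equal to
    their arc position.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    recs = list(records)
    by_kind = {r.point_kind: r for r in recs}
    if "head" in by_kind and "tail" in by_kind:
        head = np.asarray(by_kind["head"].position, float)
        tail = np.asarray(by_kind["tail"].position, float)
        proto = by_kind["tail"]
    else:
        # fall back to first/last records of the tube
        tail = np.asarray(recs[0].position, float)
        head = np.asarray(recs[-1].position, float)
        proto = recs[0]
    length = float(np.linalg.norm(head - tail))
    if length < spacing:
        raise ValueError("tube shorter than the requested spacing")
    axis = (head - tail) / length
    n = int(np.floor(length / spacing + 1e-9))
    out = []
    for k in range(n + 1):
        arc = k * spacing
        out.append(
            replace(
                proto,
                position=tuple(tail + arc * axis),
                track_length=arc,
                point_kind="centroid",
            )
        )
    return out


# ---------------------------------------------------------------------------
# table export / import

SUPPORTED_DIALECTS = ("star", "csv")


def export_table(table: ParticleTable, path, dialect: str = "star") -> None:
    """Write a particle table; ``dialect`` is ``star`` or ``csv``.

    The STAR dialect uses the RELION helical-prior tags (helical tube id and
    track length, tilt/psi priors, psi flip ratio).
    """
    if dialect not in SUPPORTED_DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; supported: {SUPPORTED_DIALECTS}"
        )
    df = table.to_dataframe()
    if dialect == "csv":
        df.to_csv(path, index=False)
        return
    doc = gemmi.cif.Document()
    block = doc.add_new_block("particles")
    block.set_pair("_filtomoVoxelSizeAngstrom", f"{table.voxel_size_a:.6f}")
    block.set_pair(
        "_filtomoVolumeShape",
        f"'{table.volume_shape[0]} {table.volume_shape[1]} {table.volume_shape[2]}'",
    )
    tags = [STAR_TAGS[c] for c in TABLE_COLUMNS]
    loop = block.init_loop("", tags)
    for row in df.itertuples(index=False):
        vals = []
        for col, v in zip(TABLE_COLUMNS, row):
            if col == "tomogram_id":
                vals.append(str(v))
            elif col == "tube_id":
                vals.append(str(int(v)))
            else:
                vals.append(f"{float(v):.6f}")
        loop.add_row(vals)
    doc.write_file(str(path))


def import_table(path, dialect: str | None = None) -> ParticleTable:
    """Read a particle table written by :func:`export_table`."""
    path = Path(path)
    if dialect is None:
        dialect = "star" if path.suffix == ".star" else "csv"
    if dialect not in SUPPORTED_DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; supported: {SUPPORTED_DIALECTS}"
        )
    if dialect == "csv":
        df = pd.read_csv(path)
        if df.empty:
            return ParticleTable(records=[])
        return ParticleTable.from_dataframe(df)
    doc = gemmi.cif.read_file(str(path))
    block = doc.sole_block()
    voxel = float(block.find_value("_filtomoVoxelSizeAngstrom") or 9.52)
    shape_str = block.find_value("_filtomoVolumeShape")
    shape = (96, 96, 96)
    if shape_str:
        shape = tuple(int(s) for s in shape_str.strip("'\"").split())
    cols = {c: list(block.find_loop(STAR_TAGS[c])) for c in TABLE_COLUMNS}
    n = len(cols["x"])
    if n == 0:
        return ParticleTable(records=[], voxel_size_a=voxel, volume_shape=shape)
    df = pd.DataFrame(
        {
            c: (cols[c] if c == "tomogram_id" else pd.to_numeric(cols[c]))
            for c in TABLE_COLUMNS
        }
    )
    return ParticleTable.from_dataframe(df, voxel_size_a=voxel, volume_shape=shape)


# ---------------------------------------------------------------------------
# pick sources


def contours_from_ground_truth(
    gt: pd.DataFrame,
    voxel_nm: float,
    randomize_head_tail: bool = True,
    seed: int = 0,
    tomogram_id: str = "tomo",
) -> list[TwoPointContour]:
    """Two-point contours from a scene ground-truth table.

    Mimics manual picking: the two poles of each tube become head and tail.
    With ``randomize_head_tail`` (default) the assignment of head vs tail is
    random per filament, so filament polarity is unknown to downstream
    alignment, exactly as for real picks (psi flip ratio 0.5).
    """
    rng = np.random.default_rng(seed)
    contours = []
    for tube_id, sub in gt.groupby("tube_id", sort=True):
        sub = sub.sort_values("segment_index")
        first = sub.iloc[0]
        last = sub.iloc[-1]
        a = (first.x_vox, first.y_vox, first.z_vox)
        b = (last.x_vox, last.y_vox, last.z_vox)
        # ground-truth polarity points tail->head = first->last
        head, tail = (b, a)
        if randomize_head_tail and rng.random() < 0.5:
            head, tail = tail, head
        contours.append(TwoPointContour(head=head, tail=tail, tomogram_id=tomogram_id))
    return contours


CONTOUR_COLUMNS = ["tomogram_id", "head_x", "head_y", "head_z", "tail_x", "tail_y", "tail_z"]


def write_contours_csv(path, contours: list) -> None:
    rows = [
        {
            "tomogram_id": c.tomogram_id,
            "head_x": c.head[0], "head_y": c.head[1], "head_z": c.head[2],
            "tail_x": c.tail[0], "tail_y": c.tail[1], "tail_z": c.tail[2],
        }
        for c in contours
    ]
    pd.DataFrame(rows, columns=CONTOUR_COLUMNS).to_csv(path, index=False)


def read_contours_csv(path) -> list:
    df = pd.read_csv(path)
    return [
        TwoPointContour(
            head=(r.head_x, r.head_y, r.head_z),
            tail=(r.tail_x, r.tail_y, r.tail_z),
            tomogram_id=str(r.tomogram_id),
        )
        for r in df.itertuples()
    ]
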