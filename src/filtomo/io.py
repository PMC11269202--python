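"""Volume, table and configuration I/O.

Volumes are written as MRC2014 mode-2 (32-bit float) maps through gemmi,
with the voxel size recorded in the header cell; ground-truth and summary
tables are plain CSV via pandas; scene configurations are YAML or JSON
mirrors of :class:`~filtomo.scene.SceneSpec`.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

from .scene import GROUND_TRUTH_COLUMNS, SceneSpec


def write_mrc(path, volume: np.ndarray, voxel_size_a: float) -> None:
    """Write a 3D volume as an MRC2014 mode-2 map.

    The array is indexed ``[z, y, x]``; the header cell is set so that the
    voxel size (angstrom) round-trips.
    """
    data = np.ascontiguousarray(np.asarray(volume, dtype=np.float32))
    if data.ndim != 3:
        raise ValueError("volume must be 3-dimensional")
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(data)
    # gemmi maps numpy axis 0 onto grid axis u: cell edges follow array shape
    m.grid.unit_cell = gemmi.UnitCell(
        data.shape[0] * voxel_size_a,
        data.shape[1] * voxel_size_a,
        data.shape[2] * voxel_size_a,
        90, 90, 90,
    )
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read an MRC map; returns ``(volume[z, y, x], voxel_size_a)``."""
    m = gemmi.read_ccp4_map(str(path))
    data = np.array(m.grid, copy=True)
    voxel = m.grid.unit_cell.a / m.grid.nu
    return data, float(voxel)


def write_ground_truth(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_ground_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(GROUND_TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ground-truth table missing columns: {sorted(missing)}")
    return df


def write_scene_config(path, scene: SceneSpec) -> None:
    """Serialize a SceneSpec to YAML (``.yaml``/``.yml``) or JSON."""
    path = Path(path)
    d = scene.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def read_scene_config(path) -> SceneSpec:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return SceneSpec.from_dict(d)
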