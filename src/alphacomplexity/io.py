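"""Readers and writers for the formats the pipeline touches.

Volumes: multi-page TIFF stacks (via tifffile) and headerless raw volumes
with a JSON/YAML sidecar describing dimensions, dtype, byte order and
voxel size.  Point clouds: XYZ text and ASCII PLY (optionally with one
per-vertex scalar).  Meshes: whatever trimesh exports (PLY/OFF/STL).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import trimesh
import yaml

from .errors import InvalidParameter
from .preprocess import BinaryVolume, PointCloud

__all__ = [
    "read_tiff_stack",
    "write_tiff_stack",
    "read_raw_volume",
    "write_raw_volume",
    "read_xyz",
    "write_xyz",
    "read_ply_points",
    "write_ply_points",
    "write_mesh",
    "write_curve_csv",
]


def read_tiff_stack(path, voxel_size_mm: float | None = None):
    """Load a multi-page TIFF as a (slice, row, col) array."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise InvalidParameter(f"expected a 2D/3D TIFF, got shape {arr.shape}")
    return arr


def write_tiff_stack(path, vol: BinaryVolume | np.ndarray) -> None:
    arr = vol.grid if isinstance(vol, BinaryVolume) else np.asarray(vol)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    tifffile.imwrite(str(path), arr)


_DTYPES = {"uint8": np.uint8, "uint16": np.uint16}


def read_raw_volume(raw_path, sidecar_path) -> tuple[np.ndarray, float]:
    """Headerless raw volume + sidecar metadata -> (array, voxel size).

    The sidecar (JSON or YAML) must provide nx, ny, nz, voxel_size_mm and
    dtype (uint8/uint16); byte_order ('little'/'big') defaults to little.
    The array is shaped (nz, ny, nx) = (slice, row, col).
    """
    sidecar_path = Path(sidecar_path)
    text = sidecar_path.read_text()
    meta = json.loads(text) if sidecar_path.suffix == ".json" else yaml.safe_load(text)
    missing = {"nx", "ny", "nz", "voxel_size_mm", "dtype"} - set(meta)
    if missing:
        raise InvalidParameter(f"sidecar missing keys: {sorted(missing)}")
    if meta["dtype"] not in _DTYPES:
        raise InvalidParameter(f"unsupported dtype {meta['dtype']!r}")
    dt = np.dtype(_DTYPES[meta["dtype"]])
    if meta.get("byte_order", "little") == "big":
        dt = dt.newbyteorder(">")
    data = np.fromfile(str(raw_path), dtype=dt)
    n = meta["nx"] * meta["ny"] * meta["nz"]
    if data.size != n:
        raise InvalidParameter(
            f"raw file holds {data.size} voxels, sidecar promises {n}"
        )
    return data.reshape(meta["nz"], meta["ny"], meta["nx"]), float(meta["voxel_size_mm"])


def write_raw_volume(raw_path, sidecar_path, vol: BinaryVolume) -> None:
    arr = vol.grid.astype(np.uint8) * 255
    arr.tofile(str(raw_path))
    nz, ny, nx = arr.shape
    meta = {
        "nx": nx,
        "ny": ny,
        "nz": nz,
        "voxel_size_mm": vol.voxel_size_mm,
        "dtype": "uint8",
        "byte_order": "little",
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=2) + "\n")


def write_xyz(path, pc: PointCloud | np.ndarray) -> None:
    coords = pc.coordinates if isinstance(pc, PointCloud) else np.asarray(pc)
    np.savetxt(str(path), coords, fmt="%.9g")


def read_xyz(path) -> PointCloud:
    coords = np.loadtxt(str(path), ndmin=2)
    if coords.shape[1] != 3:
        raise InvalidParameter("XYZ file must have exactly 3 columns")
    return PointCloud(coords)


def write_ply_points(path, pc, scalar: np.ndarray | None = None, scalar_name: str = "coarsest_k") -> None:
    """ASCII PLY point cloud, optionally with one per-vertex float property."""
    coords = pc.coordinates if isinstance(pc, PointCloud) else np.asarray(pc)
    n = len(coords)
    if scalar is not None and len(scalar) != n:
        raise InvalidParameter("scalar length must match point count")
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {n}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        if scalar is not None:
            fh.write(f"property double {scalar_name}\n")
        fh.write("end_header\n")
        for i in range(n):
            row = f"{coords[i, 0]:.9g} {coords[i, 1]:.9g} {coords[i, 2]:.9g}"
            if scalar is not None:
                row += f" {scalar[i]:.9g}"
            fh.write(row + "\n")


def read_ply_points(path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Read an ASCII PLY vertex cloud written by :func:`write_ply_points`."""
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise InvalidParameter("not a PLY file")
        n = 0
        props: list[str] = []
        while True:
            line = fh.readline().strip()
            if line.startswith("element vertex"):
                n = int(line.split()[-1])
            elif line.startswith("property"):
                props.append(line.split()[-1])
            elif line == "end_header":
                break
        data = np.loadtxt(fh, max_rows=n, ndmin=2)
    coords = data[:, :3]
    extra = {name: data[:, 3 + i] for i, name in enumerate(props[3:])}
    return coords, extra


def write_mesh(path, vertices: np.ndarray, faces: np.ndarray, comment: str | None = None) -> None:
    """Export a triangle mesh; format chosen by extension (ply/off/stl)."""
    mesh = trimesh.Trimesh(vertices, faces, process=False)
    path = str(path)
    mesh.export(path)
    if comment and path.endswith(".off"):
        # OFF has no comment field trimesh writes; prepend one
        text = Path(path).read_text()
        Path(path).write_text(text.replace("OFF\n", f"OFF\n# {comment}\n", 1))


def write_curve_csv(path, curve) -> None:
    curve.to_frame().to_csv(str(path), index=False, float_format="%.10g")
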