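"""Volume and dataset I/O: multi-page TIFF and MRC stacks, paired-image
archives, and run manifests.

On-disk slice order is (z, m, n) — the multi-page TIFF convention — while
in memory stacks are indexed (m, n, z); readers and writers transpose so
volumes round-trip exactly (float32 for TIFF, MRC mode 2).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np

from .noise_model import NoisyImagePair
from .voxel_imaging import GridSpec, VoxelStack

__all__ = [
    "write_stack",
    "read_stack",
    "save_pairs",
    "load_pairs",
    "write_manifest",
    "read_manifest",
]

_NM_PER_ANGSTROM = 0.1


def write_stack(stack: VoxelStack, path: str | Path) -> Path:
    """Write a stack to .tif/.tiff (float32, ImageJ-style spacing metadata)
    or .mrc (mode 2, voxel size carried in the cell dimensions)."""
    path = Path(path)
    data_zmn = np.ascontiguousarray(stack.data.transpose(2, 0, 1).astype(np.float32))
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(
            path,
            data_zmn,
            imagej=True,
            resolution=(1.0 / stack.grid.voxel_size, 1.0 / stack.grid.voxel_size),
            metadata={"spacing": stack.grid.voxel_size, "unit": "nm", "axes": "ZYX"},
        )
    elif path.suffix.lower() == ".mrc":
        import gemmi

        grid = gemmi.FloatGrid(np.ascontiguousarray(stack.data.astype(np.float32)))
        ext = stack.grid.extent_nm / _NM_PER_ANGSTROM  # cell in Angstrom
        grid.set_unit_cell(gemmi.UnitCell(ext[0], ext[1], ext[2], 90.0, 90.0, 90.0))
        m = gemmi.Ccp4Map()
        m.grid = grid
        m.update_ccp4_header()
        m.write_ccp4_map(str(path))
    else:
        raise ValueError(f"unsupported volume format {path.suffix!r}")
    return path


def read_stack(path: str | Path, voxel_size: float | None = None) -> VoxelStack:
    """Read a TIFF or MRC volume; voxel size comes from the file metadata
    unless overridden.  Stacks whose intensities lie in [0, 1] are marked
    normalized."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(path) as tf:
            data_zmn = tf.asarray()
            if voxel_size is None:
                meta = tf.imagej_metadata or {}
                voxel_size = float(meta.get("spacing", 0.0)) or None
        if data_zmn.ndim == 2:
            data_zmn = data_zmn[None]
        data = np.asarray(data_zmn, dtype=np.float64).transpose(1, 2, 0)
    elif path.suffix.lower() == ".mrc":
        import gemmi

        m = gemmi.read_ccp4_map(str(path))
        data = np.array(m.grid, copy=True).astype(np.float64)
        if voxel_size is None:
            cell_a = m.grid.unit_cell.a  # Angstrom along the first axis
            voxel_size = cell_a * _NM_PER_ANGSTROM / data.shape[0]
    else:
        raise ValueError(f"unsupported volume format {path.suffix!r}")
    voxel_size = voxel_size or 3.0
    grid = GridSpec(shape=data.shape, voxel_size=float(voxel_size))
    normalized = bool(data.size and data.min() >= 0.0 and data.max() <= 1.0)
    return VoxelStack(data=data, grid=grid, normalized=normalized)


def save_pairs(pairs: list, path: str | Path) -> Path:
    """Save (clean, noisy) image pairs to a compressed .npz archive."""
    path = Path(path)
    clean = np.stack([p.clean for p in pairs]).astype(np.float32)
    noisy = np.stack([p.noisy for p in pairs]).astype(np.float32)
    np.savez_compressed(path, clean=clean, noisy=noisy)
    return path


def load_pairs(path: str | Path) -> list:
    with np.load(Path(path)) as data:
        clean, noisy = data["clean"], data["noisy"]
    return [NoisyImagePair(clean=c, noisy=n) for c, n in zip(clean, noisy)]


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_manifest(path: str | Path, stage: str, seed: int, config) -> Path:
    """Record a pipeline stage's full configuration, seed, and config hash so
    every output is reproducible from its manifest."""
    payload = {"stage": stage, "seed": int(seed), "config": _jsonable(config)}
    blob = json.dumps(payload["config"], sort_keys=True).encode()
    payload["config_sha256"] = hashlib.sha256(blob).hexdigest()
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
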