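"""Point-cloud voxelization into synthetic HAADF-STEM voxel stacks.

A voxel's raw intensity is the number of pseudo-atoms enclosed in its
half-open axis-aligned box, mimicking HAADF-STEM contrast where intensity
scales with the local scattering mass.  Stacks default to 28 x 28 x 9
voxels at 3 nm per edge, the geometry of the experimental tomogram
sub-volumes the autoencoder is trained for.

Axis convention: ``data[m, n, z]`` with row m along physical x, column n
along y, slice z along the beam axis; the origin is the minimum grid
corner.  :func:`extract_slices` / :func:`restack` convert to and from the
slice-major (z, m, n) order used by multi-page TIFF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fiber_synth import PointCloud

__all__ = [
    "GridSpec",
    "VoxelStack",
    "voxelize",
    "centered_grid",
    "normalize_intensity",
    "reference_histogram",
    "extract_slices",
    "restack",
]

DEFAULT_SHAPE = (28, 28, 9)
DEFAULT_VOXEL_NM = 3.0


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid geometry: (rows, cols, slices), edge length in nm, origin."""

    shape: tuple = DEFAULT_SHAPE
    voxel_size: float = DEFAULT_VOXEL_NM
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError("shape must be three positive integers")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def extent_nm(self) -> np.ndarray:
        return np.asarray(self.shape) * self.voxel_size


@dataclass
class VoxelStack:
    """3D intensity grid ``data[m, n, z]`` plus its physical geometry."""

    data: np.ndarray
    grid: GridSpec
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )
        if self.normalized:
            if self.data.size and (self.data.min() < 0 or self.data.max() > 1):
                raise ValueError("normalized stack must lie in [0, 1]")
        elif self.data.size and self.data.min() < 0:
            raise ValueError("raw intensities must be non-negative")

    @property
    def n_slices(self) -> int:
        return self.grid.shape[2]


def centered_grid(
    cloud: PointCloud,
    shape: tuple = DEFAULT_SHAPE,
    voxel_size: float = DEFAULT_VOXEL_NM,
) -> GridSpec:
    """Grid of the given shape centered on the cloud centroid."""
    centroid = cloud.positions.mean(axis=0) if cloud.n_points else np.zeros(3)
    origin = centroid - np.asarray(shape) * voxel_size / 2.0
    return GridSpec(shape=shape, voxel_size=voxel_size, origin=tuple(origin))


def voxelize(cloud: PointCloud, grid: GridSpec) -> VoxelStack:
    """Count atoms per half-open voxel box.

    Each atom falls in exactly one voxel ``[origin + i*s, origin + (i+1)*s)``;
    atoms outside the grid (including on the upper boundary faces) are
    dropped, so the intensity sum equals the in-bounds atom count.
    """
    data = np.zeros(grid.shape, dtype=np.float64)
    pos = cloud.positions
    if len(pos):
        idx = np.floor((pos - np.asarray(grid.origin)) / grid.voxel_size).astype(np.int64)
        inb = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
        idx = idx[inb]
        np.add.at(data, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    return VoxelStack(data=data, grid=grid, normalized=False)


def reference_histogram(n: int = 20000, seed: int = 12345) -> np.ndarray:
    """Synthetic experimental-like intensity sample: right-skewed with mode
    near 0.1, emulating the sparse bright-on-dark contrast of ChromSTEM
    tomograms.  Used as the default target for histogram matching."""
    rng = np.random.default_rng(seed)
    vals = rng.beta(1.3, 8.0, size=n)
    return np.clip(vals, 0.0, 1.0)


def normalize_intensity(
    stack: VoxelStack,
    mode: str = "minmax",
    ref: np.ndarray | None = None,
) -> VoxelStack:
    """Map raw voxel counts monotonically into [0, 1].

    ``minmax`` divides by the stack maximum (raw counts are >= 0, so this is
    the affine map of [0, max]); an all-zero stack stays all-zero.
    ``histmatch`` monotonically matches the intensity distribution to a
    reference sample (default :func:`reference_histogram`), preserving ties
    and rank order.
    """
    if stack.normalized:
        raise ValueError("stack is already normalized")
    data = stack.data.astype(np.float64)
    if mode == "minmax":
        peak = data.max() if data.size else 0.0
        out = data / peak if peak > 0 else data.copy()
    elif mode == "histmatch":
        ref_vals = np.sort(reference_histogram() if ref is None else np.asarray(ref))
        uniq, inv = np.unique(data.ravel(), return_inverse=True)
        counts = np.bincount(inv)
        cdf = (np.cumsum(counts) - counts / 2.0) / data.size
        mapped = np.interp(cdf, (np.arange(len(ref_vals)) + 0.5) / len(ref_vals), ref_vals)
        if uniq[0] == 0.0:
            mapped[0] = 0.0  # empty voxels stay background
        out = mapped[inv].reshape(data.shape)
        out = np.clip(out, 0.0, 1.0)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return VoxelStack(data=out, grid=stack.grid, normalized=True)


def extract_slices(stack: VoxelStack) -> list[np.ndarray]:
    """Split into Z planar (M, N) images in slice order."""
    return [stack.data[:, :, z].copy() for z in range(stack.grid.shape[2])]


def restack(slices: list[np.ndarray], grid: GridSpec, normalized: bool = False) -> VoxelStack:
    """Inverse of :func:`extract_slices`."""
    data = np.stack(slices, axis=-1)
    return VoxelStack(data=data, grid=grid, normalized=normalized)
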