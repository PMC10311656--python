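"""Synthetic tomogram phantoms with planted, analytically known structure.

These stand in for experimental tomograms (which are not redistributable)
when validating the packing-domain pipeline: a planted domain has an exact
power-law mass profile M(r) ~ r^D inside a known radius, so detection rate,
recovered exponent, and recovered size can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .voxel_imaging import GridSpec, VoxelStack

__all__ = ["PlantedDomain", "planted_domain_stack", "gaussian_blob_stack"]


@dataclass(frozen=True)
class PlantedDomain:
    """Ground truth for one planted power-law domain."""

    center_nm: tuple  # physical position of the centroid
    D: float  # planted mass-scaling exponent
    radius_nm: float  # planted domain radius
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.D <= 3.0:
            raise ValueError("planted exponent must lie in (0, 3]")
        if self.radius_nm <= 0:
            raise ValueError("radius must be positive")


def planted_domain_stack(
    domains: list[PlantedDomain],
    shape: tuple = (96, 96, 32),
    voxel_size: float = 3.0,
    core_nm: float = 1.5,
    background: float = 0.0,
    seed: int = 0,
) -> VoxelStack:
    """Voxelize planted power-law domains into a normalized stack.

    Each domain contributes a radial density rho(r) = A * (r / core)^(D-3)
    for core <= r <= radius (capped at A inside the core), whose enclosed
    mass grows as r^D between the core and the domain edge.  Optional uniform
    background noise is added with the given seed.
    """
    shape = tuple(int(s) for s in shape)
    grid = GridSpec(shape=shape, voxel_size=voxel_size, origin=(0.0, 0.0, 0.0))
    axes = [(np.arange(s) + 0.5) * voxel_size for s in shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    data = np.zeros(shape, dtype=np.float64)
    for dom in domains:
        r = np.sqrt(sum((g - c) ** 2 for g, c in zip(mesh, dom.center_nm)))
        r_eff = np.maximum(r, core_nm)
        field = dom.amplitude * (r_eff / core_nm) ** (dom.D - 3.0)
        field[r > dom.radius_nm] = 0.0
        data += field
    if background > 0:
        rng = np.random.default_rng(seed)
        data += background * rng.random(shape)
    peak = data.max()
    if peak > 0:
        data /= peak
    return VoxelStack(data=np.clip(data, 0.0, 1.0), grid=grid, normalized=True)


def gaussian_blob_stack(
    centers_vox: list[tuple],
    sigma_vox: float = 2.0,
    shape: tuple = (48, 48, 16),
    voxel_size: float = 3.0,
    amplitudes: list | None = None,
) -> VoxelStack:
    """Stack of isotropic Gaussian blobs at given voxel positions — a simple
    phantom for centroid-detection tests."""
    shape = tuple(int(s) for s in shape)
    grid = GridSpec(shape=shape, voxel_size=voxel_size, origin=(0.0, 0.0, 0.0))
    mesh = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    data = np.zeros(shape, dtype=np.float64)
    amplitudes = amplitudes or [1.0] * len(centers_vox)
    for cen, amp in zip(centers_vox, amplitudes):
        r2 = sum((g - c) ** 2 for g, c in zip(mesh, cen))
        data += amp * np.exp(-r2 / (2.0 * sigma_vox**2))
    peak = data.max()
    if peak > 0:
        data /= peak
    return VoxelStack(data=data, grid=grid, normalized=True)
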