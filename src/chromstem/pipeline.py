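"""End-to-end synthetic benchmark: fibers -> voxel stacks -> noise -> DAE
training -> DAE/BM3D/NLM comparison.

This is the programmatic form of the full study: generate seeded chromatin
fibers (4-16 nucleosomes, NRL 150-200 bp), voxelize each to a 28x28x9 stack
at 3 nm voxels, collapse the stack along the beam axis into the 2D
whole-fiber snapshot used for training, corrupt with the count-scale-swept
HAADF noise model, train the autoencoder on an 80% split, and score all
three denoisers on the 20% hold-out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fiber_synth as fs
from . import noise_model as nm
from . import voxel_imaging as vi
from .dae_core import DAEConfig, TrainedDAE, build_model, train
from .quality_metrics import MetricsReport, benchmark, bm3d_denoiser, dae_denoiser, nlm_denoiser

__all__ = ["BenchmarkResult", "make_clean_images", "run_synthetic_benchmark"]

@dataclass
class BenchmarkResult:
    report: MetricsReport
    trained: TrainedDAE
    train_pairs: list
    test_pairs: list


def make_clean_images(n_fibers: int, seed: int, template_atoms: int = 500) -> list:
    """Noise-free 28x28 snapshots, one per fiber.

    Each fiber's voxel stack is collapsed along the beam (z) axis — atom
    counts summed over the 9 slices — so the whole fragment is visible in
    one image; intensities are then histogram-matched to the packaged
    experimental-like reference distribution (empty voxels stay zero), the
    normalization that makes synthetic snapshots resemble tomogram patches.
    """
    confs = fs.generate_dataset(n_fibers, seed=seed)
    template = fs.make_template(n_atoms=template_atoms, seed=seed)
    images = []
    for conf in confs:
        cloud = fs.build_point_cloud(conf, template)
        stack = vi.voxelize(cloud, vi.centered_grid(cloud))
        proj = stack.data.sum(axis=2)
        flat = vi.VoxelStack(
            data=proj[:, :, None],
            grid=vi.GridSpec(shape=(*proj.shape, 1), voxel_size=stack.grid.voxel_size),
        )
        normed = vi.normalize_intensity(flat, mode="histmatch")
        images.append(normed.data[:, :, 0])
    return images


def run_synthetic_benchmark(
    n_fibers: int = 500,
    seed: int = 0,
    max_epochs: int = 50,
    patience: int = 5,
    test_fraction: float = 0.2,
    counts_range: tuple = nm.DEFAULT_COUNTS_RANGE,
    include_baselines: bool = True,
    verbose: bool = False,
) -> BenchmarkResult:
    """Run the full synthetic study and return the scored comparison.

    All randomness derives from ``seed``: fiber sampling, noise draws, the
    train/test split, and network initialization use distinct child seeds.
    """
    ss = np.random.SeedSequence(seed)
    s_fiber, s_noise, s_split, s_net = (int(s) for s in ss.generate_state(4) % (2**31 - 1))

    images = make_clean_images(n_fibers, seed=s_fiber)
    pairs = nm.corrupt_sweep(images, counts_range=counts_range, seed=s_noise)

    rng = np.random.default_rng(s_split)
    perm = rng.permutation(n_fibers)
    n_test = int(round(test_fraction * n_fibers))
    test_pairs = [pairs[i] for i in perm[:n_test]]
    train_pairs = [pairs[i] for i in perm[n_test:]]

    config = DAEConfig(max_epochs=max_epochs, patience=patience, seed=s_net)
    model = build_model(config)
    trained = train(model, train_pairs, config, verbose=verbose)

    denoisers = {"DAE": dae_denoiser(trained)}
    if include_baselines:
        denoisers["BM3D"] = bm3d_denoiser()
        denoisers["NLM"] = nlm_denoiser()
    report = benchmark(test_pairs, denoisers)
    return BenchmarkResult(
        report=report, trained=trained, train_pairs=train_pairs, test_pairs=test_pairs
    )
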