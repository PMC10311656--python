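import pytest

from chromstem import fiber_synth as fs
from chromstem import noise_model as nm


@pytest.fixture(scope="session")
def template():
    return fs.make_template(n_atoms=500, seed=0)


@pytest.fixture(scope="session")
def small_clean_images():
    """60 normalized whole-fiber snapshot images (the training image class)."""
    from chromstem.pipeline import make_clean_images

    return make_clean_images(60, seed=11)


@pytest.fixture(scope="session")
def small_pairs(small_clean_images):
    return nm.corrupt_sweep(small_clean_images, seed=12)


@pytest.fixture(scope="session")
def noisy_pairs(small_clean_images):
    """Heavily shot-noise-limited pairs (low count budget) where denoising
    has clear headroom."""
    return [
        nm.corrupt(img, nm.NoiseConfig(counts_scale=3.0, seed=100 + i))
        for i, img in enumerate(small_clean_images)
    ]


@pytest.fixture(scope="session")
def tiny_trained(noisy_pairs):
    """A small-width autoencoder trained briefly; used where tests need any
    functioning trained model rather than benchmark-quality denoising."""
    from chromstem.dae_core import DAEConfig, build_model, train

    cfg = DAEConfig(
        encoder_filters=(16, 12, 8), max_epochs=15, patience=15, learning_rate=2e-3, seed=3
    )
    return train(build_model(cfg), noisy_pairs, cfg)
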