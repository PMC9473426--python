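"""Shared fixtures: small phantom cohorts and one scaled-down training run.

The ``scaled_run`` fixture trains the Pix2Pix model and the U-Net baseline
once per session on a small 64x64 phantom cohort (8 training volumes x 2
retained slices x 16 motion conditions = 256 pairs, 20 epochs) and evaluates
both on held-out volumes; every test that needs a trained model shares it.
"""

import numpy as np
import pytest

from motioncorr import atrophy, evalstats, gan, kspace, phantom

SIDE = 64
N_SLICES = 6
STRIDE = 3


@pytest.fixture(scope="session")
def small_volume():
    return phantom.generate_phantom_volume(1, N_SLICES, (SIDE, SIDE))


@pytest.fixture(scope="session")
def phantom_slice_256():
    vol = phantom.generate_phantom_volume(1, 3, (256, 256))
    return vol.slices[1]


@pytest.fixture(scope="session")
def scaled_run():
    """Train both models once and evaluate on held-out phantoms."""
    rng = np.random.default_rng(0)
    train_vols = [phantom.generate_phantom_volume(
        100 + i, N_SLICES, (SIDE, SIDE),
        atrophy_level=float(rng.uniform(0, 0.8))) for i in range(8)]
    test_vols = [phantom.generate_phantom_volume(
        900 + i, N_SLICES, (SIDE, SIDE),
        atrophy_level=float(rng.uniform(0, 0.6))) for i in range(4)]
    control_vols = [phantom.generate_phantom_volume(
        2000 + i, N_SLICES, (SIDE, SIDE)) for i in range(8)]

    train_pairs = kspace.build_paired_dataset(
        train_vols, kspace.TRAIN_PATTERNS, STRIDE)
    test_pairs = kspace.build_paired_dataset(
        test_vols, kspace.TEST_PATTERNS, STRIDE)

    spec = gan.TrainingSpec(
        learning_rate=3e-3, batch_size=16, unet_batch_size=16, epochs=20,
        seed=7, generator=gan.GeneratorSpec(base_channels=24),
        discriminator=gan.DiscriminatorSpec(patch_size=32, base_channels=8))
    pix2pix, p2p_log = gan.train_pix2pix(train_pairs, spec)
    unet, unet_log = gan.train_unet_baseline(train_pairs, spec)

    retained = list(range(0, N_SLICES, STRIDE))
    normative = atrophy.fit_normative_model(
        [v.slices[retained] for v in control_vols])
    report = evalstats.evaluate_suite(
        test_pairs, {"unet": unet, "pix2pix": pix2pix}, normative,
        volumes=dict(enumerate(test_vols)))
    return {
        "pix2pix": pix2pix, "unet": unet,
        "p2p_log": p2p_log, "unet_log": unet_log,
        "train_pairs": train_pairs, "test_pairs": test_pairs,
        "test_vols": test_vols, "normative": normative,
        "report": report, "spec": spec,
    }
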