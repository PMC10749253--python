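import numpy as np
import pytest

from truet import segmentation, simulate


@pytest.fixture(scope="session")
def stain():
    return simulate.StainProfile()


@pytest.fixture(scope="session")
def tiny_patch_config():
    """64x64 patches with 8 well-separated cells: fast and oracle-friendly."""
    return simulate.PatchSimConfig(
        patch_height_px=64, patch_width_px=64, positive_count_dist=8,
        negative_count_dist=12, cell_radius_range_px=(3.0, 5.0),
        overlap_allowed=False, seed=2,
    )


@pytest.fixture(scope="session")
def tiny_patches(tiny_patch_config, stain):
    rng = np.random.default_rng(3)
    return [
        simulate.simulate_patch(tiny_patch_config, stain,
                                patient_id=f"P{i:03d}", rng=rng)
        for i in range(8)
    ]


@pytest.fixture(scope="session")
def tiny_train_config():
    return segmentation.TrainConfig(
        input_size_px=64, batch_size=2, learning_rate=5e-3, epochs=8,
        augment_rotation_max_deg=0.0, augment_flip_prob=0.0,
        base_channels=4, blocks_per_stage=(1, 1, 1, 1), seed=0,
    )
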