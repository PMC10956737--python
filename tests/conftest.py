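"""Shared fixtures: a small, fast synthetic acquisition and trained models.

The test scenario uses a 32 x 32 pixel grid (16 x 16 mm), four probes 3 mm
apart starting at the focal center, and a 100 s heat (60 s on) / cool run
sampled every 2 s, giving 51 frames x 4 probes = 204 aligned samples.
"""

import numpy as np
import pytest

from hifutherm.synthdata import (
    HeatingScenario,
    extract_patch_dataset,
    render_modalities,
    simulate_temperature_history,
    split_dataset,
)
from hifutherm.teacher import TeacherConfig, train_teacher
from hifutherm.student import StudentConfig, train_student


@pytest.fixture(scope="session")
def small_scenario():
    return HeatingScenario(
        focal_center=(8.0, 5.0),
        image_dims=(32, 32),
        peak_delta_T=10.0,
        baseline_T=37.0,
        tau_heat=30.0,
        tau_cool=40.0,
        heat_on_interval=(0.0, 60.0),
        dt=2.0,
        noise_sigma=(0.01, 0.01, 0.01),
        name="test",
    )


@pytest.fixture(scope="session")
def small_field(small_scenario):
    return simulate_temperature_history(small_scenario, 100.0)


@pytest.fixture(scope="session")
def small_images(small_field):
    return render_modalities(small_field, seed=99)


@pytest.fixture(scope="session")
def small_patches(small_images, small_field):
    return extract_patch_dataset(small_images, small_field, patch_size=8)


@pytest.fixture(scope="session")
def noiseless_patches(small_field):
    imgs = render_modalities(small_field, noise_params=(0.0, 0.0, 0.0), seed=5)
    return extract_patch_dataset(imgs, small_field, patch_size=8)


@pytest.fixture(scope="session")
def tiny_teacher_config():
    return TeacherConfig(epochs=5, c=1, d_prime=16, r=8, r_m=1e-3)


@pytest.fixture(scope="session")
def tiny_split(small_patches):
    keep = np.flatnonzero(small_patches.frame_index % 3 == 0)
    return split_dataset(small_patches.take(keep), 0.7, seed=4)


@pytest.fixture(scope="session")
def tiny_teacher(tiny_split, tiny_teacher_config):
    train, val = tiny_split
    return train_teacher(train, val, tiny_teacher_config, seed=21)


@pytest.fixture(scope="session")
def tiny_student(tiny_split, tiny_teacher):
    train, val = tiny_split
    cfg = StudentConfig(epochs=5, c=1, d_prime=16)
    return train_student(train.target_modality("UBI"), train.labels, tiny_teacher,
                         cfg, seed=8, val_x=val.target_modality("UBI"),
                         val_y=val.labels)
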