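import numpy as np
import pytest

from kakispec.hypercube import HyperCube, ReferenceSet, WavelengthAxis
from kakispec.pipeline import (
    DetectionRecord,
    detect_cube,
    synthetic_scene_config,
    train_damage_pca_from_cubes,
)
from kakispec.synthetic import SceneSpec, generate_cube, iterate_dataset, make_templates


@pytest.fixture(scope="session")
def templates():
    return make_templates()


@pytest.fixture(scope="session")
def scene_day2(templates):
    """One default day-2 scene: (cube, ground-truth masks)."""
    return generate_cube(SceneSpec(seed=42), templates, 2)


@pytest.fixture(scope="session")
def synth_config():
    return synthetic_scene_config(seed=0)


@pytest.fixture(scope="session")
def damage_model(synth_config):
    """Damage PCA fitted on two bruised fruit per day (seeded sample)."""
    pairs = [(cube, None)
             for _, state, cube, _ in iterate_dataset(2, seed=100)
             if state != "intact"]
    return train_damage_pca_from_cubes(pairs, synth_config)


def _run_detection(n_per_state, seed, model, config, templates=None):
    records, masks_by_name = [], {}
    for idx, state, cube, masks in iterate_dataset(n_per_state,
                                                   templates=templates,
                                                   seed=seed):
        name = f"{idx:04d}"
        records.append(DetectionRecord(name, state,
                                       detect_cube(cube, model, config)))
        masks_by_name[name] = masks
    return records, masks_by_name


@pytest.fixture(scope="session")
def detection_run(damage_model, synth_config):
    """End-to-end detection over 10 cubes per state (50 total), fixed seed."""
    return _run_detection(10, 1, damage_model, synth_config)


def flat_reference_cubes(axis_values, white_level, dark_level, shape=(1, 1)):
    axis = WavelengthAxis(np.asarray(axis_values, float))
    n = len(axis)
    white = HyperCube(np.full(shape + (n,), float(white_level)), axis)
    dark = HyperCube(np.full(shape + (n,), float(dark_level)), axis)
    return ReferenceSet(white=white, dark=dark)
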