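import numpy as np
import pytest

from fadesame import SimulationConfig, generate_cohort
from fadesame.glm import ContrastMaps
from fadesame.reference import build_reference


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small two-group cohort shared by unit tests (fast to build)."""
    cfg = SimulationConfig(n_young=10, n_older=10, grid_shape=(8, 8, 4),
                           n_active_voxels=30, n_deactive_voxels=20,
                           noise_sd=0.25, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """Mid-sized cohort for integration-level checks."""
    cfg = SimulationConfig(n_young=60, n_older=60, grid_shape=(10, 10, 6),
                           n_active_voxels=60, n_deactive_voxels=40,
                           seed=11)
    return generate_cohort(cfg)


def maps_from_values(values, mask_shape=None, contrast="memory",
                     group="young", t_values=None):
    """Build ContrastMaps for a stack of flat per-subject voxel values."""
    values = np.asarray(values, dtype=float)
    n, v = values.shape
    if mask_shape is None:
        mask_shape = (v, 1, 1)
    mask = np.zeros(mask_shape, dtype=bool)
    mask.ravel()[:v] = True
    t_values = values if t_values is None else np.asarray(t_values, float)
    return [ContrastMaps(subject_id=f"s{i:02d}", mask=mask,
                         gamma={contrast: values[i]},
                         t={contrast: t_values[i]}, group=group)
            for i in range(n)]


@pytest.fixture(scope="session")
def tiny_references(tiny_cohort):
    young = [m for m in tiny_cohort.maps if m.group == "young"]
    return {c: build_reference(young, c) for c in ("novelty", "memory")}
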