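import numpy as np
import pytest

from bioturbaton import archetype, make_burrow_volume, make_profile_image
from bioturbaton.synthetic import ExperimentDesign, make_experiment

TREATMENTS = ("HD", "HU", "CV", "Mix")


@pytest.fixture(scope="session")
def gallery_image():
    """One synthetic gallery-diffuser profile image with its ground truth."""
    return make_profile_image(
        archetype("gallery_diffuser"), width_px=300, height_px=1500, seed=1, n_particles=2000
    )


@pytest.fixture(scope="session")
def shaft_volume_clean():
    """A noise-free vertical-shaft volume with exact ground truth."""
    return make_burrow_volume(archetype("i_shaft"), shape_zyx=(90, 60, 60), noise_sd=0.0, seed=5)


@pytest.fixture
def null_experiment():
    """Factory for null factorial tables: equal means, equal sds."""

    def make(seed, replicates=5, sigma=120.0):
        design = ExperimentDesign(core_shapes=("square",), replicates=replicates, seed=seed)
        return make_experiment(
            design,
            sigma_by_group={t: sigma for t in TREATMENTS},
            mean_by_group={t: 0.0 for t in TREATMENTS},
        )

    return make


def flood_fill_oracle(gray, seed, threshold, connectivity):
    """Exhaustive BFS flood fill, independent of the package's region grower.

    Returns the set of (z, y, x) tuples with gray <= threshold reachable
    from ``seed`` under the given connectivity.
    """
    from collections import deque

    if connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offsets = [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    shape = gray.shape
    seed = tuple(int(c) for c in seed)
    assert gray[seed] <= threshold
    seen = {seed}
    queue = deque([seed])
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in offsets:
            nz, ny, nx = z + dz, y + dy, x + dx
            if 0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]:
                p = (nz, ny, nx)
                if p not in seen and gray[nz, ny, nx] <= threshold:
                    seen.add(p)
                    queue.append(p)
    return seen
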