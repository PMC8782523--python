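import numpy as np
import pandas as pd
import pytest

from parkshift import LandscapeConfig, generate_landscape
from parkshift.traitspace import FunctionalSpace, finalize_space


@pytest.fixture(scope="session")
def small_dataset():
    """A modest noisy landscape shared by read-only tests."""
    return generate_landscape(
        LandscapeConfig(
            grid_rows=24,
            grid_cols=20,
            n_species=12,
            n_parks=4,
            shift_cells=3,
            noise_sd=0.03,
            seed=11,
        )
    )


def make_space(points: np.ndarray) -> FunctionalSpace:
    """A FunctionalSpace straight from explicit Euclidean coordinates."""
    pts = np.asarray(points, dtype=float)
    coords = pd.DataFrame(
        pts,
        index=[f"sp_{i:03d}" for i in range(len(pts))],
        columns=[f"axis_{i+1}" for i in range(pts.shape[1])],
    )
    space = FunctionalSpace(coords=coords, eigenvalues=np.ones(pts.shape[1]))
    d = pd.DataFrame(
        np.linalg.norm(pts[:, None] - pts[None, :], axis=-1),
        index=coords.index,
        columns=coords.index,
    )
    return finalize_space(d, space)


@pytest.fixture
def unit_square_space():
    """Pool = four corners of the unit square, a 2-axis test space."""
    return make_space(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float))
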