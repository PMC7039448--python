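import numpy as np
import pandas as pd
import pytest

from corridorscape import (GridGeometry, LandCoverRaster, LandscapeConfig,
                           OccurrenceSet, generate_landscape)
from corridorscape.synthetic import CLASS_CODES


def uniform_raster(name: str, n: int = 10, cell: float = 10.0) -> LandCoverRaster:
    code = CLASS_CODES[name]
    return LandCoverRaster(
        grid=np.full((n, n), code), class_names={code: name},
        geometry=GridGeometry(n_rows=n, n_cols=n, cell_size_m=cell))


@pytest.fixture
def woodland_raster():
    return uniform_raster("woodland")


@pytest.fixture
def checkerboard():
    """20 m cells, alternating woodland / arable."""
    n = 21
    grid = np.indices((n, n)).sum(axis=0) % 2
    codes = {0: "woodland", 1: "arable"}
    grid = np.where(grid == 0, CLASS_CODES["woodland"], CLASS_CODES["arable"])
    return LandCoverRaster(
        grid=grid,
        class_names={CLASS_CODES["woodland"]: "woodland",
                     CLASS_CODES["arable"]: "arable"},
        geometry=GridGeometry(n_rows=n, n_cols=n, cell_size_m=20.0))


@pytest.fixture(scope="session")
def demo_landscape():
    return generate_landscape(LandscapeConfig(seed=7))


def toy_table(n1: int = 30, n0: int = 30, seed: int = 0,
              beta: float = 3.0) -> pd.DataFrame:
    """Small presence/pseudo-absence table with one informative covariate
    (woodland) and one noise covariate (arable)."""
    rng = np.random.default_rng(seed)
    x = rng.random(n1 + n0)
    noise = rng.random(n1 + n0)
    p = 1 / (1 + np.exp(-(beta * (x - 0.5))))
    labels = np.where(rng.random(n1 + n0) < p, "presence", "pseudo_absence")
    # force both labels present
    labels[0], labels[-1] = "presence", "pseudo_absence"
    return pd.DataFrame({"woodland": x, "arable": noise, "label": labels,
                         "study_area": "toy"})


@pytest.fixture
def occurrence_csv(tmp_path):
    path = tmp_path / "occ.csv"
    pd.DataFrame({
        "x": [10.0, 20.0, 20.0], "y": [-10.0, -20.0, -20.0],
        "study_area": ["ticino", "ticino", "apennine"],
        "label": ["presence", "pseudo_absence", "presence"],
    }).to_csv(path, index=False)
    return path
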