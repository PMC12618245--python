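import numpy as np
import pytest

from ch4scale import FluxTable, LandCoverGrid


@pytest.fixture
def toy_codebook():
    return {1: "fen", 2: "bog", 3: "upland", 4: "forest"}


@pytest.fixture
def toy_grid(toy_codebook):
    """4x4 map with fen in the top-left corner, mixed dry classes elsewhere."""
    values = np.array(
        [
            [1, 1, 3, 3],
            [1, 2, 3, 4],
            [3, 3, 3, 4],
            [3, 4, 4, 4],
        ]
    )
    return LandCoverGrid(values=values, pixel_size_m=2.5, codebook=toy_codebook)


@pytest.fixture
def simple_flux_table():
    return FluxTable(
        mean_flux={"fen": 4.0, "bog": 2.0, "upland": -0.4, "forest": -0.1},
        se_flux={"fen": 1.0, "bog": 0.5, "upland": 0.1, "forest": 0.05},
        n_plots={"fen": 30, "bog": 20, "upland": 15, "forest": 12},
    )


def make_grid(values, pixel_size_m=1.0, nodata=-9999, names=None):
    values = np.asarray(values)
    codes = sorted(set(values.ravel().tolist()) - {nodata})
    if names is None:
        names = {c: f"class_{c}" for c in codes}
    return LandCoverGrid(
        values=values, pixel_size_m=pixel_size_m, codebook=names, nodata_code=nodata
    )
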