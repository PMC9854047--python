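import numpy as np
import pandas as pd
import pytest

from phospec.preprocess import RawSpectra
from phospec.spatial import build_layout


@pytest.fixture
def chain3():
    """Three plots in a row (1D chain), 1 m apart."""
    return build_layout(n_rows=3, n_cols=1, plot_dx=1.0, plot_dy=1.0)


@pytest.fixture
def pair():
    """Two adjacent plots."""
    return build_layout(n_rows=2, n_cols=1, plot_dx=1.0, plot_dy=1.0)


def make_raw(curves: dict, wavelengths: np.ndarray) -> RawSpectra:
    """Long-format RawSpectra from {plot_id: reflectance array}."""
    frames = [
        pd.DataFrame(
            {"plot_id": pid, "wavelength_nm": wavelengths, "reflectance": refl}
        )
        for pid, refl in curves.items()
    ]
    return RawSpectra(pd.concat(frames, ignore_index=True))


@pytest.fixture
def dense_grid():
    return np.arange(339.0, 1029.5, 1.0)
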