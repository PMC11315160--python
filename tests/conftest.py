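import numpy as np
import pytest

from stisebs.grid import GridGeometry, LabelGrid, TimeSeriesGrid


def make_grid(values, mask=None, times=None):
    """TimeSeriesGrid from an (H, W, T) array, all-valid by default."""
    values = np.asarray(values, dtype=float)
    h, w, t = values.shape
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    if times is None:
        times = TimeSeriesGrid.default_times(t)
    return TimeSeriesGrid(GridGeometry(height=h, width=w), times, values, np.asarray(mask, bool))


def make_labels(labels, kind="superpixel"):
    labels = np.asarray(labels, dtype=np.int32)
    return LabelGrid(GridGeometry(height=labels.shape[0], width=labels.shape[1]), labels, kind)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
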