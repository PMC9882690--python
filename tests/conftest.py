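import numpy as np
import pandas as pd
import pytest

from trackforge import RunConfig, TrackTable
from trackforge.io_tracks import FLAG_ORIGINAL


def make_table(rows, is_2d=False, frame_interval=None):
    """Build a TrackTable from (cell_id, t, x, y, z) tuples."""
    df = pd.DataFrame(rows, columns=["cell_id", "t", "x", "y", "z"])
    df["cell_id"] = df["cell_id"].astype(np.int64)
    df["flag"] = FLAG_ORIGINAL
    return TrackTable(df, is_2d=is_2d, frame_interval=frame_interval)


def linear_track(cell_id=1, n=10, v=(1.0, 2.0, 3.0), dt=1.0, start=(0.0, 0.0, 0.0)):
    """Exactly linear constant-speed track rows."""
    v = np.asarray(v)
    start = np.asarray(start)
    return [
        (cell_id, i * dt, *(start + i * dt * v))
        for i in range(n)
    ]


@pytest.fixture
def basic_config():
    return RunConfig(tau_max=5, min_displacement=0.1)


@pytest.fixture
def tracks_csv(tmp_path):
    """Small well-formed tracks CSV on disk."""
    path = tmp_path / "tracks.csv"
    rows = linear_track(1, n=8, v=(2, 0, 0), dt=30.0) + linear_track(
        2, n=8, v=(0, 1, 1), dt=30.0, start=(50, 0, 0)
    )
    pd.DataFrame(rows, columns=["ID", "T", "X", "Y", "Z"]).to_csv(path, index=False)
    return path
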