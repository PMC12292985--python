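import numpy as np
import pandas as pd
import pytest

from efloop.tracks import TrackTable


def make_table(records, frame_interval=5.0) -> TrackTable:
    """TrackTable from (cell_id, frame, x, y) tuples."""
    df = pd.DataFrame(records, columns=["cell_id", "frame", "x", "y"])
    return TrackTable(data=df, frame_interval=frame_interval)


@pytest.fixture
def straight_cell():
    """One cell walking +x at unit steps for 13 frames."""
    return make_table([(0, f, float(f), 0.0) for f in range(13)])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
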