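import numpy as np
import pytest

import photokin as pk


@pytest.fixture(scope="session")
def assay_schedule():
    """30-min dark acclimation followed by three 5-min light/dark cycles."""
    return pk.make_schedule(1800, 300, 3)


@pytest.fixture(scope="session")
def imaging_schedule():
    """1-min no-light lead-in followed by four 30-s ON/OFF cycles."""
    return pk.make_schedule(60, 30, 4)


@pytest.fixture(scope="session")
def short_schedule():
    """Compact assay (1-min acclimation, three 2-min cycles) for fast tests."""
    return pk.make_schedule(60, 120, 3)


def pi_arrays(schedule, params, n, seed, **track_kw):
    """Score ``n`` simulated fish and return their valid PI values."""
    tracks = [
        pk.simulate_track(
            params, schedule, seed=pk.substream(seed, f"fish{i}"), well_id=f"w{i}", **track_kw
        )
        for i in range(n)
    ]
    table, summary = pk.score_population(tracks, schedule)
    return table.loc[table["valid"], "pi"].to_numpy(), summary


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
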