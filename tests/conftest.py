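import numpy as np
import pandas as pd
import pytest

from sofpipe.synthetic_data import SimConfig, generate_environment


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig.test_scale()


@pytest.fixture(scope="session")
def env(sim_cfg):
    return generate_environment(sim_cfg, seed=11)


@pytest.fixture(scope="session")
def pipeline_results():
    """One full test-scale pipeline run shared by the end-to-end checks."""
    from sofpipe.pipeline import RunConfig, run_pipeline
    return run_pipeline(RunConfig(seed=1))


def make_track(xy, start="2012-10-15T08:00:00Z", freq="min",
               colony=(17.93, -33.05), individual_id="t1"):
    """Track helper from an (n, 2) km-coordinate array."""
    from sofpipe.trajectory import Track
    xy = np.asarray(xy, dtype=float)
    t = pd.date_range(start, periods=len(xy), freq=freq)
    df = pd.DataFrame({"timestamp": t, "x": xy[:, 0], "y": xy[:, 1]})
    return Track(individual_id=individual_id, fixes=df, colony=colony)


@pytest.fixture
def track_factory():
    return make_track
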