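import numpy as np
import pandas as pd
import pytest

from startlescreen.schedule import build_habituation_schedule, build_screen_schedule
from startlescreen.simulate import BehaviorModelConfig, make_metas, simulate_cohort


@pytest.fixture(scope="session")
def screen_schedule():
    return build_screen_schedule()


@pytest.fixture(scope="session")
def hab_schedule():
    return build_habituation_schedule()


@pytest.fixture()
def default_config():
    return BehaviorModelConfig()


@pytest.fixture(scope="session")
def small_cohort(screen_schedule):
    """60 simulated larvae on the screen schedule, seed-fixed."""
    metas = make_metas(60, seed=101)
    return simulate_cohort(screen_schedule, metas, BehaviorModelConfig(), 202)


def make_larva_events(
    larva_id: str,
    n_stimuli: int,
    slc_indices=(),
    llc_indices=(),
    turn_angle=120.0,
    max_ang_vel=25.0,
    distance=3.0,
) -> pd.DataFrame:
    """Hand-built single-larva event table for metric fixtures."""
    slc_indices = set(slc_indices)
    llc_indices = set(llc_indices)
    assert not slc_indices & llc_indices
    rows = []
    for i in range(1, n_stimuli + 1):
        if i in slc_indices:
            cls, lat, responded = "SLC", 8.0, True
        elif i in llc_indices:
            cls, lat, responded = "LLC", 28.0, True
        else:
            cls, lat, responded = "none", np.nan, False
        rows.append(
            {
                "larva_id": larva_id,
                "stimulus_index": i,
                "responded": responded,
                "response_class": cls,
                "latency_ms": lat,
                "turn_angle_deg": turn_angle if responded else np.nan,
                "max_ang_vel_deg_per_ms": max_ang_vel if responded else np.nan,
                "distance_mm": distance if responded else np.nan,
            }
        )
    return pd.DataFrame(rows)
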