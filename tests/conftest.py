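import numpy as np
import pandas as pd
import pytest

from octtrend import DesignParams, TrajectoryParams, generate_cohort
from octtrend.cohort import COHORT_COLUMNS, EyeSeries


def make_cohort_frame(rows):
    """Canonical cohort frame from (eye, session, t, measure, sector, y) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["eye_id", "session_index", "t_years", "measure", "sector", "thickness_um"],
    )
    df["session_excluded"] = False
    return df[COHORT_COLUMNS]


@pytest.fixture
def one_eye_cohort():
    """One eye, 10 sessions at 6-month intervals, both measures x 7 sectors."""
    from octtrend.cohort import MEASURES, SECTORS

    rows = []
    for j in range(10):
        t = 0.5 * j
        for m in MEASURES:
            for s in SECTORS:
                rows.append(("eye1", j, t, m, s, 100.0 - 0.5 * t + 0.01 * j))
    return make_cohort_frame(rows)


@pytest.fixture
def decreasing_series():
    return EyeSeries("e1", "RNFL", "G", np.array([0.0, 1.0, 2.0, 3.0]), np.array([4.0, 3.0, 2.0, 1.0]))


@pytest.fixture
def small_design():
    """Small, fast simulation design for unit tests."""
    return DesignParams(
        n_eyes=25,
        mean_followup_years=5.0,
        sd_followup_years=0.5,
        followup_min_years=3.0,
        followup_max_years=6.0,
        p_session_excluded=0.0,
        seed=11,
    )


@pytest.fixture
def flat_params():
    """Global-sector-only trajectory parameters for both measures."""
    return {
        ("RNFL", "G"): TrajectoryParams(60.0, -0.6, 10.0, 0.7, sigma_resid_um=2.0),
        ("MRW", "G"): TrajectoryParams(160.0, -1.0, 40.0, 2.0, sigma_resid_um=6.0),
    }


@pytest.fixture
def small_cohort(small_design, flat_params):
    cohort, truth = generate_cohort(small_design, flat_params)
    return cohort, truth
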