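import numpy as np
import pytest

import breathkin as bk


@pytest.fixture(scope="session")
def default_cohort():
    """One default-calibration cohort (29/29) shared across read-only tests."""
    subjects, washout = bk.simulate_cohort(bk.SimConfig(seed=1))
    return subjects, washout


@pytest.fixture(scope="session")
def default_kinetics(default_cohort):
    _, washout = default_cohort
    return bk.analyze_cohort(washout)


def make_curve(points, subject_id="S1"):
    """Curve from {time: amount}; nothing censored."""
    t = sorted(points)
    return bk.WashoutCurve(
        subject_id=subject_id,
        timepoints_min=tuple(float(x) for x in t),
        amounts_ng=tuple(float(points[x]) for x in t),
        censored=tuple(False for _ in t),
    )
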