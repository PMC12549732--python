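import warnings

import numpy as np
import pytest

from gaittwin.cohort import (ChildRecord, CohortSpec, DEFAULT_EFFECTS,
                             generate_cohort)
from gaittwin.features import extract_features, metrics_frame
from gaittwin.gaitsim import GaitParams, generate_gait_trial, params_for_child
from gaittwin.pipeline import make_fixtures


def make_child(child_id: str = "c000", ga: float = 39.0, bw: float = 3300.0,
               **kw) -> ChildRecord:
    """A syntactically valid child record with controllable GA/BW."""
    from gaittwin.cohort import assign_risk_label
    defaults = dict(child_id=child_id, sex="F", ga_weeks=ga, twin=False,
                    bw_g=bw, length_birth_cm=49.0, length_t24_cm=87.0,
                    weight_t24_g=12000.0, walk_exp_weeks=45.0, cog_score=100.0,
                    group="preterm" if ga <= 37 else "fullterm",
                    risk=assign_risk_label(ga, bw))
    defaults.update(kw)
    return ChildRecord(**defaults)


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free, jitter-free 20-stride trial with exact ground truth."""
    child = make_child()
    params = GaitParams(duration_s=21.0, stride_time_mean=1.0,
                        stride_time_sd=0.0, noise_sd=0.0, gyro_noise_sd=0.0)
    return generate_gait_trial(child, params, seed=11), child, params


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The 6-child / 20-s mini-cohort used across pipeline tests."""
    out = tmp_path_factory.mktemp("fixtures")
    cfg = make_fixtures(out)
    return out, cfg


@pytest.fixture(scope="session")
def effect_cohort_metrics():
    """Metric table for 30 high-risk vs 30 low-risk synthetic children.

    Children are constructed directly with forced risk labels so group sizes
    are exact; gait parameters carry the default group effect sizes.
    """
    rng = np.random.default_rng(123)
    children = []
    for i in range(30):
        children.append(make_child(f"hi{i:03d}", ga=26.0 + rng.uniform(-2, 2),
                                   bw=800.0 + rng.uniform(-150, 150)))
    for i in range(30):
        children.append(make_child(f"lo{i:03d}", ga=34.0 + rng.uniform(-2, 2),
                                   bw=2200.0 + rng.uniform(-300, 300)))
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for child in children:
            p = params_for_child(child, DEFAULT_EFFECTS)
            trial = generate_gait_trial(child, p, seed=123)
            rows.append(extract_features(trial, child))
    return metrics_frame(rows)
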