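import numpy as np
import pandas as pd
import pytest

from wearisk import GeneratorConfig, generate_cohort
from wearisk.pipeline import build_features


def make_sessions(specs):
    """Build a sleep-session frame from (start, time_in_bed, kwargs) tuples.

    kwargs: fall, after, wake, main, asleep, deep, rem.
    Defaults: fall/after/wake 0, main sleep, stages all light.
    """
    rows = []
    for start, inbed, kw in specs:
        kw = dict(kw)
        fall = kw.get("fall", 0)
        after = kw.get("after", 0)
        wake = kw.get("wake", 0)
        asleep = kw.get("asleep", inbed - fall - after - wake)
        deep = kw.get("deep", 0)
        rem = kw.get("rem", 0)
        rows.append({
            "subject_id": kw.get("subject_id", 1),
            "startTime": pd.Timestamp(start),
            "isMainSleep": kw.get("main", True),
            "timeInBed": inbed,
            "minutesAsleep": asleep,
            "minutesToFallAsleep": fall,
            "minutesAfterWakeup": after,
            "deepMinutes": deep,
            "remMinutes": rem,
            "lightMinutes": asleep - deep - rem,
            "wakeMinutes": wake,
        })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def session_builder():
    return make_sessions


@pytest.fixture(scope="session")
def small_config():
    # onset rate raised so a 120-subject cohort still contains positives
    return GeneratorConfig(n_subjects=120, onset_rate=0.06, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    features, report = build_features(small_cohort)
    return features, report


@pytest.fixture(scope="session")
def toy_model_data():
    """Linearly separable two-feature toy set with subject groups."""
    rng = np.random.default_rng(11)
    n = 400
    y = (rng.random(n) < 0.2).astype(int)
    x0 = y * 2.0 + rng.normal(0, 0.3, n)
    x1 = rng.normal(0, 1, n)
    X = pd.DataFrame({"f0": x0, "f1": x1})
    groups = np.arange(n) // 4  # 4 windows per subject
    return X, y, groups
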