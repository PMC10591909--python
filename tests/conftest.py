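import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from invivosyn import GROUPS, GrowthCurve, StudyDataset

settings.register_profile(
    "default",
    settings(
        derandomize=True,
        max_examples=50,
        deadline=None,
        suppress_health_check=[HealthCheck.too_slow],
    ),
)
settings.load_profile("default")

DEFAULT_RATES = {"C": 0.099, "A": 0.066, "B": 0.073, "AB": 0.030}
WEEKLY_DAYS = (0.0, 4.0, 7.0, 10.0, 14.0, 18.0, 21.0)


@pytest.fixture
def exp_study():
    """Factory for studies of exact exponential curves with known rates."""

    def make(rates=None, n=3, days=WEEKLY_DAYS, tv0=200.0, jitter=None, seed=0):
        rates = dict(DEFAULT_RATES if rates is None else rates)
        rng = np.random.default_rng(seed)
        curves = []
        for g in GROUPS:
            for i in range(n):
                d = np.asarray(days, dtype=float)
                v = tv0 * np.exp(rates[g] * d)
                if jitter:
                    v = v * np.exp(rng.normal(0.0, jitter, size=d.size))
                curves.append(GrowthCurve(f"{g}{i + 1}", g, d, v))
        return StudyDataset(curves=curves)

    return make


@pytest.fixture
def study_csv(tmp_path, exp_study):
    """A well-formed 4-group study CSV on disk (3 mice x 7 days per group)."""
    from invivosyn import write_study

    path = tmp_path / "study.csv"
    write_study(exp_study(), path)
    return path
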