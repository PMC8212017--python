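import numpy as np
import pytest

from akiattn.kdigo import CreatinineSeries, UrineSeries
from akiattn.synthetic import SyntheticCohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-stay synthetic cohort shared by pipeline/evaluation tests."""
    spec = SyntheticCohortSpec(n_stays=60)
    return spec, generate_cohort(spec, seed=7)


def make_scr(pairs) -> CreatinineSeries:
    t, v = zip(*pairs)
    return CreatinineSeries(np.array(t, float), np.array(v, float))


def make_urine(pairs, weight=80.0) -> UrineSeries:
    t, v = zip(*pairs)
    return UrineSeries(np.array(t, float), np.array(v, float), weight)


@pytest.fixture
def hourly_urine():
    """Factory: hourly urine chart at a constant rate (ml/kg/h) with
    overrides for chosen hours."""

    def _make(hours, rate=1.0, weight=80.0, overrides=None):
        t = np.arange(1.0, hours + 0.5)
        rates = np.full_like(t, rate)
        for h, r in (overrides or {}).items():
            rates[int(h) - 1] = r
        return UrineSeries(t, rates * weight, weight)

    return _make
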