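import numpy as np
import pytest
from hypothesis import settings

import psdcount as pc

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lognormal_20k():
    """Reference lognormal population: median 20 nm, IQR% 30, 20000 particles."""
    return pc.generate(pc.SyntheticSpec("lognormal", median=20.0, iqr_pct=30.0,
                                        n=20000, seed=1))


@pytest.fixture(scope="session")
def d50_curve_20k(lognormal_20k):
    """Precision curve for D50 of Fmin on the reference population."""
    return pc.precision_curve(lognormal_20k, pc.Measurand.FMIN, "D50",
                              reps=500, seed=1)


@pytest.fixture(scope="session")
def small_design():
    """3 days x 2 replicates design, 3% day CV, +2% bias, 4000 particles each."""
    return pc.generate(pc.SyntheticSpec(
        "lognormal", median=20.0, iqr_pct=30.0, n=4000, seed=7,
        design=pc.DesignSpec(days=3, reps_per_day=2,
                             between_day_cv=0.03, bias_fraction=0.02)))
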