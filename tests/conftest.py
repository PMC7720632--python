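import numpy as np
import pandas as pd
import pytest

from serosig import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient synthetic cohort shared across read-only tests."""
    cfg = SimulationConfig(n_patients=40, rng_seed=7)
    return cfg, generate_cohort(cfg)


def make_survival(n, seed, hazard=0.05, lp=None, censor_hazard=0.02, admin=36.0):
    """Simple exponential PH survival instance for statistics tests."""
    rng = np.random.default_rng(seed)
    lp = np.zeros(n) if lp is None else np.asarray(lp, float)
    T = rng.exponential(1.0 / (hazard * np.exp(lp)))
    C = np.minimum(rng.exponential(1.0 / censor_hazard, n), admin)
    return np.minimum(T, C), (T <= C).astype(int)


@pytest.fixture
def survival_factory():
    return make_survival


def spot_rows(sample, analyte, reps, flags=None, bg=0.0, **extra):
    """Build spot-table rows for one (sample, analyte) triplet."""
    flags = flags or [0] * len(reps)
    base = dict(slide_id="SL01", scan_batch="scan1", slide_batch="slide1",
                subarray=1, clone_id=analyte)
    base.update(extra)
    return [
        dict(sample_id=sample, analyte_id=analyte, replicate=i + 1,
             fg=bg + v, bg=bg, flag=flags[i], **base)
        for i, v in enumerate(reps)
    ]
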