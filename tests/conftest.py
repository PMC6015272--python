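import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trialcea import costing, outcomes, pipeline, synthetic

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def value_set():
    return outcomes.load_value_set()


@pytest.fixture(scope="session")
def unit_costs():
    return costing.load_unit_costs()


@pytest.fixture(scope="session")
def cost_model():
    return costing.default_cost_model()


def make_config(seed=0, n_per_arm=(60, 60), n_centers=6, **kw):
    """Small-trial configuration for fast pipeline tests."""
    return synthetic.TrialConfig(
        n_per_arm=n_per_arm, n_centers=n_centers, seed=seed, **kw
    )


@pytest.fixture(scope="session")
def small_complete_table():
    """Aggregated analysis table of a small complete synthetic trial
    (assessment jitter kept inside the validity window so no outcome is
    invalidated)."""
    cfg = make_config(
        seed=42,
        assess_month_params={0: (0.0, 0.0), 3: (3.0, 0.2), 12: (12.0, 0.4)},
    )
    df, _ = synthetic.generate_trial(cfg)
    return pipeline.prepare_analysis_table(df)


@pytest.fixture(scope="session")
def small_missing_table():
    """Same trial after questionnaire-level nonresponse."""
    cfg = make_config(seed=42)
    df, _ = synthetic.generate_trial(cfg)
    return pipeline.prepare_analysis_table(synthetic.impose_missingness(df, cfg))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
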