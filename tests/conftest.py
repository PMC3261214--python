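import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from epirt import CohortConfig, GeneratorConfig, generate, records
from epirt.irt import irf

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


DEFAULT_WINDOW = CohortConfig(dt.date(1997, 1, 1), dt.date(2006, 12, 31), 30)


def simulate_matrix(alpha, beta, n, seed, theta=None):
    """Raw binary responses from a 2PL, no pipeline, no screening."""
    rng = np.random.default_rng(seed)
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if theta is None:
        theta = rng.standard_normal(n)
    prob = irf(theta[:, None], alpha[None, :], beta[None, :])
    return (rng.random(prob.shape) < prob).astype(np.uint8), theta


@pytest.fixture(scope="session")
def small_config():
    rng = np.random.default_rng(99)
    return GeneratorConfig(
        alpha=rng.uniform(0.8, 2.0, 12),
        beta=np.linspace(-1.5, 2.0, 12),
        n_patients=800,
        n_practices=20,
        practice_sd=0.3,
        duplicate_rate=0.1,
        post_index_spread_days=30,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_events(small_config):
    events, truth = generate(small_config)
    return events, truth


@pytest.fixture(scope="session")
def small_matrix(small_events, small_config):
    events, _ = small_events
    ev = records.deduplicate_same_date(events)
    cohort = records.build_cohort(ev, DEFAULT_WINDOW)
    return records.build_response_matrix(ev, cohort, DEFAULT_WINDOW)


@pytest.fixture(scope="session")
def preset_pipeline():
    """Paper-like preset run through the full records pipeline (shared)."""
    from epirt.synthetic import paper_like_preset

    cfg = paper_like_preset(n_patients=20_000, seed=1)
    events, truth = generate(cfg)
    ev = records.deduplicate_same_date(events)
    cohort = records.build_cohort(ev, DEFAULT_WINDOW)
    matrix = records.build_response_matrix(ev, cohort, DEFAULT_WINDOW)
    return cfg, events, truth, matrix


def events_frame(rows):
    """Build an event table from (patient, practice, code, iso_date) tuples."""
    return pd.DataFrame(
        [
            {
                "patient_id": p,
                "practice_id": pr,
                "code": c,
                "event_date": pd.Timestamp(d),
            }
            for p, pr, c, d in rows
        ]
    )
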