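"""Shared fixtures: seeded synthetic cohorts reused across test modules."""

import numpy as np
import pytest

import uromet as u

COHORT_SEED = 1


@pytest.fixture(scope="session")
def default_cohort():
    """Full default cohort: 54 samples, 998 metabolites, 19 planted markers,
    64 exogenous, 11 unknown-structure features."""
    return u.generate_cohort(u.CohortConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def default_normalized(default_cohort):
    return u.normalize_osmolality(default_cohort.matrix, default_cohort.osmolality)


@pytest.fixture(scope="session")
def null_cohort():
    """Same geometry with no planted effects of any kind."""
    return u.generate_cohort(u.CohortConfig(seed=COHORT_SEED).null())


@pytest.fixture(scope="session")
def three_marker_cohort():
    """Small cohort carrying only the selected three-marker panel
    (folds 12 / 11 / 10, sigma_log 0.5) among 60 metabolites."""
    markers = tuple(m for m in u.DISEASE_MARKERS if m.name in u.THREE_MARKER_PANEL)
    cfg = u.CohortConfig(
        n_metabolites=60,
        planted_markers=markers,
        n_exogenous=0,
        n_unknown_structure=0,
        seed=COHORT_SEED,
    )
    return u.generate_cohort(cfg)


@pytest.fixture(scope="session")
def three_marker_normalized(three_marker_cohort):
    return u.normalize_osmolality(
        three_marker_cohort.matrix, three_marker_cohort.osmolality
    )


def toy_groups(n_cases=15, n_controls=39):
    return ["case"] * n_cases + ["control"] * n_controls


def toy_sample_ids(n):
    return [f"s{i:03d}" for i in range(n)]


def lognormal_matrix(rng, n, p, sigma=0.5, mu=3.0):
    return np.exp(rng.normal(mu, sigma, size=(n, p)))
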