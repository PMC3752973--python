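"""Shared fixtures: calibrated networks and analyzed replicate cohorts.

The expensive session fixtures are shared across test modules so the
default-condition cohorts (35 controls / 38 patients, 300 retained volumes)
are simulated and analyzed once.
"""

from __future__ import annotations

import numpy as np
import pytest

from rsgca.pipeline import compute_subject_maps
from rsgca.preprocess import PreprocConfig, preprocess_series
from rsgca.simulate import CohortConfig, build_default_networks, simulate_cohort


@pytest.fixture(scope="session")
def default_networks():
    return build_default_networks()


def analyze_cohort(subjects, seed_region="rAI"):
    """Preprocess and map every subject; returns list of (subject, gca, fc, pairs)."""
    pp = PreprocConfig()
    out = []
    for s in subjects:
        clean = preprocess_series(s.series, pp, s.confounds, s.confound_names)
        gca, fc, pairs = compute_subject_maps(clean, s.regions, seed_region, s.id)
        out.append((s, gca, fc, pairs))
    return out


@pytest.fixture(scope="session")
def replicate_cohorts(default_networks):
    """20 analyzed replicate cohorts under the default study conditions."""
    reps = []
    for seed in range(20):
        subs = simulate_cohort(CohortConfig(rng_seed=9000 + seed))
        reps.append(analyze_cohort(subs))
    return reps


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for pipeline and I/O tests."""
    return simulate_cohort(
        CohortConfig(n_controls=10, n_patients=10, n_timepoints=120, rng_seed=42)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
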