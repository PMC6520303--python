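"""Shared fixtures: small synthetic cohorts reused across test modules.

All fixtures are seeded and desk-scale (seconds to build) so the suite
stays fast; study-scale behaviour is exercised in the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from eegnetrel import CohortSpec, connectivity_matrix, epoch_and_select
from eegnetrel.cohort import generate_recording

BETA = ("beta", 12.0, 25.0)


def cohort_pli_matrices(spec: CohortSpec, epoch_length: float = 5.0,
                        n_epochs: int = 20, method: str = "pli"):
    """Connectivity matrices for every subject-session of a one-band spec."""
    band_name = spec.bands[0][0]
    mats = []
    for s in range(spec.n_subjects):
        for sess in (1, 2):
            rec = generate_recording(spec, s, sess)
            eps = epoch_and_select(rec, epoch_length, n_epochs,
                                   seed=1000 + s * 2 + sess,
                                   band_name=band_name)
            mats.append(connectivity_matrix(eps, method))
    return mats


@pytest.fixture(scope="session")
def small_cohort_spec() -> CohortSpec:
    """8 subjects x 8 channels x 40 s, beta band only: builds in seconds."""
    return CohortSpec(n_subjects=8, n_channels=8, duration=40.0,
                      bands=(BETA,), session_stability=0.8, seed=5)


@pytest.fixture(scope="session")
def small_cohort_matrices(small_cohort_spec):
    return cohort_pli_matrices(small_cohort_spec, epoch_length=5.0,
                               n_epochs=8)


def random_symmetric_matrix(rng: np.random.Generator, n: int,
                            low: float = 0.05, high: float = 0.9) -> np.ndarray:
    """Random positive symmetric zero-diagonal matrix (a synthetic PLI)."""
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = rng.uniform(low, high, size=len(iu[0]))
    return m + m.T
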