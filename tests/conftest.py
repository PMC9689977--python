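"""Shared fixtures: simulator voices and a small labeled cohort table."""

import numpy as np
import pytest

import glottiswt as g
from glottiswt.pipeline import cohort_feature_table


@pytest.fixture(scope="session")
def clean_voice():
    """An unperturbed 1 s vowel with its ground-truth glottal signal."""
    rec, truth = g.render_voice(
        g.LFParams(f0_hz=140.0),
        g.TractSpec(),
        g.PathologyProfile("clean"),
        duration_s=1.0,
        seed=3,
    )
    return rec, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A 10+10 healthy/polyp-like cohort (1 s recordings, fixed seed)."""
    spec = g.binary_cohort_spec(n_per_class=10, duration_s=1.0)
    recs, truths = g.make_cohort(spec, seed=7)
    return recs, truths


@pytest.fixture(scope="session")
def small_cohort_table(small_cohort):
    """Descriptor table for the small cohort (full default pipeline)."""
    recs, _ = small_cohort
    return cohort_feature_table(recs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
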