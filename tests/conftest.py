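"""Shared fixtures: canonical synthetic profiles with known truth."""

import numpy as np
import pytest

from dlmokit import synthetic
from dlmokit.profile import MelatoninProfile


@pytest.fixture
def clean_truth():
    """Noiseless canonical profile: onset 22.25 h, baseline 1 pg/mL,
    linear rise 4 pg/mL/h, sampled 19:00-01:00 every 30 min."""
    return synthetic.generate_profile(conc_cv=0.0)


@pytest.fixture
def clean_profile(clean_truth):
    return clean_truth.profile


@pytest.fixture
def noisy_truth():
    """Same shape with 7.9% multiplicative assay noise, fixed seed."""
    return synthetic.generate_profile(conc_cv=0.079, seed=42)


@pytest.fixture
def zigzag_profile():
    """Ascending region whose tail zig-zags above threshold; its minimal
    parallelogram has diagonal/lateral slope ratio <= 1/2, so truncation
    rule 2 fires (twice)."""
    return MelatoninProfile(
        id="zigzag",
        times=np.array([-1.0, -0.5, 0.0, 0.3, 1.2, 1.5]),
        concentrations=np.array([1.0, 1.0, 1.0, 5.0, 2.5, 5.2]),
    )
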