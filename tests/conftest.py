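"""Shared fixtures: one trained model chain, one default sample, one
calibration setup — session-scoped because they are deterministic and
several test modules exercise them."""

from __future__ import annotations

import numpy as np
import pytest

import edtaqc as eq
from edtaqc.pipeline import calibrate, generate_blank, generate_standards
from edtaqc.templates import default_template_db

LW_PPM = 1.5 / 600.13  # default line width at the reference field


@pytest.fixture(scope="session")
def db():
    return default_template_db()


@pytest.fixture(scope="session")
def chain():
    return eq.train_default_chain(n=120, seed=7)


@pytest.fixture(scope="session")
def sample():
    """One default synthetic serum-EDTA sample (spectrum, truth)."""
    return eq.generate_spectrum(eq.GeneratorConfig(), seed=1)


@pytest.fixture(scope="session")
def noise_free_sample():
    cfg = eq.GeneratorConfig(noise_sd=0.0)
    return eq.generate_spectrum(cfg, seed=2)


@pytest.fixture(scope="session")
def calib_setup(chain, db):
    blank = generate_blank(600.13, seed=5)
    standards = generate_standards(600.13, 8, seed=11)
    return calibrate(standards, blank, chain, db)


def integral_over(spectrum, low, high):
    sl = spectrum.region_slice(low, high)
    return float(np.sum(spectrum.intensity[sl]) * spectrum.dppm)
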