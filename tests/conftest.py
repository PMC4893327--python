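"""Shared fixtures: published-scale preferred ranges and small synthetic studies."""

from __future__ import annotations

import numpy as np
import pytest

from thermoreg.records import PreferredTemperatureRange
from thermoreg.synthetic import generate_study


@pytest.fixture(scope="session")
def ptr_specialist() -> PreferredTemperatureRange:
    """Narrow, low set-point range of a cold-adapted specialist."""
    return PreferredTemperatureRange(27.9, 29.7)


@pytest.fixture(scope="session")
def ptr_generalist() -> PreferredTemperatureRange:
    """Broad, high set-point range of a thermal generalist."""
    return PreferredTemperatureRange(30.1, 34.5)


@pytest.fixture(scope="session")
def study():
    """One small synthetic two-species study (1 day of logging)."""
    return generate_study(seed=11, days=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
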