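import numpy as np
import pytest

from cbcpref.schema import Attribute, AttributeSchema, pain_treatment_schema
from cbcpref.simulate import (
    PanelSpec,
    SegmentSpec,
    _levels_to_coded,
    _TRADER_MEANS,
    make_panel,
)


@pytest.fixture(scope="session")
def schema():
    return pain_treatment_schema()


@pytest.fixture(scope="session")
def tiny_schema():
    """Two binary attributes: the smallest legal schema (p = 2)."""
    return AttributeSchema(
        (Attribute("first", ("a", "b")), Attribute("second", ("x", "y")))
    )


@pytest.fixture(scope="session")
def trader_mean(schema):
    """A realistic single-segment mean part-worth vector."""
    return _levels_to_coded(schema, _TRADER_MEANS["W"])


@pytest.fixture(scope="session")
def small_panel(schema, trader_mean):
    """One-segment, one-wave panel of 40 respondents for model tests."""
    segments = [
        SegmentSpec("seg", 1.0, tuple(trader_mean), heterogeneity_sd=0.3)
    ]
    return make_panel(
        segments,
        PanelSpec(n_respondents=40, waves=1, seed=42),
        schema,
        t=10,
        seed=42,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
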