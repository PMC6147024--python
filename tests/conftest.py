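"""Shared fixtures: a small default synthetic study and its quantification."""

import numpy as np
import pytest

from conmeth.diffmeth import StudyDesign
from conmeth.rrbs import quantify_fragments
from conmeth.simulate import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """One default-configuration synthetic study, shared across tests."""
    return simulate_bundle(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_meth(default_bundle):
    b = default_bundle
    return quantify_fragments(b.calls, b.fragments, 10, 3, b.design)


@pytest.fixture()
def design_3v3():
    return StudyDesign(
        {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"},
        group_order=["A", "B"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
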