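"""Shared fixtures.

The heavy periodic-branch continuations are session-scoped so that the
acceptance checks for the torus/period-doubling points, the branch-tail
classifications and the two-parameter bracketing all share one computation
per parameter set.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from pyrcell import ModelParameters, full_diagram

warnings.filterwarnings("ignore", message=".*step collapsed.*")
warnings.filterwarnings("ignore", message=".*cycle Newton stopped.*")


@pytest.fixture(scope="session")
def ca3():
    return ModelParameters()


@pytest.fixture(scope="session")
def ca1():
    return ModelParameters(gCa=7.0)


@pytest.fixture(scope="session")
def isapp_diagram_ca3():
    """Full somatic-current diagram of the CA3 cell (gCa=10)."""
    return full_diagram(ModelParameters(), "ISapp", start_p=10.0,
                        period_cap=160.0)


@pytest.fixture(scope="session")
def isapp_diagram_ca1():
    """Full somatic-current diagram of the CA1 variant (gCa=7)."""
    return full_diagram(ModelParameters(gCa=7.0), "ISapp", start_p=10.0,
                        period_cap=1500.0)
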