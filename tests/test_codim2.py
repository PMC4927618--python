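"""Two-parameter continuation: slice consistency with the codim-1 diagrams.

The augmented fold/Hopf defining systems are validated by the published
construction rule: a horizontal slice of a codim-2 curve at fixed gCa must
land on the one-parameter bifurcation value for that gCa.
"""

import numpy as np
import pytest

from pyrcell import (ModelParameters, continue_codim1_in_two_params,
                     equilibrium_diagram)


@pytest.fixture(scope="module")
def ca3_diagram():
    return equilibrium_diagram(ModelParameters(), "ISapp")


def test_sn1_curve_slices_match_codim1(ca3_diagram):
    curve = continue_codim1_in_two_params(
        ModelParameters(), ca3_diagram.labels["SN1"], "ISapp",
        gca_range=(6.5, 10.5))
    g = curve.gca_values
    assert g.min() < 7.0 and g.max() > 10.0
    # slices at the two published gCa values (rheobase folds)
    assert curve.I_at_gca(10.0) == pytest.approx(0.02651, abs=1e-3)
    assert curve.I_at_gca(7.0) == pytest.approx(0.0557, abs=1e-3)


def test_hb_curve_slices_match_codim1(ca3_diagram):
    curve = continue_codim1_in_two_params(
        ModelParameters(), ca3_diagram.labels["HB"], "ISapp",
        gca_range=(6.5, 10.5))
    assert curve.I_at_gca(10.0) == pytest.approx(23.69, abs=0.02)
    assert curve.I_at_gca(7.0) == pytest.approx(24.01, abs=0.02)


def test_sn2_curve_spans_window_without_meeting_sn1_hb(ca3_diagram):
    sn2 = continue_codim1_in_two_params(
        ModelParameters(), ca3_diagram.labels["SN2"], "ISapp",
        gca_range=(6.0, 11.0))
    g = sn2.gca_values
    assert g.min() < 6.5 and g.max() > 10.5
    # SN2 sits at strongly negative currents, far from SN1 (near 0) and
    # HB (near +24) throughout the window
    assert np.all(sn2.I_values < -70.0)
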