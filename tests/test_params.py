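"""Parameter sets, presets and serialization."""

import pytest

from pyrcell import ModelParameters, load_params, preset, save_params


def test_defaults_are_published_ca3_set():
    p = ModelParameters()
    assert (p.gNa, p.gKDR, p.gKCa, p.gKAHP) == (30.0, 15.0, 15.0, 0.8)
    assert (p.gCa, p.gL, p.gC) == (10.0, 0.1, 2.1)
    assert (p.VNa, p.VK, p.VCa, p.VL) == (60.0, -75.0, 80.0, -60.0)
    assert p.p == 0.5 and p.Cm == 3.0
    assert p.ISapp == 0.0 and p.IDapp == 0.0


def test_presets():
    assert preset("ca3_default") == ModelParameters()
    ca1 = preset("ca1_gca7")
    assert ca1.gCa == 7.0
    assert ca1.replace(gCa=10.0) == ModelParameters()
    with pytest.raises(ValueError):
        preset("nope")


@pytest.mark.parametrize("bad", [
    {"gNa": -1.0}, {"p": 0.0}, {"p": 1.0}, {"Cm": 0.0},
    {"variant": "fancy"},
])
def test_invalid_parameters_rejected(bad):
    with pytest.raises(ValueError):
        ModelParameters(**bad)


def test_yaml_round_trip(tmp_path):
    p = preset("ca1_gca7", ISapp=0.3, variant="original")
    f = tmp_path / "pars.yaml"
    save_params(p, f)
    assert load_params(f) == p


def test_unknown_keys_rejected():
    with pytest.raises(ValueError, match="unknown"):
        ModelParameters.from_dict({"gNa": 30.0, "gNaP": 1.0})
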