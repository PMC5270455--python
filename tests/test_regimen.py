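import numpy as np
import pytest

from timdyn import Regimen, algorithm2_build, cspbn_to_ptim, evaluate_regimen
from timdyn.fixtures import load_fixture


@pytest.fixture(scope="module")
def model():
    return algorithm2_build(load_fixture("table5"), epsilon=0.05, p=0.001, q=0.001)


def test_regimen_needs_at_least_one_phase():
    with pytest.raises(ValueError):
        Regimen(())


def test_sustained_regimen_equals_map_entry(model):
    mp = cspbn_to_ptim(model)
    for targets in (set(), {"K3"}, {"K2", "K3"}, {"K1", "K2", "K3"}):
        res = evaluate_regimen(model, Regimen.sustained(targets))
        assert res.sensitivity == pytest.approx(
            mp.entry(targets), abs=1e-10
        )


def test_sustained_k3_matches_published_steady_state(model):
    res = evaluate_regimen(model, Regimen.sustained({"K3"}))
    assert res.sensitivity == pytest.approx(0.65, abs=0.01)


def test_alternating_regimen_is_rotation_invariant(model):
    a = evaluate_regimen(model, Regimen.alternating({"K3"}, {"K1", "K2"}))
    b = evaluate_regimen(model, Regimen.alternating({"K1", "K2"}, {"K3"}))
    assert a.sensitivity == pytest.approx(b.sensitivity, abs=1e-9)
    assert sorted(a.phase_sensitivities) == pytest.approx(
        sorted(b.phase_sensitivities), abs=1e-9
    )


def test_phase_sensitivities_average_to_reported_value(model):
    res = evaluate_regimen(model, Regimen.alternating({"K3"}, set()))
    assert res.sensitivity == pytest.approx(
        np.mean(res.phase_sensitivities)
    )
    assert len(res.phase_sensitivities) == 2


def test_plain_sequences_are_accepted(model):
    res = evaluate_regimen(model, [{"K3"}, {"K1", "K2"}])
    ref = evaluate_regimen(model, Regimen.alternating({"K3"}, {"K1", "K2"}))
    assert res.sensitivity == pytest.approx(ref.sensitivity)
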