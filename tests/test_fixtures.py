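import numpy as np
import pytest

from timdyn import binarize, cut_tim
from timdyn.fixtures import (
    fixture_names,
    load_fixture,
    random_pathway,
    random_ptim,
)


def test_every_fixture_loads():
    for name in fixture_names():
        assert load_fixture(name) is not None


def test_unknown_fixture_reports_available_names():
    with pytest.raises(KeyError, match="table5"):
        load_fixture("nope")


def test_reference_map_binarizes_to_reference_tim():
    tim = binarize(load_fixture("table2"), 0.5)
    assert np.array_equal(tim.bits, load_fixture("fig1_tim").bits)


def test_screen_map_binarizes_to_its_level_maps():
    ptim = load_fixture("table8")
    for alpha, name in ((0.3, "table9"), (0.55, "table10"), (0.8, "table11")):
        assert np.array_equal(binarize(ptim, alpha).bits, load_fixture(name).bits)


def test_level_maps_are_nested_and_monotone():
    t9, t10, t11 = (load_fixture(n) for n in ("table9", "table10", "table11"))
    for tim in (t9, t10, t11):
        tim.check_monotone()
    # deeper levels block fewer combinations
    assert np.all(t11.bits <= t10.bits)
    assert np.all(t10.bits <= t9.bits)


def test_reference_chain_rows_are_stochastic():
    chain = load_fixture("table3")
    assert np.allclose(chain.P.sum(axis=1), 1.0)


def test_random_pathway_is_reproducible_and_self_sustaining():
    a = random_pathway(5)
    b = random_pathway(5)
    assert a.blocks == b.blocks
    heads = {line[0] for line in a.blocks[0]}
    assert a.mutations == heads


def test_random_ptim_levels_follow_cut_function():
    pw = random_pathway(9)
    ptim = random_ptim(9, pw, levels=(0.6, 0.9), noise=0.0)
    tim = cut_tim(pw)
    # every blocked combination of the shallow map scores at least 0.6
    assert np.all(ptim.values[tim.bits == 1] >= 0.6 - 1e-12)
    assert np.all(ptim.values[tim.bits == 0] == 0.0)


def test_random_ptim_rejects_excessive_noise():
    pw = random_pathway(3)
    with pytest.raises(ValueError):
        random_ptim(3, pw, levels=(0.6, 0.9), noise=0.2)
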