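import numpy as np
import pytest

from timdyn import (
    BlockStructure,
    expected_bound,
    experiment_bounds,
    simulate_orientation_discovery,
    worst_case_bound,
)
from timdyn.fixtures import load_fixture


def test_published_structure_closed_form_bounds():
    s = load_fixture("fig4_structure")
    assert worst_case_bound(s) == 6
    assert expected_bound(s) == pytest.approx(13 / 3)


def test_all_singleton_serial_chain_bounds():
    # block-ordering only: worst L-1, expected (2L-1)/3
    s = BlockStructure(((1,),) * 4)
    assert worst_case_bound(s) == 3
    assert expected_bound(s) == pytest.approx(7 / 3)


def test_single_block_needs_no_ordering_experiments():
    s = BlockStructure(((1, 1),))
    assert worst_case_bound(s) == 0
    assert expected_bound(s) == 0.0


def test_bounds_object_orders_worst_above_expected():
    b = experiment_bounds(load_fixture("fig4_structure"))
    assert b.worst_case >= b.expected >= 0


def test_simulated_counts_respect_worst_case():
    s = load_fixture("fig4_structure")
    counts = simulate_orientation_discovery(s, runs=2000, seed=7)
    assert counts.max() <= worst_case_bound(s)
    assert counts.min() >= 0


def test_pure_serial_chain_simulation_matches_expectation():
    s = BlockStructure(((1,),) * 5)
    counts = simulate_orientation_discovery(s, runs=20_000, seed=3)
    assert counts.max() <= 4
    assert counts.mean() == pytest.approx(3.0, abs=0.05)  # (2*5-1)/3


def test_simulation_is_seed_reproducible():
    s = load_fixture("fig4_structure")
    a = simulate_orientation_discovery(s, runs=500, seed=11)
    b = simulate_orientation_discovery(s, runs=500, seed=11)
    assert np.array_equal(a, b)
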