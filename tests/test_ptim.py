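import numpy as np
import pytest

from timdyn import (
    GridLayout,
    MonotonicityError,
    PTIM,
    TIM,
    TargetPanel,
    binarize,
    feasible_mutation_patterns,
    gray_order,
    minimal_blocking_sets,
    read_ptim_text,
    write_ptim,
)
from timdyn.fixtures import load_fixture


def test_panel_encode_decode_roundtrip():
    panel = TargetPanel(("A", "B", "C"))
    for i in range(panel.n_subsets):
        assert panel.encode(panel.decode(i)) == i
    # first target is the most significant bit
    assert panel.encode({"A"}) == 0b100
    assert panel.encode({"C"}) == 0b001


def test_panel_rejects_duplicates_and_unknowns():
    with pytest.raises(ValueError):
        TargetPanel(("A", "A"))
    panel = TargetPanel(("A", "B"))
    with pytest.raises(KeyError):
        panel.encode({"Z"})


def test_gray_order_adjacent_entries_differ_in_one_bit():
    seq = gray_order(3)
    assert len(seq) == 8 and len(set(seq)) == 8
    assert seq[0] == (0, 0, 0)
    for a, b in zip(seq, seq[1:]):
        assert sum(x != y for x, y in zip(a, b)) == 1


def test_ptim_values_validated():
    panel = TargetPanel(("A",))
    with pytest.raises(ValueError):
        PTIM(panel, np.array([0.0, 1.2]))
    with pytest.raises(ValueError):
        PTIM(panel, np.array([0.0, 0.5, 0.5]))


def test_binarize_closed_lower_boundary():
    panel = TargetPanel(("A",))
    ptim = PTIM(panel, np.array([0.0, 0.55]))
    assert binarize(ptim, 0.55).bits[panel.encode({"A"})] == 1
    assert binarize(ptim, 0.551).bits[panel.encode({"A"})] == 0


def test_monotonicity_check_names_violating_pair():
    panel = TargetPanel(("A", "B"))
    tim = TIM(panel, np.array([0, 1, 0, 0], dtype=np.int8))
    with pytest.raises(MonotonicityError):
        tim.check_monotone()


def test_grid_roundtrip_preserves_values():
    ptim = load_fixture("table5")
    text = write_ptim(ptim, fmt="grid")
    back = read_ptim_text(text)
    for subset in ptim.panel.subsets():
        assert back.entry(subset) == pytest.approx(ptim.entry(subset))


def test_json_roundtrip_preserves_values():
    ptim = load_fixture("table2")
    back = read_ptim_text(write_ptim(ptim, fmt="json"), fmt="json")
    for subset in ptim.panel.subsets():
        assert back.entry(subset) == pytest.approx(ptim.entry(subset))


def test_grid_layout_splits_columns_first():
    panel = TargetPanel(("A", "B", "C"))
    layout = GridLayout.from_panel(panel)
    assert layout.column_targets == ("A", "B")
    assert layout.row_targets == ("C",)


def test_minimal_blocking_sets_of_parallel_serial_map():
    tim = load_fixture("fig1_tim")
    assert minimal_blocking_sets(tim) == [
        frozenset({"K3"}),
        frozenset({"K1", "K2"}),
    ]


def test_feasible_mutation_patterns_are_the_blocking_subsets():
    tim = load_fixture("fig1_tim")
    pats = feasible_mutation_patterns(tim)
    assert len(pats) == 5
    assert frozenset({"K3"}) in pats
    assert frozenset({"K1"}) not in pats
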