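import numpy as np
import pytest

from timdyn import (
    InterventionMask,
    TargetPanel,
    attractor,
    bn_from_tim,
    bn_step,
    bn_to_tim,
    build_bn,
    cut_tim,
    transition_table,
)
from timdyn.boolnet import bn_chain_matrix
from timdyn.fixtures import load_fixture, random_pathway
from timdyn.pathway import DirectionalPathway


def test_intervention_matrix_matches_published_form():
    T = InterventionMask(TargetPanel(("K1", "K2", "K3")), frozenset({"K1", "K2"})).matrix()
    assert np.array_equal(T, load_fixture("table1"))
    # one 1 per row, projection is idempotent
    assert np.array_equal(T.sum(axis=1), np.ones(16))
    assert np.array_equal(T @ T, T)


def test_intervention_fixed_points_and_preimages_partition_space():
    mask = InterventionMask(TargetPanel(("A", "B")), frozenset({"A"}))
    fps = mask.fixed_points()
    assert all(mask.apply(s) == s for s in fps)
    covered = sorted(s for fp in fps for s in mask.preimage(fp))
    assert covered == list(range(8))


def test_published_transition_of_parallel_serial_network():
    bn = build_bn(load_fixture("fig2a_pathway"))
    # with only K3 active the constitutive targets recover, K3 decays
    # (no upstream), and the tumor reads the previous K3 state
    assert bn.next_state(0b0010) == 0b1101


def test_network_profile_equals_cut_function_for_published_pathway():
    pw = load_fixture("fig2a_pathway")
    bn = build_bn(pw)
    assert np.array_equal(bn_to_tim(bn).bits, cut_tim(pw).bits)


def test_network_profile_equals_cut_function_on_random_pathways():
    for seed in range(20):
        pw = random_pathway(seed, L_range=(1, 4), max_targets=8)
        bn = build_bn(pw)
        assert np.array_equal(
            bn_to_tim(bn).bits, cut_tim(pw).bits
        ), f"seed {seed}"


def test_unmutated_head_without_activator_is_rejected():
    pw = DirectionalPathway(blocks=((("A",), ("B",)),), mutations=frozenset({"A"}))
    with pytest.raises(ValueError):
        build_bn(pw)


def test_monotone_fallback_reproduces_majority_map():
    tim = load_fixture("table6")[1]
    bn = bn_from_tim(tim)
    assert np.array_equal(bn_to_tim(bn).bits, tim.bits)


def test_attractor_under_full_inhibition_is_tumor_free():
    bn = build_bn(load_fixture("fig2a_pathway"))
    cyc = attractor(bn, bn.mask({"K1", "K2", "K3"}))
    assert all(s & 1 == 0 for s in cyc)


def test_step_masks_successor_not_predecessor():
    bn = build_bn(load_fixture("fig2a_pathway"))
    mask = bn.mask({"K1"})
    s = bn.panel.n_states - 1
    assert bn_step(bn, s, mask) == mask.apply(bn.next_state(s))


def test_chain_matrix_is_deterministic_and_consistent():
    bn = build_bn(load_fixture("fig2a_pathway"))
    P = bn_chain_matrix(bn)
    succ = transition_table(bn)
    assert np.array_equal(P.sum(axis=1), np.ones(P.shape[0]))
    assert all(P[s, succ[s]] == 1.0 for s in range(P.shape[0]))
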