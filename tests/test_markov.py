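import numpy as np
import pytest

from timdyn import (
    InterventionMask,
    MarkovChain,
    ReducibleChainError,
    TargetPanel,
    aggregate_distribution,
    algorithm1_chain,
    chain_to_ptim,
    flip_matrix,
    masked_chain,
    perturb,
    stationary,
    trivial_chain_from_ptim,
)
from timdyn.fixtures import load_fixture


def _random_ergodic_chain(panel, rng):
    N = panel.n_states
    P = rng.uniform(0.01, 1.0, size=(N, N))
    return MarkovChain(panel, P / P.sum(axis=1, keepdims=True))


def test_chain_validation_rejects_non_stochastic_rows():
    panel = TargetPanel(("A",))
    with pytest.raises(ValueError):
        MarkovChain(panel, np.eye(4) * 0.5)


def test_flip_matrix_is_hamming_kernel():
    F = flip_matrix(3, 0.1)
    assert F[0b000, 0b101] == pytest.approx(0.1 * 0.9 * 0.1)
    assert np.allclose(F.sum(axis=1), 1.0)
    F0 = flip_matrix(3, 0.1, noiseless_lsb=True)
    assert F0[0b000, 0b001] == 0.0


def test_reset_and_redirect_masking_agree_after_aggregation():
    # the two intervention semantics give identical aggregated steady states
    rng = np.random.default_rng(0)
    panel = TargetPanel(("A", "B"))
    for _ in range(25):
        chain = _random_ergodic_chain(panel, rng)
        for inhibited in ({"A"}, {"B"}, {"A", "B"}):
            mask = InterventionMask(panel, frozenset(inhibited))
            pi_reset = stationary(masked_chain(chain, mask, "reset").P)
            pi_redirect = stationary(masked_chain(chain, mask, "redirect").P)
            agg = aggregate_distribution(pi_reset, mask)
            assert np.allclose(agg, pi_redirect, atol=1e-10)


def test_redirected_chain_lives_on_post_intervention_states():
    rng = np.random.default_rng(1)
    panel = TargetPanel(("A", "B"))
    chain = _random_ergodic_chain(panel, rng)
    mask = InterventionMask(panel, frozenset({"A"}))
    pi = stationary(masked_chain(chain, mask, "redirect").P)
    off = [s for s in range(panel.n_states) if mask.apply(s) != s]
    assert np.allclose(pi[off], 0.0)


def test_trivial_chain_reproduces_any_sensitivity_map_exactly():
    ptim = load_fixture("table2")
    chain = trivial_chain_from_ptim(ptim)
    model = chain_to_ptim(chain, p=0.0)
    assert np.allclose(model.values, ptim.values, atol=1e-12)


def test_trivial_chain_full_inhibition_robust_to_perturbation():
    # under full inhibition only the deepest pair survives masking, so the
    # perturbed steady state still approaches its split as p -> 0
    ptim = load_fixture("table2")
    chain = trivial_chain_from_ptim(ptim)
    full = set(ptim.panel.names)
    for p in (1e-3, 1e-4):
        model = chain_to_ptim(chain, p=p)
        assert model.entry(full) == pytest.approx(ptim.entry(full), abs=60 * p)


def test_reference_chain_reproduces_its_source_map_at_zero_noise():
    chain = load_fixture("table3")
    model = chain_to_ptim(chain, p=0.0)
    ptim = load_fixture("table2")
    # uncoupled entries are exact; the coupled combination {K1, K2} carries
    # the rounding of the published matrix (0.12 where 0.125 is exact)
    assert model.entry({"K2", "K3"}) == pytest.approx(0.65)
    assert model.entry({"K1", "K3"}) == pytest.approx(0.7)
    assert model.entry({"K1", "K2", "K3"}) == pytest.approx(0.9)
    assert np.max(np.abs(model.values - ptim.values)) < 0.01


def test_identity_chain_needs_a_start_state():
    panel = TargetPanel(("A",))
    chain = MarkovChain(panel, np.eye(4))
    with pytest.raises(ReducibleChainError):
        stationary(chain.P)
    pi = stationary(chain.P, start=2)
    assert pi[2] == pytest.approx(1.0)


def test_absorbing_mixture_weights_from_start_state():
    # from state 0 the chain splits 30/70 between two absorbing states
    P = np.array(
        [
            [0.0, 0.3, 0.7, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    pi = stationary(P, start=0)
    assert pi[1] == pytest.approx(0.3)
    assert pi[2] == pytest.approx(0.7)


def test_single_network_chain_matches_input_map():
    ptim = load_fixture("table2")
    chain = algorithm1_chain(ptim, alpha=0.5, mutations={"K1", "K2"})
    model = chain_to_ptim(chain, p=0.0)
    assert np.allclose(model.values, ptim.values, atol=1e-9)


def test_single_network_chain_small_noise_agreement():
    ptim = load_fixture("table2")
    chain = algorithm1_chain(ptim, alpha=0.5, mutations={"K1", "K2"})
    model = chain_to_ptim(chain, p=0.001)
    assert np.max(np.abs(model.values - ptim.values)) < 0.005


def test_perturbed_chain_is_strictly_positive():
    chain = load_fixture("table3")
    assert np.all(perturb(chain, 0.01).P > 0)
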