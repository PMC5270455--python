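import numpy as np
import pytest

from timdyn import (
    LevelDecomposition,
    algorithm2_build,
    bn_to_tim,
    cspbn_chain,
    cspbn_to_ptim,
    ptim_error,
    sensitivity_levels,
)
from timdyn.fixtures import load_fixture, random_pathway, random_ptim
from timdyn.pathway import NotSeriesParallelError
from timdyn.ptim import PTIM, TargetPanel


def test_level_clustering_on_three_level_map():
    dec = sensitivity_levels(load_fixture("table5"), 0.05)
    assert dec.levels == pytest.approx((0.65, 0.9, 1.0))
    assert dec.weights == pytest.approx((0.65, 0.25, 0.1))
    assert dec.thresholds == pytest.approx((0.6, 0.85, 0.95))


def test_noise_plateau_is_discarded_and_empty_map_rejected():
    panel = TargetPanel(("A",))
    flat = PTIM(panel, np.array([0.01, 0.03]))
    with pytest.raises(ValueError):
        sensitivity_levels(flat, 0.05)


def test_decomposition_validation():
    with pytest.raises(ValueError):
        LevelDecomposition((0.5, 0.4), (0.45, 0.35), (0.5, -0.1))
    dec = LevelDecomposition((0.6,), (0.55,), (0.6,))
    assert dec.normalized() == pytest.approx((1.0,))


def test_level_networks_match_published_threshold_maps():
    model = algorithm2_build(load_fixture("table5"), epsilon=0.05)
    t6 = load_fixture("table6")
    for bn, ref in zip(model.networks, t6):
        assert np.array_equal(bn_to_tim(bn).bits, ref.bits)


def test_three_level_model_steady_states_match_published_values():
    model = algorithm2_build(load_fixture("table5"), epsilon=0.05, p=0.001, q=0.001)
    mp = cspbn_to_ptim(model)
    mean_err, max_err = ptim_error(mp, load_fixture("table7"))
    assert max_err < 0.01


def test_network_marginal_is_pinned_to_clone_weights():
    model = algorithm2_build(load_fixture("table5"), epsilon=0.05, p=0.001, q=0.001)
    chain = cspbn_chain(model, {"K3"})
    marg = chain.network_marginal(chain.stationary())
    assert np.allclose(marg, model.weights, atol=1e-9)


def test_zeroth_order_law_weighted_sum_of_clone_maps():
    # as p, q -> 0 each map entry approaches sum_k c_k TIM_k
    model = algorithm2_build(load_fixture("table5"), epsilon=0.05, p=1e-5, q=1e-5)
    mp = cspbn_to_ptim(model)
    tims = np.array([bn_to_tim(bn).bits for bn in model.networks], dtype=float)
    expect = np.asarray(model.weights) @ tims
    assert np.max(np.abs(mp.values - expect)) < 1e-3


def test_biological_screen_model_reproduces_rounded_map():
    model = algorithm2_build(
        load_fixture("table8"),
        thresholds=(0.3, 0.55, 0.8),
        weights=(0.5, 0.25, 0.25),
        p=0.001,
        q=0.001,
    )
    for bn, name in zip(model.networks, ("table9", "table10", "table11")):
        assert np.array_equal(bn_to_tim(bn).bits, load_fixture(name).bits)
    mp = cspbn_to_ptim(model)
    _, max12 = ptim_error(mp, load_fixture("table12"))
    assert max12 < 0.01


def test_strict_mode_rejects_non_series_parallel_level():
    with pytest.raises(NotSeriesParallelError):
        algorithm2_build(
            load_fixture("table5"), epsilon=0.05, require_series_parallel=True
        )


def test_planted_level_recovery_on_synthetic_maps():
    from timdyn import cut_tim, minimal_blocking_sets

    rng = np.random.default_rng(42)
    checked = 0
    while checked < 5:
        pw = random_pathway(rng, max_targets=6)
        # a second level only exists when a blocking set can be retired
        if len(minimal_blocking_sets(cut_tim(pw))) < 2:
            continue
        levels = (0.5, 0.8)
        ptim = random_ptim(rng, pw, levels=levels, noise=0.05)
        dec = sensitivity_levels(ptim, epsilon=0.12)
        assert len(dec.levels) == len(levels)
        assert np.allclose(dec.levels, levels, atol=0.06)
        assert np.allclose(dec.weights, np.diff((0.0,) + levels), atol=0.12)
        checked += 1


def test_model_weights_must_form_distribution():
    model = algorithm2_build(load_fixture("table5"), epsilon=0.05)
    assert sum(model.weights) == pytest.approx(1.0)
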