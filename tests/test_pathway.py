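import numpy as np
import pytest

from timdyn import (
    BlockStructure,
    DirectionalPathway,
    NotSeriesParallelError,
    count_models,
    cut_tim,
    enumerate_orientations,
    infer_structures,
)
from timdyn.fixtures import load_fixture, random_pathway


def test_block_structure_validation():
    with pytest.raises(ValueError):
        BlockStructure(())
    with pytest.raises(ValueError):
        BlockStructure(((0,),))


def test_count_models_block_and_line_orderings():
    # L! * prod(b!): two serial blocks, one line of three targets
    assert count_models(BlockStructure(((3,), (1,)))) == 2 * 6
    assert count_models(load_fixture("fig4_structure")) == 720 * 6


def test_pathway_cut_function_matches_published_map():
    pw = load_fixture("fig2a_pathway")
    tim = load_fixture("fig1_tim")
    assert np.array_equal(cut_tim(pw).bits, tim.bits)


def test_inference_recovers_parallel_serial_structure():
    tim = load_fixture("fig1_tim")
    cands = infer_structures(tim)
    assert len(cands) == 1
    blocks = {frozenset(blk) for blk in cands[0].blocks}
    assert blocks == {
        frozenset({frozenset({"K1"}), frozenset({"K2"})}),
        frozenset({frozenset({"K3"})}),
    }


def test_two_orientations_for_two_serial_blocks():
    tim = load_fixture("fig1_tim")
    cand = infer_structures(tim)[0]
    pws = list(enumerate_orientations(cand, {"K1", "K2"}))
    assert len(pws) == 2
    for pw in pws:
        assert np.array_equal(cut_tim(pw).bits, tim.bits)


def test_majority_map_is_monotone_but_not_series_parallel():
    tim = load_fixture("table6")[1]  # blocked by any two of the three targets
    tim.check_monotone()
    assert infer_structures(tim) == []
    with pytest.raises(NotSeriesParallelError):
        infer_structures(tim, raise_on_failure=True)


def test_inference_on_six_target_screen_map():
    tim = load_fixture("table11")
    cands = infer_structures(tim)
    assert len(cands) == 1
    cand = cands[0]
    assert np.array_equal(cut_tim(cand).bits, tim.bits)
    sizes = sorted(tuple(sorted(len(l) for l in blk)) for blk in cand.blocks)
    assert sizes == [(1,), (1, 1, 1, 2)]


def test_inference_inverts_cut_function_on_random_pathways():
    for seed in range(15):
        pw = random_pathway(seed, max_targets=7)
        tim = cut_tim(pw)
        cands = infer_structures(tim)
        assert cands, f"seed {seed}: no structure recovered"
        assert any(
            np.array_equal(cut_tim(c).bits, tim.bits) for c in cands
        )


def test_pathway_serialization_roundtrip():
    pw = load_fixture("fig2a_pathway")
    back = DirectionalPathway.from_json_dict(pw.to_json_dict())
    assert back.blocks == pw.blocks
    assert back.mutations == pw.mutations


def test_pathway_requires_nonempty_mutations():
    with pytest.raises(ValueError):
        DirectionalPathway(blocks=((("A",),),), mutations=frozenset())
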