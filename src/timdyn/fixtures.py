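"""Embedded reference datasets and synthetic generators.

The published worked examples — a three-target sensitivity map with its
hand-built Markov chain, a three-level heterogeneous-tumor example, and a
six-kinase canine osteosarcoma screen — are transcribed here so every layer
of the package is testable without downloads.  Random generators produce
synthetic pathways and layered sensitivity maps for property tests.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .boolnet import InterventionMask
from .markov import MarkovChain
from .pathway import BlockStructure, DirectionalPathway
from .ptim import PTIM, TIM, TargetPanel, ptim_from_grid, tim_from_grid

__all__ = ["load_fixture", "fixture_names", "random_pathway", "random_ptim"]

_K3 = ("K1", "K2", "K3")
_SY = ("IGF1R", "PSMB5", "TGFBR2", "AKT2", "EGFR", "HDAC1")


def _fig1_tim() -> TIM:
    # blocked iff K3 inhibited or both K1 and K2 inhibited
    return tim_from_grid([[0, 0, 1, 0], [1, 1, 1, 1]], _K3)


def _fig2a_pathway() -> DirectionalPathway:
    return DirectionalPathway(
        blocks=((("K1",), ("K2",)), (("K3",),)),
        mutations=frozenset({"K1", "K2"}),
    )


def _fig4_structure() -> BlockStructure:
    # six serial blocks; one line of three targets in series on block 4
    return BlockStructure(((1, 1, 1, 1), (1,), (1,), (3, 1), (1,), (1, 1)))


def _table1() -> np.ndarray:
    panel = TargetPanel(_K3)
    return InterventionMask(panel, frozenset({"K1", "K2"})).matrix()


def _table2() -> PTIM:
    return ptim_from_grid([[0, 0, 0.8, 0], [0.55, 0.65, 0.9, 0.7]], _K3)


def _table3() -> MarkovChain:
    panel = TargetPanel(_K3)
    rows = {
        0b0000: {0b0001: 0.1, 0b0010: 0.12, 0b1100: 0.78},
        0b0001: {0b0001: 0.1, 0b1100: 0.9},
        0b0010: {0b0011: 0.2, 0b1101: 0.8},
        0b0011: {0b0011: 0.2, 0b1101: 0.8},
        0b0100: {0b0101: 0.3, 0b1110: 0.7},
        0b0101: {0b0101: 0.3, 0b1110: 0.7},
        0b1000: {0b1001: 0.35, 0b1110: 0.65},
        0b1001: {0b1001: 0.35, 0b1110: 0.65},
        0b1100: {0b1101: 0.45, 0b1110: 0.55},
        0b1101: {0b1101: 0.45, 0b1110: 0.55},
    }
    for s in (0b0110, 0b0111, 0b1010, 0b1011, 0b1110, 0b1111):
        rows[s] = {0b1111: 1.0}
    P = np.zeros((16, 16))
    for s, dests in rows.items():
        for t, pr in dests.items():
            P[s, t] = pr
    return MarkovChain(panel, P)


def _table4() -> PTIM:
    return ptim_from_grid(
        [
            [0.002003, 0.002994, 0.800463, 0.002995],
            [0.549716, 0.649251, 0.89785, 0.698992],
        ],
        _K3,
    )


def _table5() -> PTIM:
    return ptim_from_grid(
        [[0.02, 0.01, 0.98, 0.03], [0.65, 0.89, 1.0, 0.9]], _K3
    )


def _table6() -> tuple[TIM, TIM, TIM]:
    return (
        tim_from_grid([[0, 0, 1, 0], [1, 1, 1, 1]], _K3),
        tim_from_grid([[0, 0, 1, 0], [0, 1, 1, 1]], _K3),
        tim_from_grid([[0, 0, 1, 0], [0, 0, 1, 0]], _K3),
    )


def _table7() -> PTIM:
    return ptim_from_grid(
        [[0.0017, 0.0029, 0.9964, 0.0029], [0.6495, 0.8982, 0.9981, 0.8982]],
        _K3,
    )


_TABLE8_GRID = [
    # columns: Gray order over IGF1R, PSMB5, TGFBR2; rows over AKT2, EGFR, HDAC1
    [0.11, 0.38, 1, 1, 1, 1, 0.68, 0.60],
    [0.55, 0.64, 1, 1, 1, 1, 0.76, 0.68],
    [0.64, 0.64, 1, 1, 1, 1, 0.76, 0.76],
    [0.17, 0.52, 1, 1, 1, 1, 0.68, 0.68],
    [0.58, 0.64, 1, 1, 1, 1, 0.76, 0.76],
    [0.73, 0.76, 1, 1, 1, 1, 0.88, 0.84],
    [0.64, 0.73, 1, 1, 1, 1, 0.84, 0.76],
    [0.47, 0.57, 1, 1, 1, 1, 0.76, 0.68],
]


def _table8() -> PTIM:
    return ptim_from_grid(_TABLE8_GRID, _SY)


def _table9() -> TIM:
    grid = [
        [0, 1, 1, 1, 1, 1, 1, 1],
        [1, 1, 1, 1, 1, 1, 1, 1],
        [1, 1, 1, 1, 1, 1, 1, 1],
        [0, 1, 1, 1, 1, 1, 1, 1],
        [1, 1, 1, 1, 1, 1, 1, 1],
        [1, 1, 1, 1, 1, 1, 1, 1],
        [1, 1, 1, 1, 1, 1, 1, 1],
        [1, 1, 1, 1, 1, 1, 1, 1],
    ]
    return tim_from_grid(grid, _SY)


def _table10() -> TIM:
    grid = [
        [0, 0, 1, 1, 1, 1, 1, 1],
        [1, 1, 1, 1, 1, 1, 1, 1],
        [1, 1, 1, 1, 1, 1, 1, 1],
        [0, 0, 1, 1, 1, 1, 1, 1],
        [1, 1, 1, 1, 1, 1, 1, 1],
        [1, 1, 1, 1, 1, 1, 1, 1],
        [1, 1, 1, 1, 1, 1, 1, 1],
        [0, 1, 1, 1, 1, 1, 1, 1],
    ]
    return tim_from_grid(grid, _SY)


def _table11() -> TIM:
    grid = [
        [0, 0, 1, 1, 1, 1, 0, 0],
        [0, 0, 1, 1, 1, 1, 0, 0],
        [0, 0, 1, 1, 1, 1, 0, 0],
        [0, 0, 1, 1, 1, 1, 0, 0],
        [0, 0, 1, 1, 1, 1, 0, 0],
        [0, 0, 1, 1, 1, 1, 1, 1],
        [0, 0, 1, 1, 1, 1, 1, 0],
        [0, 0, 1, 1, 1, 1, 0, 0],
    ]
    return tim_from_grid(grid, _SY)


def _table12() -> PTIM:
    grid = [
        [0.00, 0.50, 0.99, 0.99, 0.99, 1.00, 0.75, 0.75],
        [0.75, 0.75, 1.00, 0.99, 0.99, 1.00, 0.75, 0.75],
        [0.75, 0.75, 1.00, 0.99, 0.99, 1.00, 0.75, 0.75],
        [0.00, 0.50, 0.99, 0.99, 0.99, 1.00, 0.75, 0.75],
        [0.75, 0.75, 1.00, 0.99, 0.99, 1.00, 0.75, 0.75],
        [0.75, 0.75, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00],
        [0.75, 0.75, 1.00, 0.99, 0.99, 1.00, 1.00, 0.75],
        [0.50, 0.75, 1.00, 0.99, 0.99, 1.00, 0.75, 0.75],
    ]
    return ptim_from_grid(grid, _SY)


_FIXTURES = {
    "fig1_tim": _fig1_tim,
    "fig2a_pathway": _fig2a_pathway,
    "fig4_structure": _fig4_structure,
    "table1": _table1,
    "table2": _table2,
    "table3": _table3,
    "table4": _table4,
    "table5": _table5,
    "table6": _table6,
    "table7": _table7,
    "table8": _table8,
    "table9": _table9,
    "table10": _table10,
    "table11": _table11,
    "table12": _table12,
}


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def load_fixture(name: str):
    """Return a validated fixture object by name."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        ) from None
    return builder()


# ---------------------------------------------------------------------------
# Synthetic generators


def random_pathway(
    seed: int | np.random.Generator,
    L_range: tuple[int, int] = (1, 3),
    a_range: tuple[int, int] = (1, 3),
    b_range: tuple[int, int] = (1, 2),
    max_targets: int = 10,
) -> DirectionalPathway:
    """Random directional pathway with auto-named targets T01, T02, ...

    Mutations are the first block's line heads, making the circuit
    self-sustaining without latent activations elsewhere.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(200):
        L = int(rng.integers(L_range[0], L_range[1] + 1))
        shape = [
            [
                int(rng.integers(b_range[0], b_range[1] + 1))
                for _ in range(int(rng.integers(a_range[0], a_range[1] + 1)))
            ]
            for _ in range(L)
        ]
        if sum(sum(blk) for blk in shape) <= max_targets:
            break
    else:
        raise ValueError("could not draw a pathway within the target budget")
    counter = 0
    blocks = []
    for blk in shape:
        lines = []
        for b in blk:
            lines.append(tuple(f"T{counter + k + 1:02d}" for k in range(b)))
            counter += b
        blocks.append(tuple(lines))
    heads = frozenset(line[0] for line in blocks[0])
    return DirectionalPathway(blocks=tuple(blocks), mutations=heads)


def random_ptim(
    seed: int | np.random.Generator,
    pathway: DirectionalPathway,
    levels: Iterable[float] = (0.6, 0.9),
    noise: float = 0.0,
) -> PTIM:
    """Layered sensitivity map with planted levels.

    Starting from the pathway's inhibition map, a nested family of monotone
    maps is built by repeatedly retiring a random minimal blocking set; the
    PTIM value of a subset is the level of the deepest map it still blocks,
    plus bounded uniform noise.  By construction the level-decomposition
    step recovers the planted levels and weights to within the noise.
    """
    from .ptim import minimal_blocking_sets
    from .pathway import cut_tim

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    levels = sorted(float(v) for v in levels)
    if not levels or levels[0] <= 0 or levels[-1] > 1:
        raise ValueError("levels must be sorted values in (0, 1]")
    gaps = [levels[0]] + [b - a for a, b in zip(levels, levels[1:])]
    if noise < 0 or (noise > 0 and noise >= min(gaps) / 2):
        raise ValueError(
            f"noise {noise} must be below half the minimum level gap {min(gaps)}"
        )

    panel = pathway.panel
    tims = [cut_tim(pathway)]
    for _ in levels[1:]:
        prev = tims[-1]
        bits = prev.bits.copy()
        msets = minimal_blocking_sets(prev)
        if len(msets) > 1:
            victim = msets[int(rng.integers(len(msets)))]
            bits[panel.encode(victim)] = 0
        tims.append(TIM(panel, bits))

    weights = np.diff([0.0] + levels)
    values = np.zeros(panel.n_subsets)
    for w, tim in zip(weights, tims):
        values += w * tim.bits
    if noise > 0:
        values = values + rng.uniform(-noise, noise, size=values.shape)
    return PTIM(panel, np.clip(values, 0.0, 1.0))
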