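"""Series-parallel pathway structures behind a target inhibition map.

A tumor-survival circuit is modeled as L blocks in series, block i holding
a_i parallel lines, line j of block i holding b_ji targets in series.  The
tumor proliferates while an uncut left-to-right path exists; a drug
combination blocks proliferation exactly when it fully cuts some block,
i.e. hits at least one target on every line of that block.  The TIM only
determines the block/line membership, not the left-to-right orientation of
blocks or the order of targets within a line — those orderings are the
"directional" degrees of freedom that separate the static map from a
dynamic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations, product
from math import factorial, prod
from typing import Iterable, Iterator, Sequence

import numpy as np

from .ptim import TIM, TargetPanel, minimal_blocking_sets

__all__ = [
    "BlockStructure",
    "DirectionalPathway",
    "InferredStructure",
    "NotSeriesParallelError",
    "cut_function",
    "cut_tim",
    "infer_structures",
    "enumerate_orientations",
    "count_models",
]


class NotSeriesParallelError(ValueError):
    """A monotone TIM admits no exact series-parallel circuit; the
    ``uncovered`` attribute lists the minimal blocking sets that could not
    be grouped into one-per-line block transversals."""

    def __init__(self, uncovered):
        self.uncovered = list(uncovered)
        super().__init__(
            "TIM has no exact series-parallel representation; minimal blocking "
            f"sets not factorable into blocks: {[sorted(s) for s in self.uncovered]}"
        )


@dataclass(frozen=True)
class BlockStructure:
    """Shape of a series-parallel circuit: line lengths per block.

    ``blocks[i][j]`` is b_ji, the number of targets on line j of block i.
    """

    blocks: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        blocks = tuple(tuple(int(b) for b in blk) for blk in self.blocks)
        object.__setattr__(self, "blocks", blocks)
        if not blocks:
            raise ValueError("structure needs at least one block")
        for blk in blocks:
            if not blk or any(b < 1 for b in blk):
                raise ValueError(f"each block needs lines of length >= 1, got {blk}")

    @property
    def L(self) -> int:
        return len(self.blocks)

    def a(self, i: int) -> int:
        """Number of parallel lines in block i."""
        return len(self.blocks[i])

    @property
    def n_targets(self) -> int:
        """Total number of targets placed on the circuit (N_K)."""
        return sum(sum(blk) for blk in self.blocks)


def count_models(structure: BlockStructure) -> int:
    """Number of distinct directional models for a structure.

    Block order and within-line target order are free: L! * prod (b_ji)!.
    Parallel lines within a block are unordered.
    """
    return factorial(structure.L) * prod(
        factorial(b) for blk in structure.blocks for b in blk
    )


@dataclass(frozen=True)
class DirectionalPathway:
    """A fully oriented survival circuit.

    ``blocks[i][j]`` is the ordered target list of line j in block i,
    upstream first.  ``mutations`` are the constitutively activated targets
    (initial mutations or latent activations); for a self-sustaining circuit
    they cover the first block's line heads.  ``off_circuit`` maps targets
    that sit on no survival line to their assigned upstream activator; they
    exist in the dynamic state space but never affect proliferation.
    """

    blocks: tuple[tuple[tuple[str, ...], ...], ...]
    mutations: frozenset
    off_circuit: tuple[tuple[str, str], ...] = ()
    panel: TargetPanel | None = None

    def __post_init__(self):
        blocks = tuple(
            tuple(tuple(line) for line in blk) for blk in self.blocks
        )
        object.__setattr__(self, "blocks", blocks)
        object.__setattr__(self, "mutations", frozenset(self.mutations))
        object.__setattr__(
            self, "off_circuit", tuple(sorted(dict(self.off_circuit).items()))
        )
        circuit = [t for blk in blocks for line in blk for t in line]
        off = [t for t, _ in self.off_circuit]
        everyone = circuit + off
        if len(set(everyone)) != len(everyone):
            raise ValueError("each target may appear only once on the circuit")
        if not self.mutations:
            raise ValueError("mutation/latent-activation set must be nonempty")
        unknown = self.mutations - set(everyone)
        if unknown:
            raise ValueError(f"mutations not on the panel: {sorted(unknown)}")
        if self.panel is None:
            object.__setattr__(self, "panel", TargetPanel(tuple(everyone)))
        elif set(self.panel.names) != set(everyone):
            raise ValueError("panel does not match the pathway's targets")

    @property
    def structure(self) -> BlockStructure:
        return BlockStructure(
            tuple(tuple(len(line) for line in blk) for blk in self.blocks)
        )

    def line_ends(self, i: int) -> tuple[str, ...]:
        return tuple(line[-1] for line in self.blocks[i])

    def line_heads(self, i: int) -> tuple[str, ...]:
        return tuple(line[0] for line in self.blocks[i])

    def to_json_dict(self) -> dict:
        return {
            "blocks": [[list(line) for line in blk] for blk in self.blocks],
            "mutations": sorted(self.mutations),
            "off_circuit": dict(self.off_circuit),
        }

    @classmethod
    def from_json_dict(cls, doc: dict) -> "DirectionalPathway":
        return cls(
            blocks=tuple(
                tuple(tuple(line) for line in blk) for blk in doc["blocks"]
            ),
            mutations=frozenset(doc["mutations"]),
            off_circuit=tuple(doc.get("off_circuit", {}).items()),
        )


def _blocks_as_sets(obj) -> list[list[frozenset]]:
    if isinstance(obj, DirectionalPathway):
        return [[frozenset(line) for line in blk] for blk in obj.blocks]
    if isinstance(obj, InferredStructure):
        return [[frozenset(line) for line in blk] for blk in obj.blocks]
    raise TypeError(f"expected a pathway or inferred structure, got {type(obj)!r}")


def cut_function(pathway, subset: Iterable[str]) -> int:
    """1 iff inhibiting ``subset`` fully cuts some block of the circuit.

    Off-circuit targets never affect the outcome.
    """
    subset = set(subset)
    panel = pathway.panel
    for name in subset:
        panel.index(name)  # raises on unknown targets
    for blk in _blocks_as_sets(pathway):
        if all(line & subset for line in blk):
            return 1
    return 0


def cut_tim(pathway) -> TIM:
    """The full 2^n TIM induced by a circuit's cut function."""
    panel = pathway.panel
    bits = np.zeros(panel.n_subsets, dtype=np.int8)
    blocks = _blocks_as_sets(pathway)
    for i in range(panel.n_subsets):
        subset = panel.decode(i)
        bits[i] = 1 if any(all(line & subset for line in blk) for blk in blocks) else 0
    return TIM(panel, bits)


@dataclass(frozen=True)
class InferredStructure:
    """Block/line membership inferred from a TIM, orientation-free.

    ``blocks[i][j]`` is the (unordered) target content of line j of block i;
    ``off_circuit`` are panel targets on no survival line.
    """

    panel: TargetPanel
    blocks: tuple[tuple[frozenset, ...], ...]
    off_circuit: frozenset

    @property
    def structure(self) -> BlockStructure:
        return BlockStructure(
            tuple(tuple(len(line) for line in blk) for blk in self.blocks)
        )


def _factor_block(family: list[frozenset]) -> list[frozenset] | None:
    """Factor a family of equal-size minimal sets into parallel lines.

    Succeeds iff the family is exactly the set of one-target-per-line
    transversals of some collection of disjoint lines.
    """
    sizes = {len(s) for s in family}
    if len(sizes) != 1:
        return None
    a = sizes.pop()
    universe = sorted(set().union(*family))
    co = {x: set() for x in universe}
    for s in family:
        for x, y in combinations(sorted(s), 2):
            co[x].add(y)
            co[y].add(x)
    # same line <=> never co-occur; for a true transversal family this is an
    # equivalence relation, so greedy class building suffices (verified below)
    lines: list[set] = []
    for x in universe:
        for line in lines:
            if not co[x] & line:
                line.add(x)
                break
        else:
            lines.append({x})
    if len(lines) != a:
        return None
    expect = {frozenset(pick) for pick in product(*lines)}
    if expect != set(family):
        return None
    return [frozenset(line) for line in lines]


def infer_structures(tim: TIM, raise_on_failure: bool = False) -> list[InferredStructure]:
    """Series-parallel structures whose cut function reproduces a monotone TIM.

    Minimal blocking sets are grouped into blocks whose cut families are
    one-per-line transversals.  Size-one minimal sets are returned as
    singleton serial blocks (a single line of several targets in series has
    the same cut function; the maximally serial form is the canonical one).
    Targets in no minimal blocking set are off-circuit.  Returns an empty
    list (or raises :class:`NotSeriesParallelError`) when the TIM is
    monotone but not series-parallel, e.g. a 2-of-3 majority map.
    """
    msets = minimal_blocking_sets(tim)
    if not msets:
        raise ValueError("TIM has no blocking set; nothing to infer")
    singles = [s for s in msets if len(s) == 1]
    larger = [s for s in msets if len(s) > 1]

    # union-find over single-exchange adjacency: |S| == |T|, |S ∩ T| == |S|-1
    parent = list(range(len(larger)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(len(larger)), 2):
        s, t = larger[i], larger[j]
        if len(s) == len(t) and len(s & t) == len(s) - 1:
            parent[find(i)] = find(j)

    groups: dict[int, list[frozenset]] = {}
    for i, s in enumerate(larger):
        groups.setdefault(find(i), []).append(s)

    blocks: list[tuple[frozenset, ...]] = [tuple([s]) for s in singles]
    for fam in groups.values():
        lines = _factor_block(fam)
        if lines is None:
            if raise_on_failure:
                raise NotSeriesParallelError(fam)
            return []
        blocks.append(tuple(sorted(lines, key=lambda l: (len(l), sorted(l)))))
    blocks.sort(key=lambda blk: (len(blk), [sorted(l) for l in blk]))

    on_circuit = set().union(*msets)
    off = frozenset(set(tim.panel.names) - on_circuit)
    cand = InferredStructure(tim.panel, tuple(blocks), off)

    # exhaustive safety check: the candidate's cut function must equal the TIM
    ctim = _candidate_cut_tim(cand)
    if not np.array_equal(ctim.bits, tim.bits):
        if raise_on_failure:
            raise NotSeriesParallelError(msets)
        return []
    return [cand]


def _candidate_cut_tim(cand: InferredStructure) -> TIM:
    panel = cand.panel
    bits = np.zeros(panel.n_subsets, dtype=np.int8)
    for i in range(panel.n_subsets):
        subset = panel.decode(i)
        bits[i] = (
            1
            if any(all(line & subset for line in blk) for blk in cand.blocks)
            else 0
        )
    return TIM(panel, bits)


def _default_off_circuit_wiring(
    cand: InferredStructure, ordered_blocks
) -> tuple[tuple[str, str], ...]:
    """Attach off-circuit targets to an activator in the last block.

    The wiring is a modeling convention only: the cut function and every
    inhibition-profile quantity are independent of it.
    """
    if not cand.off_circuit:
        return ()
    anchor = ordered_blocks[-1][0][-1]  # end of the last block's first line
    return tuple((t, anchor) for t in sorted(cand.off_circuit))


def enumerate_orientations(
    cand: InferredStructure, mutations: Iterable[str]
) -> Iterator[DirectionalPathway]:
    """All directional pathways of an inferred structure.

    Yields every block permutation crossed with every within-line target
    permutation (``count_models`` of them).  Each orientation's constitutive
    set is its own first block's line heads — the targets that must hold
    initial activation for the circuit to be self-sustaining; the requested
    ``mutations`` act as a feasibility gate (they must block the tumor when
    jointly inhibited), otherwise the stream is empty.
    """
    mutations = frozenset(mutations)
    if mutations and not any(
        all(line & mutations for line in blk) for blk in cand.blocks
    ):
        return
    if not mutations:
        return
    line_perm_spaces = [
        [list(permutations(sorted(line))) for line in blk] for blk in cand.blocks
    ]
    idx = list(range(len(cand.blocks)))
    for order in permutations(idx):
        per_block_lines = [line_perm_spaces[i] for i in order]
        flat = [space for blk in per_block_lines for space in blk]
        shape = [len(blk) for blk in per_block_lines]
        for pick in product(*flat):
            blocks = []
            k = 0
            for cnt in shape:
                blocks.append(tuple(pick[k : k + cnt]))
                k += cnt
            heads = frozenset(line[0] for line in blocks[0])
            yield DirectionalPathway(
                blocks=tuple(blocks),
                mutations=heads,
                off_circuit=_default_off_circuit_wiring(cand, blocks),
                panel=cand.panel,
            )
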