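"""Deterministic Boolean networks from directional pathways.

The dynamic state packs the n target activities (first panel target as the
most significant bit) and the tumor phenotype as the least significant bit,
giving 2^(n+1) states.  Update rules for the oncogene circuit:

* a constitutively activated target (initial mutation or latent activation)
  returns to 1 one step after any inhibition is lifted;
* any other target copies the OR of its immediate upstream activators —
  its within-line predecessor, or for a line head the line ends of the
  previous block;
* the tumor bit at t+1 is the OR of the terminal block's line-end states at
  time t (a one-step reporter delay, so transient trajectories may show the
  tumor bit oscillating while the drug reshapes the target states).

Sustained inhibition of a target set I is a projection applied after each
update: the successor's I-bits are forced to 0.  As a matrix this is the
0/1 row-stochastic intervention matrix T_c right-multiplying the transition
matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .pathway import DirectionalPathway
from .ptim import TIM, TargetPanel

__all__ = [
    "BooleanNetwork",
    "InterventionMask",
    "build_bn",
    "bn_from_tim",
    "bn_step",
    "transition_table",
    "attractor",
    "bn_to_tim",
]


@dataclass(frozen=True)
class InterventionMask:
    """Sustained inhibition of a target set I on an (n+1)-bit state space.

    ``apply`` forces the I-bits of a state to 0 (the tumor bit is never
    masked); it is idempotent, its fixed points form the post-intervention
    state set I_c, and the induced matrix T_c has exactly one 1 per row.
    """

    panel: TargetPanel
    inhibited: frozenset

    def __post_init__(self):
        object.__setattr__(self, "inhibited", frozenset(self.inhibited))
        for name in self.inhibited:
            self.panel.index(name)

    @property
    def keep_bits(self) -> int:
        """AND-mask over the (n+1)-bit state that zeroes the inhibited targets."""
        n = self.panel.n
        mask = (1 << (n + 1)) - 1
        for name in self.inhibited:
            mask &= ~(1 << (n - self.panel.index(name)))
        return mask

    def apply(self, state: int) -> int:
        return state & self.keep_bits

    def matrix(self) -> np.ndarray:
        N = self.panel.n_states
        T = np.zeros((N, N))
        keep = self.keep_bits
        for s in range(N):
            T[s, s & keep] = 1.0
        return T

    def fixed_points(self) -> list[int]:
        """The post-intervention state set I_c = {s : f_c(s) = s}."""
        keep = self.keep_bits
        return [s for s in range(self.panel.n_states) if s & keep == s]

    def preimage(self, state: int) -> list[int]:
        """S_{c,i}: states that the intervention projects onto ``state``."""
        keep = self.keep_bits
        return [s for s in range(self.panel.n_states) if s & keep == state]


@dataclass(frozen=True)
class BooleanNetwork:
    """Deterministic update on the (n+1)-bit target/tumor state space.

    ``rules[j]`` drives target j: ``("const",)`` for a constitutively
    activated target or ``("or", indices)`` for OR over upstream activators.
    The tumor rule is either ``("or", indices)`` (OR of terminal line ends)
    or ``("tim", bits)`` — a general monotone rule that proliferates exactly
    when the currently inactive targets fail to block the map, used for
    monotone maps with no series-parallel circuit.
    """

    panel: TargetPanel
    rules: tuple[tuple, ...]
    tumor_rule: tuple

    def __post_init__(self):
        if len(self.rules) != self.panel.n:
            raise ValueError("need exactly one rule per target")

    def target_bit(self, state: int, j: int) -> int:
        return state >> (self.panel.n - j) & 1

    def next_state(self, state: int) -> int:
        n = self.panel.n
        nxt = 0
        for j, rule in enumerate(self.rules):
            if rule[0] == "const":
                bit = 1
            else:
                bit = int(any(self.target_bit(state, k) for k in rule[1]))
            nxt |= bit << (n - j)
        kind = self.tumor_rule[0]
        if kind == "or":
            tumor = int(any(self.target_bit(state, k) for k in self.tumor_rule[1]))
        else:  # "tim": survive iff the inactive set does not block
            bits = self.tumor_rule[1]
            inactive_idx = 0
            for j in range(n):
                if not self.target_bit(state, j):
                    inactive_idx |= 1 << (n - 1 - j)
            tumor = int(bits[inactive_idx] == 0)
        return nxt | tumor

    def mask(self, inhibited: Iterable[str]) -> InterventionMask:
        return InterventionMask(self.panel, frozenset(inhibited))

    def to_json_dict(self) -> dict:
        rules = {}
        for j, rule in enumerate(self.rules):
            name = self.panel.names[j]
            if rule[0] == "const":
                rules[name] = {"const": 1}
            else:
                rules[name] = {"or": [self.panel.names[k] for k in rule[1]]}
        if self.tumor_rule[0] == "or":
            tumor = {"or": [self.panel.names[k] for k in self.tumor_rule[1]]}
        else:
            tumor = {"blocking_bits": [int(b) for b in self.tumor_rule[1]]}
        return {"targets": list(self.panel.names), "rules": rules, "tumor": tumor}


def build_bn(pathway: DirectionalPathway) -> BooleanNetwork:
    """Boolean network of a directional pathway.

    Constitutive (mutated / latently activated) targets get constant-1
    rules; every other target must have an upstream activator — its
    within-line predecessor, or for a line head all line ends of the
    previous block; off-circuit targets follow their assigned activator.
    The tumor is driven by the terminal block's line ends.
    """
    panel = pathway.panel
    rules: list[tuple] = [None] * panel.n  # type: ignore[list-item]

    def set_rule(name: str, activators: Sequence[str]):
        j = panel.index(name)
        if name in pathway.mutations:
            rules[j] = ("const",)
        elif activators:
            rules[j] = ("or", tuple(panel.index(a) for a in activators))
        else:
            raise ValueError(
                f"target {name!r} has no upstream activator and is not mutated; "
                "the circuit cannot sustain it"
            )

    for i, blk in enumerate(pathway.blocks):
        upstream_ends = pathway.line_ends(i - 1) if i > 0 else ()
        for line in blk:
            for k, name in enumerate(line):
                set_rule(name, line[k - 1 : k] if k > 0 else upstream_ends)
    for name, activator in pathway.off_circuit:
        set_rule(name, (activator,))

    tumor = ("or", tuple(panel.index(t) for t in pathway.line_ends(len(pathway.blocks) - 1)))
    return BooleanNetwork(panel, tuple(rules), tumor)


def bn_from_tim(tim: TIM) -> BooleanNetwork:
    """Direct Boolean network for any monotone TIM.

    All targets are constitutively active and the tumor proliferates exactly
    when the currently inactive target set fails to block the map.  Under
    sustained inhibition of c the attractor fixes the non-inhibited targets
    at 1 and the tumor bit at 1 - TIM(c), so the network's inhibition
    profile reproduces the TIM even when no series-parallel circuit exists
    (e.g. a 2-of-3 majority map).
    """
    tim.check_monotone()
    rules = tuple(("const",) for _ in range(tim.panel.n))
    return BooleanNetwork(tim.panel, rules, ("tim", tuple(int(b) for b in tim.bits)))


def bn_step(
    bn: BooleanNetwork, state: int, mask: InterventionMask | None = None
) -> int:
    """One synchronous update; the intervention projection (if any) is
    applied to the successor state."""
    if not 0 <= state < bn.panel.n_states:
        raise ValueError(f"state {state} out of range")
    nxt = bn.next_state(state)
    return mask.apply(nxt) if mask is not None else nxt


def transition_table(
    bn: BooleanNetwork, mask: InterventionMask | None = None
) -> np.ndarray:
    """Successor of every state as an integer array of length 2^(n+1)."""
    return np.array(
        [bn_step(bn, s, mask) for s in range(bn.panel.n_states)], dtype=np.int64
    )


def attractor(
    bn: BooleanNetwork,
    mask: InterventionMask | None = None,
    start: int | None = None,
) -> list[int]:
    """The cycle reached under repeated (masked) updates.

    The default start is the all-active state 11...1: every target and the
    tumor on, the reference condition for reading off an inhibition map.
    """
    s = bn.panel.n_states - 1 if start is None else start
    seen: dict[int, int] = {}
    path: list[int] = []
    while s not in seen:
        seen[s] = len(path)
        path.append(s)
        s = bn_step(bn, s, mask)
    return path[seen[s]:]


def bn_to_tim(bn: BooleanNetwork, return_diagnostics: bool = False):
    """Inhibition profile of a Boolean network.

    For every inhibition subset the network is run to its attractor under
    sustained intervention from the all-active state; the entry is 1 iff the
    whole attractor has tumor bit 0.  Attractor cycles with mixed tumor bits
    count as not eradicated (entry 0) and are reported in the diagnostics.
    """
    panel = bn.panel
    bits = np.zeros(panel.n_subsets, dtype=np.int8)
    mixed: dict[frozenset, list[int]] = {}
    for i in range(panel.n_subsets):
        subset = panel.decode(i)
        cyc = attractor(bn, bn.mask(subset))
        tumor_bits = {s & 1 for s in cyc}
        if tumor_bits == {0}:
            bits[i] = 1
        elif len(tumor_bits) == 2:
            mixed[subset] = cyc
    tim = TIM(panel, bits)
    if return_diagnostics:
        return tim, mixed
    return tim


def bn_chain_matrix(bn: BooleanNetwork) -> np.ndarray:
    """The network as a deterministic transition matrix (one 1 per row)."""
    N = bn.panel.n_states
    P = np.zeros((N, N))
    P[np.arange(N), transition_table(bn)] = 1.0
    return P
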