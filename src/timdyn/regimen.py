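"""Sequential drug regimens on context-sensitive PBN models.

A regimen is a periodic schedule of intervention masks (drug combinations),
one per time step.  Under a period-T schedule the model is a time-
inhomogeneous Markov chain; its long-run behavior is captured by the
stationary distribution of the period-product chain P_1 P_2 ... P_T, and
the reported sensitivity is the tumor-free probability averaged over the T
phases of the cycle.  A period-1 regimen reduces exactly to the sustained-
inhibition steady state, i.e. the model-generated PTIM entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cspbn import ContextSensitivePBN, cspbn_chain
from .markov import stationary

__all__ = ["Regimen", "evaluate_regimen"]


@dataclass(frozen=True)
class Regimen:
    """Periodic schedule of drug-target combinations.

    ``phases`` is one target collection per time step; the schedule repeats
    with period ``len(phases)``.  An empty collection means no drug that
    step.
    """

    phases: tuple[frozenset, ...]

    def __post_init__(self):
        object.__setattr__(
            self, "phases", tuple(frozenset(ph) for ph in self.phases)
        )
        if not self.phases:
            raise ValueError("a regimen needs at least one phase")

    @classmethod
    def sustained(cls, targets: Iterable[str]) -> "Regimen":
        return cls((frozenset(targets),))

    @classmethod
    def alternating(
        cls, first: Iterable[str], second: Iterable[str]
    ) -> "Regimen":
        return cls((frozenset(first), frozenset(second)))

    @property
    def period(self) -> int:
        return len(self.phases)


@dataclass(frozen=True)
class RegimenResult:
    """Phase-resolved steady-state outcome of a periodic schedule."""

    regimen: Regimen
    sensitivity: float
    phase_sensitivities: tuple[float, ...]


def evaluate_regimen(
    model: ContextSensitivePBN, regimen: Regimen | Sequence[Iterable[str]]
) -> RegimenResult:
    """Long-run tumor-free probability of a periodic drug schedule.

    The per-phase transition matrices are multiplied into the period-product
    chain, whose stationary distribution gives the phase-0 steady state;
    propagating it through the cycle and averaging the collapsed tumor-0
    mass over all phases yields the reported sensitivity.
    """
    if not isinstance(regimen, Regimen):
        regimen = Regimen(tuple(frozenset(ph) for ph in regimen))
    chains = [cspbn_chain(model, ph) for ph in regimen.phases]
    prod = chains[0].P
    for ch in chains[1:]:
        prod = prod @ ch.P
    if model.p > 0:
        pi = stationary(prod)
    else:
        pi = stationary(prod, start=prod.shape[0] - 1)
    phase_sens = []
    for ch in chains:
        pi = pi @ ch.P
        phase_sens.append(chains[0].tumor0_mass(pi))
    # after the full cycle pi has returned to the phase-0 stationary point
    return RegimenResult(regimen, float(np.mean(phase_sens)), tuple(phase_sens))
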