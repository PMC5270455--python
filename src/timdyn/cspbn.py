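"""Context-sensitive probabilistic Boolean networks from layered maps.

A heterogeneous tumor is modeled as a weighted collection of clones, each a
deterministic Boolean network; per step the governing network is resampled
from the clone proportions with a small switching probability q, the
current network updates the state, sustained inhibition projects it, and
each bit flips independently with a small perturbation probability p.  The
collapsed stationary distribution of the (network x state) chain assigns
each inhibition combination a steady-state tumor-reduction probability; as
p, q -> 0 that probability converges to the weighted sum of the clone
inhibition maps, which is why a layered sensitivity map decomposes into
thresholded binary maps with the level increments as clone weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .boolnet import (
    BooleanNetwork,
    InterventionMask,
    bn_from_tim,
    build_bn,
    transition_table,
)
from .markov import flip_matrix, stationary
from .pathway import NotSeriesParallelError, enumerate_orientations, infer_structures
from .ptim import PTIM, TIM, TargetPanel, binarize

__all__ = [
    "LevelDecomposition",
    "ContextSensitivePBN",
    "CollapsedChain",
    "sensitivity_levels",
    "algorithm2_build",
    "cspbn_chain",
    "cspbn_to_ptim",
    "ptim_error",
]


@dataclass(frozen=True)
class LevelDecomposition:
    """Sensitivity plateaus of a layered map.

    ``levels`` are the plateau values v_1 < ... < v_m above the noise floor,
    ``thresholds`` the per-level binarization cutoffs, and ``weights`` the
    increments (v_1, v_2 - v_1, ...) used as clone selection probabilities.
    The weights sum to v_m <= 1; ``normalized()`` folds the remainder
    1 - v_m into the last clone when a proper distribution is needed.
    """

    levels: tuple[float, ...]
    thresholds: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(float(v) for v in self.levels))
        object.__setattr__(self, "thresholds", tuple(float(v) for v in self.thresholds))
        object.__setattr__(self, "weights", tuple(float(v) for v in self.weights))
        if not (len(self.levels) == len(self.thresholds) == len(self.weights)):
            raise ValueError("levels, thresholds and weights must align")
        if list(self.levels) != sorted(set(self.levels)):
            raise ValueError("levels must be strictly increasing")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be nonnegative")
        if sum(self.weights) > 1 + 1e-9:
            raise ValueError("weights may not sum above 1")

    @classmethod
    def from_thresholds(
        cls, thresholds: Sequence[float], weights: Sequence[float]
    ) -> "LevelDecomposition":
        """Explicit user-chosen cutoffs and clone weights (the biological
        worked example uses equal 0.25 increments after a 0.3 floor)."""
        levels = tuple(np.cumsum(weights))
        return cls(levels, tuple(thresholds), tuple(weights))

    def normalized(self) -> tuple[float, ...]:
        w = list(self.weights)
        w[-1] += 1.0 - sum(w)
        return tuple(w)


def sensitivity_levels(ptim: PTIM, epsilon: float) -> LevelDecomposition:
    """Cluster a map's sensitivities into plateaus of spread <= epsilon.

    The plateau at the bottom is measurement noise around zero and is
    discarded (an error if nothing remains).  Each remaining plateau is
    represented by its maximum v_k and thresholded at v_k - epsilon; the
    weights are the level increments.
    """
    if not 0 < epsilon < 0.5:
        raise ValueError(f"epsilon must lie in (0, 0.5), got {epsilon}")
    vals = np.sort(np.unique(ptim.values))
    clusters: list[list[float]] = [[float(vals[0])]]
    for v in vals[1:]:
        if v - clusters[-1][0] <= epsilon:
            clusters[-1].append(float(v))
        else:
            clusters.append([float(v)])
    if clusters and max(clusters[0]) <= epsilon:
        clusters = clusters[1:]
    if not clusters:
        raise ValueError(
            f"all sensitivities sit in the noise plateau (<= {epsilon}); "
            "no effective inhibition to model"
        )
    levels = tuple(max(c) for c in clusters)
    thresholds = tuple(v - epsilon for v in levels)
    weights = tuple(np.diff((0.0,) + levels))
    return LevelDecomposition(levels, thresholds, weights)


def _bn_for_tim(
    tim: TIM, mutations: frozenset | None, require_series_parallel: bool
) -> BooleanNetwork:
    """A Boolean network whose inhibition profile equals the TIM.

    Preferably built from an inferred series-parallel pathway; monotone maps
    with no such circuit (e.g. 2-of-3 majority) fall back to the direct
    monotone construction.
    """
    cands = infer_structures(tim)
    if cands:
        muts = mutations or frozenset(
            t for line in cands[0].blocks[0] for t in line
        )
        for pw in enumerate_orientations(cands[0], muts):
            return build_bn(pw)
    if require_series_parallel:
        raise NotSeriesParallelError(tim.blocking_sets())
    return bn_from_tim(tim)


@dataclass(frozen=True)
class ContextSensitivePBN:
    """Weighted clone collection with switching and perturbation noise."""

    networks: tuple[BooleanNetwork, ...]
    weights: tuple[float, ...]
    q: float
    p: float

    def __post_init__(self):
        object.__setattr__(self, "networks", tuple(self.networks))
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if not self.networks:
            raise ValueError("need at least one network")
        if len(self.networks) != len(self.weights):
            raise ValueError("one weight per network")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be nonnegative")
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        if not (0 <= self.q < 0.5 and 0 <= self.p < 0.5):
            raise ValueError("switching and perturbation probabilities must be < 0.5")
        panels = {bn.panel.names for bn in self.networks}
        if len(panels) != 1:
            raise ValueError("all networks must share one panel")

    @property
    def panel(self) -> TargetPanel:
        return self.networks[0].panel


def algorithm2_build(
    ptim: PTIM,
    decomposition: LevelDecomposition | None = None,
    *,
    epsilon: float | None = None,
    thresholds: Sequence[float] | None = None,
    weights: Sequence[float] | None = None,
    p: float = 0.001,
    q: float = 0.001,
    mutations: Iterable[str] | None = None,
    require_series_parallel: bool = False,
) -> ContextSensitivePBN:
    """Clonal-evolution model of a layered sensitivity map.

    The map decomposes into levels (automatically from ``epsilon``, or from
    explicit ``thresholds``/``weights``); each level's thresholded TIM gets
    a consistent Boolean network and the level increments become the clone
    selection probabilities (remainder folded into the last clone).  For
    small p and q the model's collapsed steady state reproduces the input
    map within the clustering tolerance.
    """
    if decomposition is None:
        if thresholds is not None:
            if weights is None:
                raise ValueError("explicit thresholds require explicit weights")
            decomposition = LevelDecomposition.from_thresholds(thresholds, weights)
        elif epsilon is not None:
            decomposition = sensitivity_levels(ptim, epsilon)
        else:
            raise ValueError("supply a decomposition, epsilon, or thresholds+weights")
    muts = frozenset(mutations) if mutations is not None else None
    nets = []
    for thr in decomposition.thresholds:
        tim = binarize(ptim, thr)
        nets.append(_bn_for_tim(tim, muts, require_series_parallel))
    return ContextSensitivePBN(
        tuple(nets), decomposition.normalized(), q=q, p=p
    )


@dataclass(frozen=True)
class CollapsedChain:
    """The (network index x state) Markov chain of a model under one mask."""

    model: ContextSensitivePBN
    mask: InterventionMask
    P: np.ndarray

    @property
    def n_states(self) -> int:
        return self.model.panel.n_states

    def stationary(self) -> np.ndarray:
        if self.model.p > 0:
            return stationary(self.P)
        return stationary(self.P, start=self.P.shape[0] - 1)

    def collapsed(self, pi: np.ndarray) -> np.ndarray:
        """Sum a (network x state) distribution over networks."""
        return pi.reshape(len(self.model.networks), self.n_states).sum(axis=0)

    def network_marginal(self, pi: np.ndarray) -> np.ndarray:
        return pi.reshape(len(self.model.networks), self.n_states).sum(axis=1)

    def tumor0_mass(self, pi: np.ndarray | None = None) -> float:
        pi = self.stationary() if pi is None else pi
        return float(self.collapsed(pi)[0::2].sum())


def cspbn_chain(
    model: ContextSensitivePBN, inhibited: Iterable[str] = ()
) -> CollapsedChain:
    """Collapsed chain under sustained inhibition.

    Per step: with probability q the governing network is resampled from
    the clone weights (possibly landing on the same one — which pins the
    stationary network marginal to the weights), the current network
    updates the state, the intervention projects it, and each of the n+1
    bits flips independently with probability p.
    """
    panel = model.panel
    mask = InterventionMask(panel, frozenset(inhibited))
    K = len(model.networks)
    N = panel.n_states
    F = flip_matrix(panel.n + 1, model.p) if model.p > 0 else np.eye(N)
    c = np.asarray(model.weights)
    W = (1 - model.q) * np.eye(K) + model.q * np.tile(c, (K, 1))
    P = np.zeros((K * N, K * N))
    for k2 in range(K):
        succ = transition_table(model.networks[k2], mask)
        S = np.zeros((N, N))
        S[np.arange(N), succ] = 1.0
        B = S @ F
        for k1 in range(K):
            if W[k1, k2] > 0:
                P[k1 * N : (k1 + 1) * N, k2 * N : (k2 + 1) * N] = W[k1, k2] * B
    return CollapsedChain(model, mask, P)


def cspbn_to_ptim(model: ContextSensitivePBN) -> PTIM:
    """Model-generated PTIM: collapsed stationary tumor-0 mass per
    inhibition combination."""
    panel = model.panel
    values = np.empty(panel.n_subsets)
    for i in range(panel.n_subsets):
        chain = cspbn_chain(model, panel.decode(i))
        values[i] = chain.tumor0_mass()
    return PTIM(panel, np.clip(values, 0.0, 1.0))


def ptim_error(model_ptim: PTIM, reference_ptim: PTIM) -> tuple[float, float]:
    """Mean and maximum absolute entrywise difference of two maps."""
    if model_ptim.panel.names != reference_ptim.panel.names:
        raise ValueError(
            f"panel mismatch: {model_ptim.panel.names} vs {reference_ptim.panel.names}"
        )
    d = np.abs(model_ptim.values - reference_ptim.values)
    return float(d.mean()), float(d.max())
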