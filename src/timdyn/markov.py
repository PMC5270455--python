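"""Markov-chain layer: interventions, perturbation, stationary analysis.

A chain lives on the same 2^(n+1) target/tumor states as the Boolean
networks.  Sustained inhibition of a target set can be modeled two ways —
resetting each row to the row of its masked image ("reset"), or aggregating
each column onto its masked image, i.e. right-multiplying by the
intervention matrix ("redirect") — and the two agree after aggregating the
stationary mass over intervention preimages.  Ergodicity is obtained by
following each transition with independent per-bit flips of small
probability p, after which the chain's inhibition profile (stationary mass
of tumor-bit-0 states per inhibition subset) is the model-generated PTIM.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from typing import Iterable

import numpy as np
import scipy.linalg
import scipy.optimize

from .boolnet import BooleanNetwork, InterventionMask, bn_chain_matrix, build_bn, transition_table
from .pathway import DirectionalPathway, enumerate_orientations, infer_structures
from .ptim import PTIM, TIM, TargetPanel, binarize

__all__ = [
    "MarkovChain",
    "PerturbationSpec",
    "ReducibleChainError",
    "masked_chain",
    "aggregate_distribution",
    "perturb",
    "flip_matrix",
    "stationary",
    "trivial_chain_from_ptim",
    "chain_to_ptim",
    "algorithm1_chain",
    "Algorithm1Error",
]

_ROWSUM_TOL = 1e-12


class ReducibleChainError(ValueError):
    """Stationary distribution is not unique; supply a start state for
    trajectory-restricted analysis."""


class Algorithm1Error(RuntimeError):
    """The single-network chain construction could not match the PTIM."""


@dataclass(frozen=True)
class MarkovChain:
    """Row-stochastic transition matrix on the (n+1)-bit state space."""

    panel: TargetPanel
    P: np.ndarray

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float)
        object.__setattr__(self, "P", P)
        N = self.panel.n_states
        if P.shape != (N, N):
            raise ValueError(f"expected a {N}x{N} matrix, got {P.shape}")
        if np.any(P < 0):
            raise ValueError("transition probabilities must be nonnegative")
        if np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("rows must sum to 1")

    @classmethod
    def from_bn(cls, bn: BooleanNetwork) -> "MarkovChain":
        return cls(bn.panel, bn_chain_matrix(bn))

    def mask(self, inhibited: Iterable[str]) -> InterventionMask:
        return InterventionMask(self.panel, frozenset(inhibited))


@dataclass(frozen=True)
class PerturbationSpec:
    """Independent per-step flip probability for each of the n+1 bits.

    ``bits="targets"`` restricts the flips to the n target bits, leaving the
    tumor bit noiseless.
    """

    p: float
    bits: str = "all"

    def __post_init__(self):
        if not 0 <= self.p < 0.5:
            raise ValueError(f"flip probability must lie in [0, 0.5), got {self.p}")
        if self.bits not in ("all", "targets"):
            raise ValueError(f"bits must be 'all' or 'targets', got {self.bits!r}")


def masked_chain(
    chain: MarkovChain, mask: InterventionMask, semantics: str = "redirect"
) -> MarkovChain:
    """Chain under sustained inhibition.

    ``"reset"``: row j becomes the row of the masked image of j (the system
    is reset to the post-drug state and evolves from there).  ``"redirect"``:
    every transition into j is redirected into the masked image of j, which
    is exactly P @ T_c.  Both stay row-stochastic; their stationary
    distributions agree after preimage aggregation.
    """
    P = chain.P
    N = P.shape[0]
    keep = mask.keep_bits
    if semantics == "reset":
        idx = np.array([s & keep for s in range(N)])
        return MarkovChain(chain.panel, P[idx, :])
    if semantics == "redirect":
        Q = np.zeros_like(P)
        for j in range(N):
            Q[:, j & keep] += P[:, j]
        return MarkovChain(chain.panel, Q)
    raise ValueError(f"unknown intervention semantics {semantics!r}")


def aggregate_distribution(pi: np.ndarray, mask: InterventionMask) -> np.ndarray:
    """Collect the mass of every intervention preimage class onto its
    masked representative; zero elsewhere, total mass preserved."""
    pi = np.asarray(pi, dtype=float)
    keep = mask.keep_bits
    out = np.zeros_like(pi)
    for s in range(pi.shape[0]):
        out[s & keep] += pi[s]
    return out


def flip_matrix(n_bits: int, p: float, noiseless_lsb: bool = False) -> np.ndarray:
    """Matrix of independent per-bit flips: entry (i, j) = p^d (1-p)^(k-d)
    with d the Hamming distance, over the bits allowed to flip."""
    single = np.array([[1 - p, p], [p, 1 - p]])
    keep = np.eye(2)
    mats = [single] * (n_bits - 1) + [keep if noiseless_lsb else single]
    return reduce(np.kron, mats)


def perturb(chain: MarkovChain, spec: PerturbationSpec | float) -> MarkovChain:
    """Follow each transition with independent bit flips; strictly positive
    (hence ergodic) for p > 0 with all bits flippable."""
    if not isinstance(spec, PerturbationSpec):
        spec = PerturbationSpec(float(spec))
    if spec.p == 0:
        return chain
    F = flip_matrix(chain.panel.n + 1, spec.p, noiseless_lsb=spec.bits == "targets")
    return MarkovChain(chain.panel, chain.P @ F)


def _irreducible_stationary(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of an irreducible (possibly periodic) chain."""
    N = P.shape[0]
    A = P.T - np.eye(N)
    A[-1, :] = 1.0
    b = np.zeros(N)
    b[-1] = 1.0
    try:
        pi = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        pi = np.linalg.lstsq(A, b, rcond=None)[0]
    pi = np.clip(np.real(pi), 0.0, None)
    return pi / pi.sum()


def stationary(
    chain: MarkovChain | np.ndarray,
    start: int | None = None,
) -> np.ndarray:
    """Solve pi P = pi, sum(pi) = 1.

    Without a start state the chain must have a unique stationary
    distribution (checked through the null space of P^T - I).  With a start
    state the long-run time-average from that state is returned: the
    recurrent classes reachable from the start are found, their stationary
    distributions solved exactly, and mixed by the absorption probabilities
    — this covers reducible and periodic chains alike.
    """
    P = chain.P if isinstance(chain, MarkovChain) else np.asarray(chain, dtype=float)
    N = P.shape[0]
    if start is None:
        ns = scipy.linalg.null_space(P.T - np.eye(N), rcond=1e-10)
        if ns.shape[1] == 0:  # numerical corner; fall back to eigenvector
            w, v = np.linalg.eig(P.T)
            ns = np.real(v[:, [int(np.argmin(np.abs(w - 1.0)))]])
        if ns.shape[1] > 1:
            raise ReducibleChainError(
                f"stationary distribution is not unique ({ns.shape[1]}-dimensional "
                "fixed space); supply a start state"
            )
        pi = np.real(ns[:, 0])
        pi = pi / pi.sum()
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()
    if not 0 <= start < N:
        raise ValueError(f"start state {start} out of range")
    return _trajectory_stationary(P, start)


def _trajectory_stationary(P: np.ndarray, start: int) -> np.ndarray:
    import scipy.sparse
    import scipy.sparse.csgraph

    N = P.shape[0]
    # reachable set from start
    reach = {start}
    frontier = [start]
    while frontier:
        s = frontier.pop()
        for t in np.nonzero(P[s] > 0)[0]:
            t = int(t)
            if t not in reach:
                reach.add(t)
                frontier.append(t)
    idx = sorted(reach)
    sub = P[np.ix_(idx, idx)]
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(sub > 0), directed=True, connection="strong"
    )
    # terminal (closed) strongly connected components
    terminal = []
    for c in range(n_comp):
        members = np.nonzero(labels == c)[0]
        out_mass = sub[members, :].sum() - sub[np.ix_(members, members)].sum()
        if out_mass < 1e-14:
            terminal.append(members)
    pi = np.zeros(N)
    if len(terminal) == 1:
        members = terminal[0]
        loc = _irreducible_stationary(sub[np.ix_(members, members)])
        for m, v in zip(members, loc):
            pi[idx[m]] = v
        return pi
    # several closed classes: weight each by its absorption probability
    closed = set(int(m) for members in terminal for m in members)
    trans = [s for s in range(len(idx)) if s not in closed]
    T = sub[np.ix_(trans, trans)]
    weights = []
    for members in terminal:
        r = sub[np.ix_(trans, members)].sum(axis=1)
        absorb = np.linalg.solve(np.eye(len(trans)) - T, r) if trans else None
        s0 = idx.index(start) if start in idx else 0
        if start in [idx[m] for m in members]:
            w = 1.0
        elif trans:
            w = float(absorb[trans.index(idx.index(start))])
        else:
            w = 0.0
        weights.append(w)
    for members, w in zip(terminal, weights):
        if w <= 0:
            continue
        loc = _irreducible_stationary(sub[np.ix_(members, members)])
        for m, v in zip(members, loc):
            pi[idx[m]] += w * v
    return pi / pi.sum()


def trivial_chain_from_ptim(ptim: PTIM) -> MarkovChain:
    """The closed-pair chain that realizes any PTIM.

    For each inhibition index i the two states D1 = 2(2^n - i - 1) and
    D2 = D1 + 1 (target bits = complement of i; tumor bit 0 resp. 1) form a
    closed class with P(., D1) = p_i and P(., D2) = 1 - p_i, so the
    stationary tumor-0 mass under inhibition i is exactly p_i.
    """
    panel = ptim.panel
    N = panel.n_states
    P = np.zeros((N, N))
    for i in range(panel.n_subsets):
        d1 = 2 * (panel.n_subsets - i - 1)
        d2 = d1 + 1
        pi = ptim.values[i]
        for d in (d1, d2):
            P[d, d1] = pi
            P[d, d2] = 1 - pi
    return MarkovChain(panel, P)


def _tumor0_mass(pi: np.ndarray) -> float:
    return float(pi[0::2].sum())


def chain_to_ptim(
    chain: MarkovChain,
    p: float,
    bits: str = "all",
    semantics: str = "redirect",
    start: int | None = None,
) -> PTIM:
    """Model-generated PTIM of a chain.

    Per inhibition subset: apply the intervention, add per-bit perturbation
    p, solve the stationary distribution and sum the tumor-bit-0 mass.
    With p = 0 a start state (default: the all-active state) restricts the
    analysis to the trajectory actually reached.
    """
    panel = chain.panel
    spec = PerturbationSpec(p, bits)
    values = np.empty(panel.n_subsets)
    for i in range(panel.n_subsets):
        mask = InterventionMask(panel, panel.decode(i))
        pc = perturb(masked_chain(chain, mask, semantics), spec)
        if p > 0 and start is None:
            pi = stationary(pc)
        else:
            pi = stationary(pc, start=panel.n_states - 1 if start is None else start)
        values[i] = _tumor0_mass(pi)
    return PTIM(panel, np.clip(values, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Single-network chain construction (stem-cell perspective)


def _pair_states(panel: TargetPanel, i: int) -> tuple[int, int]:
    d1 = 2 * (panel.n_subsets - i - 1)
    return d1, d1 + 1


def _masked_limit_value(P: np.ndarray, panel: TargetPanel, c: int) -> float:
    """Stationary tumor-0 mass under sustained inhibition c at p -> 0,
    restricted to the trajectory from the all-active state."""
    mask = InterventionMask(panel, panel.decode(c))
    Q = masked_chain(MarkovChain(panel, P), mask, "redirect").P
    pi = stationary(Q, start=panel.n_states - 1)
    return _tumor0_mass(pi)


def _select_pathway(ptim: PTIM, alpha: float, mutations: frozenset) -> DirectionalPathway:
    tim = binarize(ptim, alpha)
    cands = infer_structures(tim)
    if not cands:
        raise Algorithm1Error(
            f"the PTIM thresholded at alpha={alpha} admits no series-parallel "
            "circuit; no consistent Boolean network backbone exists"
        )
    for pw in enumerate_orientations(cands[0], mutations):
        if frozenset(pw.mutations) <= mutations or pw.mutations == mutations:
            return pw
    raise Algorithm1Error(
        f"no orientation has its first-block heads inside the mutation set "
        f"{sorted(mutations)}"
    )


def algorithm1_chain(
    ptim: PTIM,
    alpha: float,
    mutations: Iterable[str],
    pathway: DirectionalPathway | None = None,
    tol: float = 0.02,
) -> MarkovChain:
    """Markov chain whose inhibition profile matches a PTIM, built around a
    single Boolean-network backbone (cancer stem-cell perspective).

    The PTIM is thresholded and a consistent directional pathway supplies
    the deterministic backbone F.  For every inhibition combination i the
    complementary state pair (D1, D2) receives the closed-pair split: mass
    p_i continues along the backbone from D1 (returning to the pair under
    sustained inhibition i when the map blocks), mass 1 - p_i falls to the
    tumor-1 partner; combinations the map leaves unblocked use the direct
    pair split since their backbone runs away to tumorous states.  Sustained
    inhibition of a combination whose masked flow passes through deeper
    pairs couples their sensitivities; each such combination is resolved by
    a one-dimensional search that reroutes part of the deep pair's backbone
    mass toward the shallow pair until the masked stationary tumor-0 mass
    equals the requested sensitivity.
    """
    mutations = frozenset(mutations)
    panel = ptim.panel
    tim = binarize(ptim, alpha)
    if pathway is None:
        pathway = _select_pathway(ptim, alpha, mutations)
    bn = build_bn(pathway)
    if set(bn.panel.names) != set(panel.names):
        raise ValueError("pathway panel does not match the PTIM panel")
    # reindex the backbone onto the PTIM's panel order
    order = [bn.panel.index(name) for name in panel.names]
    succ_bn = transition_table(bn)

    def backbone(s: int) -> int:
        # translate state s (PTIM panel order) through the BN and back
        n = panel.n
        t = 0
        for jj, k in enumerate(order):
            t |= ((s >> (n - jj)) & 1) << (n - k)
        t |= s & 1
        u = int(succ_bn[t])
        out = 0
        for jj, k in enumerate(order):
            out |= ((u >> (n - k)) & 1) << (n - jj)
        return out | (u & 1)

    vals = ptim.values
    if np.all((vals == 0) | (vals == 1)):
        # a binary PTIM needs no stochastic split: the backbone itself is the chain
        N = panel.n_states
        P = np.zeros((N, N))
        for s in range(N):
            P[s, backbone(s)] = 1.0
        return MarkovChain(panel, P)

    N = panel.n_states
    P = np.zeros((N, N))
    for i in range(panel.n_subsets):
        d1, d2 = _pair_states(panel, i)
        p_i = float(vals[i])
        dest = backbone(d1) if tim.bits[i] else d1
        for d in (d1, d2):
            P[d, dest] += p_i
            P[d, d2] += 1 - p_i

    # resolve coupled combinations: reroute deep-pair backbone mass
    for _ in range(3):
        worst_c, worst_err = None, 0.0
        for c in sorted(range(panel.n_subsets), key=lambda x: bin(x).count("1")):
            v = _masked_limit_value(P, panel, c)
            err = abs(v - vals[c])
            if err <= 1e-9:
                continue
            if err > worst_err:
                worst_c, worst_err = c, err
            _resolve_coupling(P, panel, c, vals, backbone)
        if worst_c is None:
            break
    # final verification of the contract
    errs = [
        abs(_masked_limit_value(P, panel, c) - vals[c])
        for c in range(panel.n_subsets)
    ]
    if max(errs) > tol:
        c = int(np.argmax(errs))
        raise Algorithm1Error(
            f"could not match the PTIM: inhibition {sorted(panel.decode(c))} "
            f"is off by {max(errs):.4f} (> {tol})"
        )
    return MarkovChain(panel, P)


def _resolve_coupling(P, panel: TargetPanel, c: int, vals, backbone) -> None:
    """One-dimensional reroute for a coupled inhibition combination.

    Under sustained inhibition c the trajectory from the all-active state
    settles into a recurrent class containing the pair of some deeper
    combination j*.  Splitting row D1(j*)'s backbone mass between its
    backbone successor and D1(c) tunes the class's stationary tumor-0 mass;
    the split is solved by bisection.
    """
    mask = InterventionMask(panel, panel.decode(c))
    Q = masked_chain(MarkovChain(panel, P), mask, "redirect").P
    # recurrent pairs reached from the masked all-active state
    reach = {panel.n_states - 1}
    frontier = [panel.n_states - 1]
    while frontier:
        s = frontier.pop()
        for t in np.nonzero(Q[s])[0]:
            if t not in reach:
                reach.add(int(t))
                frontier.append(int(t))
    deep = [
        j
        for j in range(panel.n_subsets)
        if j != c and set(_pair_states(panel, j)) & reach and vals[j] != vals[c]
    ]
    if not deep:
        return
    jstar = max(deep, key=lambda j: bin(j).count("1"))
    d1s, d2s = _pair_states(panel, jstar)
    d1c, _ = _pair_states(panel, c)
    bb = backbone(d1s)
    p_star = float(vals[jstar])

    def value_at(x: float) -> float:
        row = np.zeros(panel.n_states)
        row[bb] += p_star - x
        row[d1c] += x
        row[d2s] += 1 - p_star
        saved = P[d1s].copy()
        P[d1s] = row
        v = _masked_limit_value(P, panel, c)
        P[d1s] = saved
        return v

    lo, hi = 0.0, p_star
    flo, fhi = value_at(lo) - vals[c], value_at(hi) - vals[c]
    if flo == 0:
        x = lo
    elif flo * fhi > 0:
        return  # not resolvable along this axis; overall check will decide
    else:
        x = scipy.optimize.brentq(lambda t: value_at(t) - vals[c], lo, hi, xtol=1e-12)
    row = np.zeros(panel.n_states)
    row[bb] += p_star - x
    row[d1c] += x
    row[d2s] += 1 - p_star
    P[d1s] = row
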