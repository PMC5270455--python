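# Methods

## State and map conventions

- A **target panel** lists n ≤ 16 inhibitable targets. Inhibition subsets are
  indexed by an n-bit integer with the **first-listed target as the most
  significant bit**.
- The **dynamic state** has n + 1 bits: the n target activities (same bit
  order) plus the **tumor bit as the least significant bit**; 1 means
  proliferating.
- A **PTIM** stores 2^n sensitivities in [0, 1]; a **TIM** stores bits
  (1 = the combination blocks proliferation). Grid I/O uses the reflected
  Gray sequence over the first ⌈n/2⌉ targets as columns and the rest as rows.
- **Binarization** uses a closed lower boundary: bit = 1 iff sensitivity ≥ α.
  Published screen maps have cells exactly on the thresholds, so the boundary
  convention is observable and fixed by those tables.

## Structure inference

A monotone TIM's inclusion-minimal blocking sets are factored into serial
blocks of parallel lines: a family of equal-size minimal sets forms a block
iff it is exactly the set of one-target-per-line transversals of disjoint
lines; singleton minimal sets become singleton serial blocks (canonical
maximally-serial form; a single serial line of k targets has the same cut
function as k singleton blocks). A final exhaustive check verifies the
reconstructed cut function equals the TIM; maps that fail (e.g. 2-of-3
majority, which is monotone but not series-parallel) return no structure.
Orientation is not identifiable from kill data: `enumerate_orientations`
yields all L!·∏(b!) directional models, each taking its own first block's
line heads as the constitutive (mutated/latently activated) set.

## Experiment design

Worst case per block: max(max_j b_j − 2, ⌈(Σ_j b_j − a)/(a − 1)⌉ − 1),
clamped at 0 (the divisor term only for blocks with a ≥ 2 lines), plus L − 1
block-ordering experiments. Expected: max_j (2 b_j − 4)/3 clamped at 0, plus
(2L − 1)/3 when L ≥ 2. The source presentation of the expected bound contains
a garbled second summand; the reduced form above is the one whose value
matches the printed reference number (13/3) and is what the package returns.
The simulator mirrors the derivation: random-pivot resolution of the block
order (expected (2m − 1)/3, worst m − 1) and b − 2 within-line position
queries per line (first query free with probability 1/3, queries batched
across up to a − 1 lines per experiment).

## Boolean networks

Rules: constitutive targets are constant 1; every other target is the OR of
its immediate upstream activators (within-line predecessor, or the previous
block's line ends for a line head); the tumor bit at t + 1 is the OR of the
terminal block's line ends at time t (one-step reporter delay, fixed by the
published example transition 0010 → 1101). Sustained inhibition is applied
to the successor state (mask-after-update), equivalently right-multiplying
the transition matrix by the intervention projection T_c. For monotone maps
with no series-parallel circuit, `bn_from_tim` provides a fallback network:
all targets constitutive and a table-driven monotone tumor rule, whose
inhibition profile still equals the TIM.

## Markov chains

- Two intervention semantics are provided: **reset** (each row is replaced by
  the row of its masked image) and **redirect** (P·T_c). Their stationary
  distributions agree after aggregating every intervention preimage class
  onto its representative; this equivalence is tested on random ergodic
  chains at 1e−10.
- **Perturbation** composes the chain with independent per-bit flips over all
  n + 1 bits (matrix ⊗[[1−p, p], [p, 1−p]]). The source leaves the convention
  unstated (targets-only vs all bits); flipping all bits reproduces the
  published perturbed steady states to ≤ 6e−6, so it is the default, with
  the targets-only variant available via `bits="targets"`.
- Stationary solving uses a null-space computation with a uniqueness check;
  reducible chains require a start state and are resolved exactly via
  reachable-set + strongly-connected-component analysis and absorption
  probabilities.
- The **closed-pair chain** realizes any PTIM exactly: for combination i the
  state pair with target bits complementary to i splits its mass p_i / 1−p_i
  between tumor-0 and tumor-1. The realization is exact at p = 0 under the
  trajectory (start-state) convention; for p > 0 the ergodic stationary
  spreads mass over every pair surviving the mask, so pointwise convergence
  as p → 0 holds only for combinations where a single pair survives (e.g.
  full inhibition). The single-network construction (`algorithm1_chain`,
  whose published pseudocode is not available and was reconstructed from the
  printed example matrix) places the pair splits on a Boolean-network
  backbone; combinations whose pairs are dynamically coupled are resolved by
  a one-dimensional exact reroute (Brent solve), which yields 0.125 where the
  published matrix rounds to 0.12.

## Context-sensitive PBNs

`sensitivity_levels` greedily clusters the sorted distinct sensitivities into
plateaus of spread ≤ ε; the bottom plateau (max ≤ ε) is measurement noise and
is discarded. Each remaining plateau is represented by its maximum v_k,
thresholded at v_k − ε; the increments v_k − v_{k−1} are the clone selection
probabilities (any remainder 1 − v_m is folded into the deepest clone).
Each clone is a Boolean network consistent with its level TIM (inferred
pathway when one exists, monotone fallback otherwise — acceptance values
depend only on the TIMs and weights, not the wiring). The collapsed chain on
K·2^(n+1) states applies per step: network resampling with probability q
(from the clone weights, pinning the stationary network marginal to the
weights), the current network's masked update, and the per-bit flip kernel.
As p, q → 0 each map entry approaches Σ_k c_k·TIM_k(i) (zeroth-order law),
which bounds the reconstruction error by the quantization error of the level
decomposition.

## Regimens

A regimen is a periodic sequence of intervention masks. The package forms the
period-product chain, takes its stationary distribution (start-state analysis
when p = 0), propagates it through the cycle, and reports the time average of
the collapsed tumor-free mass over the phases. Period-1 regimens equal the
model map entries exactly; the reported value is rotation invariant. The
source's printed alternating-regimen sensitivities depend on unreadable
figure wiring and an unstated phase-sampling convention and are therefore
demonstrated (examples/06) but not treated as reference values.

## Limitations

- Only oncogene-driven circuits are modeled: inhibition can only deactivate
  targets. Tumor-suppressor logic (inversion) is out of scope.
- Panels are capped at 16 targets; all state spaces are dense and explicit.
- Series-parallel factorization is exact; maps outside that family get the
  monotone fallback network rather than a circuit diagram.
- Off-circuit targets are wired to a documented default activator (the last
  block's first line end); the choice provably does not affect any map-level
  result.
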