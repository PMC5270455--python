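"""Bound and simulate the experiments needed to orient a known structure.

The reference structure has six serial blocks with line lengths
(1,1,1,1), (1), (1), (3,1), (1), (1,1).  Closed forms give the worst-case
and expected number of steady-state expression experiments; a seeded
simulation reproduces the distribution.
"""

import numpy as np

from timdyn import (
    expected_bound,
    simulate_orientation_discovery,
    worst_case_bound,
)
from timdyn.fixtures import load_fixture

structure = load_fixture("fig4_structure")
print("structure:", structure.blocks)
print("targets:", structure.n_targets, " serial blocks:", structure.L)
print("worst-case bound:", worst_case_bound(structure))
print("expected bound:  %.4f" % expected_bound(structure))

counts = simulate_orientation_discovery(structure, runs=10_000, seed=1)
print("simulated 10,000 runs: min=%d mean=%.4f max=%d"
      % (counts.min(), counts.mean(), counts.max()))
hist = np.bincount(counts)
for k, c in enumerate(hist):
    if c:
        print(f"  {k} experiments: {c} runs")
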