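"""From a transition matrix to a model-generated sensitivity map.

The embedded 16-state reference chain encodes a tumor driven by three
targets.  Sustained inhibition right-multiplies by the intervention
projection; small independent bit flips make the chain ergodic; the
stationary tumor-free mass per drug combination is the model map.  The
single-network construction builds such a chain directly from any map.
"""

import numpy as np

from timdyn import algorithm1_chain, chain_to_ptim, write_ptim
from timdyn.fixtures import load_fixture

chain = load_fixture("table3")
ptim = load_fixture("table2")

for p in (0.0, 0.001):
    model = chain_to_ptim(chain, p=p)
    err = np.max(np.abs(model.values - ptim.values))
    print(f"reference chain, p={p}: max |model - input| = {err:.4f}")

print("\nsingle-network chain built from the map itself:")
built = algorithm1_chain(ptim, alpha=0.5, mutations={"K1", "K2"})
model = chain_to_ptim(built, p=0.001)
print(write_ptim(model))
print("max |model - input| = %.4f"
      % np.max(np.abs(model.values - ptim.values)))
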