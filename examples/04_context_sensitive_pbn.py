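"""Model a heterogeneous tumor as a mixture of Boolean-network clones.

A layered sensitivity map decomposes into plateaus; each plateau's
thresholded binary map gets a consistent Boolean network and the plateau
increments become clone proportions.  The collapsed steady state of the
switching/perturbed mixture reproduces the input map.
"""

from timdyn import (
    algorithm2_build,
    bn_to_tim,
    cspbn_to_ptim,
    ptim_error,
    sensitivity_levels,
    write_ptim,
)
from timdyn.fixtures import load_fixture

ptim = load_fixture("table5")
dec = sensitivity_levels(ptim, epsilon=0.05)
print("levels:    ", dec.levels)
print("thresholds:", dec.thresholds)
print("weights:   ", dec.weights)

model = algorithm2_build(ptim, dec, p=0.001, q=0.001)
for k, bn in enumerate(model.networks):
    print(f"\nclone {k} (weight {model.weights[k]:.2f}) inhibition map:")
    tim = bn_to_tim(bn)
    print("  blocked combos:", [sorted(s) for s in tim.blocking_sets()])

model_ptim = cspbn_to_ptim(model)
print("\nmodel-generated map:")
print(write_ptim(model_ptim))
mean_err, max_err = ptim_error(model_ptim, ptim)
print(f"agreement with input: mean |err| {mean_err:.4f}, max |err| {max_err:.4f}")
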