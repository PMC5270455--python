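"""Full workflow on a six-kinase drug-screen sensitivity map.

Threshold the 64-entry screen map at three sensitivity levels, build a
three-clone context-sensitive model, and compare its steady-state map to
the measurement.  The residual error reflects the information lost by the
three-level quantization, not the dynamics.
"""

from timdyn import (
    algorithm2_build,
    binarize,
    cspbn_to_ptim,
    infer_structures,
    minimal_blocking_sets,
    ptim_error,
)
from timdyn.fixtures import load_fixture

ptim = load_fixture("table8")
print("targets:", ", ".join(ptim.panel.names))

for alpha in (0.3, 0.55, 0.8):
    tim = binarize(ptim, alpha)
    msets = minimal_blocking_sets(tim)
    cands = infer_structures(tim)
    print(f"\nthreshold {alpha}: {len(msets)} minimal blocking sets")
    for s in msets:
        print("   ", sorted(s))
    if cands:
        print("   series-parallel structure:",
              [[sorted(l) for l in blk] for blk in cands[0].blocks])

model = algorithm2_build(
    ptim, thresholds=(0.3, 0.55, 0.8), weights=(0.5, 0.25, 0.25),
    p=0.001, q=0.001,
)
model_ptim = cspbn_to_ptim(model)
mean_err, max_err = ptim_error(model_ptim, ptim)
print(f"\nmodel vs screen: mean |err| {mean_err:.4f}, max |err| {max_err:.4f}")
print("single-drug model sensitivities:")
for t in ptim.panel.names:
    print(f"  {t:7s} measured {ptim.entry({t}):.2f}  model {model_ptim.entry({t}):.2f}")
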