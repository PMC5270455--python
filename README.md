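# timdyn

Inference of dynamic tumor-survival networks from steady-state drug-perturbation
screens, and design of drug regimens on the inferred models.

A targeted-drug screen over n inhibitable targets yields a **probabilistic
target-inhibition map (PTIM)**: one sensitivity in [0, 1] for each of the 2^n
inhibition combinations. `timdyn` turns such a map into dynamic models and back:

1. **Structure inference** — threshold the map into a binary target-inhibition
   map (TIM), extract its minimal blocking sets, and factor them into a
   series-parallel circuit of serial blocks containing parallel lines of
   targets. Orientation (block order, within-line order) is not identifiable
   from steady-state kill data alone; all consistent directional models are
   enumerated.
2. **Experiment design** — closed-form worst-case and expected bounds on the
   number of steady-state expression experiments needed to fix the
   orientation, plus a seeded simulator of the discovery process.
3. **Boolean networks** — a deterministic network on the 2^(n+1) states
   (n target bits + tumor bit) for any directional pathway; sustained
   inhibition is a projection applied after each update.
4. **Markov chains** — intervention projections, independent bit-flip
   perturbation, stationary analysis (including reducible chains via
   absorption from a start state), and a single-network chain construction
   that reproduces a given PTIM.
5. **Context-sensitive probabilistic Boolean networks** — a layered map is
   decomposed into sensitivity plateaus; each plateau's TIM gets a clone
   network and the plateau increments become clone proportions. The collapsed
   steady state of the switching/perturbed mixture reproduces the input map.
6. **Regimens** — periodic drug schedules evaluated as time-averaged
   steady-state tumor-free probability; period-1 schedules equal the model
   map entries exactly.

## Worked example

```python
from timdyn import (binarize, infer_structures, algorithm2_build,
                    cspbn_to_ptim, ptim_error, sensitivity_levels)
from timdyn.fixtures import load_fixture

ptim = load_fixture("table5")            # 3-target layered sensitivity map
dec = sensitivity_levels(ptim, 0.05)     # plateaus and clone weights
print(dec.weights)                       # (0.65, 0.25, 0.1)

model = algorithm2_build(ptim, dec, p=0.001, q=0.001)
model_ptim = cspbn_to_ptim(model)
print(round(model_ptim.entry({"K3"}), 2))          # 0.65
print(ptim_error(model_ptim, ptim))                # (0.0105, 0.0270)
```

Output of the structure-inference layer on the same map:

```
$ timdyn infer-structure table5.csv --alpha 0.55
(K3) => (K1 || K2)
  directional models: 2
```

The command-line interface (`timdyn --help`) exposes each layer:
`infer-structure`, `bounds`, `simulate-experiments`, `build-bn`,
`algorithm1`, `algorithm2`, `regimen`, `fixtures`, `validate`.
The `examples/` directory contains narrative scripts for each stage of the
pipeline, runnable in a few seconds each.

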