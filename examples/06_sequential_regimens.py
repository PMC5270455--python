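"""Evaluate sequential drug regimens on a tumor model.

A regimen is a periodic schedule of drug combinations.  Period-1 regimens
reproduce the sustained-inhibition map entries exactly; alternating
schedules trade efficacy against exposure.  Caveat: steady-state values of
alternating schedules depend on the phase-sampling convention; this module
reports the time average over the cycle.
"""

from timdyn import Regimen, algorithm2_build, cspbn_to_ptim, evaluate_regimen
from timdyn.fixtures import load_fixture

model = algorithm2_build(load_fixture("table5"), epsilon=0.05, p=0.001, q=0.001)
ptim = cspbn_to_ptim(model)

print("sustained regimens (equal the model map entries):")
for targets in ({"K3"}, {"K2", "K3"}, {"K1", "K2", "K3"}):
    res = evaluate_regimen(model, Regimen.sustained(targets))
    print(f"  {sorted(targets)}: {res.sensitivity:.4f}"
          f"  (map entry {ptim.entry(targets):.4f})")

print("\nalternating and rest-step regimens (phase-averaged):")
for phases in (
    ({"K3"}, {"K1", "K2"}),
    ({"K1", "K2", "K3"}, set()),
    ({"K3"}, set()),
):
    res = evaluate_regimen(model, Regimen(tuple(phases)))
    label = " / ".join("{" + ",".join(sorted(ph)) + "}" for ph in phases)
    print(f"  {label}: {res.sensitivity:.4f}  per phase "
          + ", ".join(f"{s:.4f}" for s in res.phase_sensitivities))
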