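"""Saddle-node structure of the stable burst count.

Scanning the adaptation conductance with continuation (carrying the
state between parameter values), the stable NSPB is an integer step
function; each unit jump is a fold where a burst-count branch appears
or disappears.  Map and network place these folds at matching
parameter values.
"""

import numpy as np

from caburst import bifurcation_scan, fixed_point, paced_params

p = paced_params()
values = np.arange(35.0, 60.1, 2.5)
br = bifurcation_scan("gAHP", values, p, with_continuous=True)

print("gAHP:     " + "".join(f"{v:5.0f}" for v in values))
print("map:      " + "".join(f"{n:5d}" for n in br.nspb_map))
print("network:  " + "".join(f"{n:5d}" for n in br.nspb_continuous))
print("fold locations  map:", br.transitions("map"),
      " network:", br.transitions("continuous"))

print("\ncoexisting stable branches (bistability) near the folds:")
for v in (40.0, 57.5):
    q = p.replace(gAHP=v)
    stable = [k for k in range(1, 10) if fixed_point(k, q).stable]
    print(f"  gAHP = {v}: stable burst counts {stable}")
print("\nStronger adaptation silences the active cell sooner, so the")
print("branch staircase descends with gAHP; where two branches overlap")
print("the realised count depends on history (hysteresis).")
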