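"""The explicit spikes-per-burst formula.

The number of cycles until the active/silent interchange solves a
quadratic in r**n; its closed form is compared here with direct
cycle-by-cycle iteration of the subthreshold-potential comparison, and
evaluated over a grid of burst-initial calcium pairs.
"""

import numpy as np

from caburst import derive_constants, nspb, nspb_real, paced_params, vsub

p = paced_params()
dc = derive_constants(p)

x0, y0 = 0.0, 3.0
n = nspb_real(x0, y0, p, dc)
print(f"n_Ca({x0}, {y0}) = {n:.3f}  ->  NSPB = {nspb(x0, y0, p, dc)}")
va = vsub((x0 - dc.Abar) * dc.r ** n + dc.Abar, 0.0, p)
vs = vsub(y0 * dc.r ** n, dc.siEnd, p)
print(f"check: at n = {n:.3f} cycles both subthreshold potentials equal "
      f"{va:.4f} / {vs:.4f} mV")

print("\nNSPB over burst-initial calcium (rows: active x0, cols: silent y0):")
grid = np.arange(0.0, 6.1, 1.0)
print("x0\\y0 " + "".join(f"{v:5.0f}" for v in grid))
for x in grid:
    row = "".join(f"{nspb(x, y, p, dc):5d}" for y in grid)
    print(f"{x:5.1f} " + row)
print()
print("A larger calcium gap y0 - x0 needs more spikes to close: the")
print("active cell must accumulate enough calcium for its adaptation")
print("current to cancel its head start in excitability.")
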