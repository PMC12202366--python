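"""Fixed points D_k of the burst map and the stability criterion.

D_k is the state the map returns to when every burst has exactly k
spikes; it is stable precisely when the real-valued burst length at
that state lies in (k-1, k).  For any k an adaptation conductance can
be found that makes D_k the stable solution.
"""

from caburst import derive_constants, find_gAHP_for_k, fixed_point, paced_params

p = paced_params()
dc = derive_constants(p)

print(f"reference configuration: gAHP = {p.gAHP}, r = {dc.r:.4f}, "
      f"Abar = {dc.Abar:.3f}")
print("k   D_k = (Cx, Cy)        n_Ca(D_k)  stable")
for k in range(1, 8):
    res = fixed_point(k, p, dc)
    print(f"{k}   ({res.point.Cx:6.3f}, {res.point.Cy:6.3f})   "
          f"{res.nCa_at_point:8.3f}  {res.stable}")
print()
print("Exactly one k satisfies k-1 < n_Ca(D_k) < k here: the network's")
print("long-run burst count.")
print()
print("Inverting for the conductance that stabilises a prescribed k:")
for k in (1, 3, 6, 10):
    g = find_gAHP_for_k(k, p)
    res = fixed_point(k, p.replace(gAHP=g))
    print(f"  k = {k:2d}: gAHP = {g:9.3f}  (n_Ca(D_k) = {res.nCa_at_point:.3f},"
          f" stable = {res.stable})")
print()
print("Stronger adaptation shortens bursts, so large k needs small gAHP.")
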