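# caburst

Calcium-modulated bursting in small inhibitory networks: a continuous
integrate-and-fire simulator and the analytic discrete map that predicts
its burst structure.

## The problem

In many circuits — the insect antennal lobe is the canonical example —
inhibitory neurons driven by a common excitatory input take turns firing.
The active cell accumulates intracellular calcium with every spike; calcium
gates a slow afterhyperpolarizing potassium current (sAHP) that erodes the
cell's excitability until a silent competitor takes over. The observable of
interest is the **number of spikes per burst (NSPB)**: how many cycles a cell
stays active before the interchange.

Simulating the full network answers this numerically but opaquely. Because
calcium is slow compared with spiking, the dynamics collapse onto a discrete
map on burst-initial calcium levels, and that map can be solved in closed
form: NSPB, fixed points, stability and bifurcations all become explicit.
This package implements both levels and verifies that they agree.

## The model

Each inhibitory cell (IC) obeys leaky integrate-and-fire dynamics

    Cm v' = -gl (v - EL) - I_AHP - gi si (v - EGABA) - ge se (v - EAMPA) + Iapp
    I_AHP = gAHP (v - EK) [Ca]/([Ca] + k1),      [Ca]' = -kCa [Ca]

with reset `vT → vR`, a calcium jump `[Ca] += dCa` per spike, and synaptic
gates `si, se` reset to 1 on each presynaptic spike and decaying at rates
`βi, βe`. One excitatory cell (EC), a plain LIF pacemaker with period
`t3 = (Cm/gl) ln((v∞−vR)/(v∞−vT))`, drives all ICs; ICs inhibit each other
all-to-all.

The reduction works on burst-initial calcium. With the per-cycle retention
factor `r = exp(−kCa t3)` and the end-of-interval asymptote
`Ā = dCa·r/(1−r)`, calcium after n cycles is

    active:  [Ca]_a(n) = rⁿ a₀ + Ā (1 − rⁿ),       silent:  [Ca]_s(n) = rⁿ s₀,

and the quasi-steady subthreshold potential is the rational function

    v_sub([Ca], si) = EK + (gl(EL−EK) + gi si (EGABA−EK) + Iapp)
                           / (gl + gAHP·[Ca]/([Ca]+k1) + gi si).

Setting `v_sub(active) = v_sub(silent)` at cycle n yields a quadratic in
`ρ = rⁿ`; its admissible root gives the real burst length `n_Ca(x₀, y₀)` and
`NSPB = ⌈n_Ca⌉` (strict ceiling, floored at one spike). The two-cell map

    Cx ← rⁿ Cy,    Cy ← rⁿ Cx + Ā(1 − rⁿ),    n = NSPB(Cx, Cy)

has explicit fixed points `D_k = (Ā rᵏ/(1+rᵏ), Ā/(1+rᵏ))`, stable exactly
when `k−1 < n_Ca(D_k) < k`. The m+1-cell generalisation replaces the swap
with a cyclic permutation and yields s-periodic orbits in closed form.

All quantities live in one self-consistent model-unit system (mV, ms,
model µM); see `docs/methods.md` for parameter values, the paced reference
configuration used in map-vs-network comparisons, and numerical choices.

## Worked example

```python
import numpy as np
from caburst import (MapState, NetworkState, derive_constants, extract_bursts,
                     iterate_map, paced_params, simulate)

p = paced_params()                 # comparison configuration
dc = derive_constants(p)
init = NetworkState(v=np.full(3, p.vR), Ca=np.array([0.0, 3.0]), si=np.zeros(2))
spikes, trace, _ = simulate(p, 2, T=2000.0, dt=0.001, init=init)
print(extract_bursts(spikes).head(4))
print(iterate_map(MapState(0.0, 3.0), 4, p, dc)[1])
```

prints

```
   burst  cell  nspb  t_start     ca0_0     ca0_1
0      0     0     4   17.549  0.000000  2.607053
1      1     1     3   87.741  2.851066  1.486886
2      2     0     4  140.361  1.871487  3.256788
3      3     1     4  210.517  3.918997  1.857987
[5, 4, 4, 4]
```

Cell 0 (lower initial calcium, hence more excitable) bursts first; roles
then alternate, and the burst table's `ca0_*` columns are the burst-initial
calcium vectors the map evolves. The map, started from the same (0, 3),
predicts burst counts 5, 4, 4, 4 — within one spike of the network — and
both settle on the stable fixed point `D_4 = (2.41, 4.23)`, which is exactly
the settled `(ca0_active, ca0_silent)` pair in the table. Running
`python examples/04_fixed_points_and_stability.py` shows why 4: among all
burst counts only k = 4 satisfies `3 < n_Ca(D_4) = 3.59 < 4`.

The `examples/` directory holds one short script per capability (single-cell
adaptation, two-cell alternation, the NSPB formula, fixed points, three-cell
rotation, bifurcation scans); each prints its numbers with a line on what
they mean. A thin CLI mirrors them, e.g.

```bash
caburst fixed-point --paced --k 4
caburst sweep-ca --grid 0:6:0.5 --continuous --out sweep.csv
caburst bifurcate --param gAHP --range 35:60:2.5 --continuous --out bif.csv
```

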