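# Methods

## Model

Inhibitory cells (ICs) are single-compartment leaky integrate-and-fire
units carrying a leak current, a calcium-gated potassium (sAHP)
adaptation current `gAHP (v−EK) [Ca]/([Ca]+k1)`, conductance-based
synapses, and an applied current. Calcium jumps by `dCa` at each of the
cell's own spikes and decays exponentially at rate `kCa`; synaptic gates
reset to 1 on presynaptic spikes and decay at `βi` (slow inhibition,
IC→IC) and `βe` (fast excitation, EC→IC). A single excitatory cell (EC)
with constant drive acts as a pacemaker with closed-form period
`t3 = (Cm/gl) ln((v∞−vR)/(v∞−vT))`, `v∞ = EL + Istim/gl` ≈ 17.54 ms at
the default constants. Every cell uses the same threshold/reset rule; an
absolute refractory period `t_ref = 2 ms` (standard for LIF cells, small
against `t3`) holds a cell at reset after each spike.

Default constants (one self-consistent model-unit system — mV, ms, model
µM; deliberately no unit conversion): `Cm=1, gl=0.18, EL=−60, vT=−50,
vR=−75, gAHP=50, k1=10, EK=−90, kCa=0.001/ms, dCa=1, Iapp=0.2, Istim=2,
gi=25, ge=4, βi=0.1/ms, βe=2/ms, EAMPA=0`.

Two constants the model text leaves open were fixed as follows:

* **EGABA = −90 mV (= EK).** The slow IC→IC inhibition is treated as
  potassium-mediated (GABA_B-like), so its reversal coincides with EK.
  This choice is forced by the model's own phenomenology: the operating
  subthreshold range is −86…−90 mV (AHP-dominated), so any reversal above
  it (e.g. −80 mV) would make "inhibition" *depolarizing* there,
  inverting the required monotonicity of burst length in `gi` and
  collapsing every burst to one spike.
* **t3 = EC period.** The active cell fires once per EC cycle, so the
  map's inter-spike interval is the pacemaker period; it can be
  overridden in the configuration or estimated from a simulation
  (`analysis.estimate_t3`, which reproduces the closed form to <1%).

## Discrete map

All map quantities sample calcium at the **end of an inter-spike
interval, just before a spike** — the instant at which the two cells'
excitabilities are compared. One cycle is spike-then-decay,
`Ca ← (Ca + dCa)·r` with `r = e^(−kCa·t3)`, whose fixed point is the
end-of-interval asymptote `Ā = dCa·r/(1−r)` (just after a spike the
asymptote is `Ā + dCa = dCa/(1−r)`; mixing the two sampling phases — an
easy slip — biases every map prediction by a factor r, ≈13% at the
comparison configuration, and the package uses the end-of-interval
convention throughout because it is the one that matches the simulated
network's burst-initial calcium exactly).

The quasi-steady subthreshold potential `v_sub(Ca, si)` balances leak,
sAHP and received inhibition against the applied current; the active
cell receives no inhibition (its competitor's gate has decayed for many
cycles and there is no self-inhibition), the silent cell receives the
active cell's gate at its interval-end value `siEnd = e^(−βi·t3)`.
Equating the two potentials after n cycles and clearing denominators
gives `m₁ρ² + m₂ρ + m₃ = 0` in `ρ = rⁿ`, with coefficients built from
`a, b, c, d` (the rational coefficients of `a + b·x_n = c + d·y_n`) and
`m = (−a−b+c+d)/k1`. Numerical handling:

* `|m₁| < 10⁻¹²` (silent cell empty, or active cell at Ā): solve the
  linear equation instead.
* Root admissibility: a root must be positive **and** give a physical
  (non-negative) active-cell calcium `(x₀−Ā)ρ + Ā ≥ 0`; clearing
  denominators introduces spurious roots violating this (they appear,
  e.g., as gAHP → 0). `ρ ≥ 1` is admissible and encodes `n_Ca ≤ 0`: the
  interchange condition already holds at burst onset.
* The principal ('+') root is preferred; the alternate root is used,
  with a warning, only when the principal one is inadmissible. No
  admissible root means the cells never interchange (`NoSwitchError`;
  sweep sentinel 0).
* `NSPB = min{z ∈ ℤ : z > n_Ca}` floored at 1 — a burst contains at
  least the spike that starts it.

Fixed points `D_k = (Ā rᵏ/(1+rᵏ), Ā/(1+rᵏ))` come from a 2×2 linear
solve (never singular, spectral radius rᵏ < 1); stability is the strict
window `k−1 < n_Ca(D_k) < k`. `find_gAHP_for_k` bisects
`n_Ca(D_k) − (k−½)` on gAHP (monotone decreasing; `D_k` itself does not
depend on gAHP) to tolerance 10⁻⁶. The gAHP → ∞ limit of `n_Ca(D_k)` is
`ln((1+rᵏ)/2)/ln r`, always below k−½ but above 1 for k ≥ 3, so "strong
adaptation ⇒ single-spike bursts" holds only for small k while the
existence of a stabilising gAHP holds for every k.

The (m+1)-cell map orders cells as (active, silents by ascending
calcium) and advances by `rⁿ E_m · Ca + d` with the cyclic permutation
`E_m`; it assumes the former active cell ends every burst with the
highest calcium. Violations of that rank-order assumption (possible
during transients or at fast `kCa`) raise a warning and are never
re-sorted silently (`resort=True` opts in). Compositions of s bursts are
affine with spectral radius `r^(Σnᵢ)`; s-periodic points solve an
(m+1)-dimensional linear system and are declared stable when every stage
of the orbit satisfies its burst-count window, with the violated stage
reported otherwise.

## Continuous simulator

Between events the gating variables are advanced with their exact
exponential decay factors. The membrane potential uses an
exponential-Euler step (coefficients frozen over dt): under the sAHP
shunt the membrane time constant drops to ~0.02 ms, where explicit Euler
at a usable dt is unstable, while exponential Euler is unconditionally
stable and exact for frozen coefficients. Thresholds are checked at step
end; the spike time is the step end (no interpolation). When several ICs
cross within one step, the one with the lowest calcium (the most
excitable, matching the map's ordering) fires and the others are held at
threshold for that step — the winner's inhibition then drives them back
down. Calcium snapshots stored with each spike are taken *before* the
spike's calcium jump, so a burst's first-spike snapshot is the
burst-initial calcium vector the map evolves.

dt guard: `dt ≤ t3/50`. Default dt is 0.01 ms; comparison experiments
use 0.002–0.001 ms because the within-cycle race that decides which cell
fires at an EC kick spans only a few hundredths of a millisecond, and
under-resolving it truncates bursts near interchange (the package's
refinement test covers dt = 0.001 vs 0.0005).

## The paced comparison configuration

The map describes a regime in which **every EC cycle triggers exactly
one IC spike** — the most excitable cell's — while the winner's
inhibition silences the rest. Whether the conductance-based network
actually realises this depends on three inequalities (evaluated at
threshold, with `x = Ca/(Ca+k1)`):

1. the winner must be kickable:
   `ge(EAMPA−vT) > gl(vT−EL) + gAHP·x·(vT−EK)` over the operating
   calcium range;
2. the losers must not be:
   `ge(EAMPA−vT) < gl(vT−EL) + gi·si·(vT−EGABA) + gAHP·x·(vT−EK)`
   once the winner's gate has reset (`si ≈ 1`);
3. the interchange must be reachable: the sAHP excitability budget
   `gAHP·Δx` must exceed the inhibition gap `gi·siEnd` before calcium
   saturates at Ā.

At the canonical constants (`ge = 4, gAHP = 50, kCa = 0.001`) inequality
1 fails for any calcium above ≈1.1 model µM, far below the map's
operating range: the network stalls into sporadic single spikes and no
choice of dt or reversal rescues it. The package therefore defines a
**paced configuration** for all map-vs-network experiments —
`kCa = 0.008/ms` (a fast decay value the model family also explores) and
`ge = 18`, the midpoint of the window `40·x_op < ge < 20 + 40·x_min`
that inequalities 1–2 leave open for the resulting operating range
(Ca ≈ 0…6.6) — with every other constant at its default. These values
were fixed from the inequalities above, before any comparison was run,
and are not tuned thereafter. The refractory period is what keeps
inequality 1's strong drive from producing several spikes within one
excitatory kick (the kick outlives the ~0.3 ms the winner needs to
recover from reset).

## Experiments

* **First-burst sweep** (initial-calcium grid, default [0, 6]²): both
  cells start at `vR` with closed gates; the lower-calcium cell is the
  first active one. Network first-burst NSPB is the first maximal run of
  one cell's spikes; the run must be followed by a takeover, else the
  no-switch sentinel. Agreement tolerance between map and network is ±1
  spike — the map is a quasi-steady approximation and its burst
  boundaries sit within one cycle of the network's.
* **Stable NSPB**: map — terminal count after 200 iterations from
  `(0, Ā/2)`; network — last 8 complete bursts of a 6 s run must agree
  (the final, possibly truncated run is dropped), else flagged.
* **Bifurcation scans** default to continuation (state carried across
  parameter values, both systems), because the stability windows of
  `D_k` and `D_{k+1}` overlap near folds — coexisting attractors are
  real (e.g. k = 3 and 4 both stable over gAHP ≈ 56…66 at the paced
  configuration), fresh starts land basin-dependently, and
  forward/backward scans expose genuine hysteresis. Under continuation
  both systems follow a branch to its fold; map and network fold
  locations agree to about one coarse grid cell (gAHP: 2.5; gi: 1.3),
  i.e. ~5% of the parameter value — the residual offset is the map's
  neglect of the conductance asymmetry in the within-kick race.
* **Adaptation**: a lone IC under a strong step current (amplitude 500,
  chosen so the calcium equilibrium sits several increments above rest,
  making the interval growth gradual rather than a single jump); ISIs
  must be non-decreasing (to one dt) and the final ten equal within 1%.

## What the synthetic conditions do and do not show

All comparisons are internal — this package's network against this
package's map under identical constants — which is the only meaningful
test given that the model's phenomenological parameters are not tied to
a dataset. Passing shows the reduction is faithful to the dynamics it
was derived from: identical cells, deterministic drive, all-to-all
coupling, no noise, no synaptic delays, no heterogeneity. It does not
show that real bursting interneurons obey the map: spike-generating
currents, calcium buffering, stochastic input and heterogeneous
conductances all blur the clean cycle structure, and the map's ±1-spike
accuracy should be read as an upper bound on what real data would give.

## Known limitations

* The paced regime's suppression window closes for `gi` ≲ 12 or
  `gAHP` ≳ 70 at the default drive; sweeps default to ranges
  (gAHP ∈ [35, 60], gi ∈ [15, 28]) that bracket the canonical values and
  respect the window. Outside it the network departs from the
  one-spike-per-cycle structure and the map no longer applies.
* Fold locations in the network are resolved to the scan grid and, very
  close to a fold, can shift by about one grid cell with dt.
* The multi-cell map's rank-order assumption genuinely fails for fast
  calcium decay; the package warns rather than hiding it.
* `n_Ca` values within 10⁻⁸ of an integer sit on the ceiling boundary,
  where formula and cycle-iteration may legitimately differ by one;
  tests exclude this measure-zero set.
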