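"""Comparison experiments between the discrete map and the full network.

Three experiment families mirror the model's canonical figures:

* :func:`sweep_initial_ca` -- first-burst NSPB as a function of the two
  cells' initial calcium, from the explicit formula and (optionally)
  from a simulation initialised at those calcium levels;
* :func:`sweep_gahp_gi` -- long-run ("stable") NSPB over a grid of the
  adaptation conductance gAHP and inhibitory conductance gi;
* :func:`bifurcation_scan` -- stable NSPB branches along one parameter,
  which are integer step functions whose jumps are the saddle-node
  (fold) points where a burst-count solution appears or disappears.

All continuous-side experiments use the paced reference configuration
(see :func:`caburst.params.paced_params`) unless told otherwise, and a
step of 0.002 ms, fine enough to resolve the within-cycle race that
decides which cell fires.

The integer ``NO_SWITCH`` (0) marks cells of a sweep where the roles
never interchange (or, on the continuous side, where no interchange was
observed / the burst sequence did not settle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import camap
from .camap import MapState, NoSwitchError, iterate_map, nspb, vsub
from .network import NetworkState, extract_bursts, simulate
from .params import DerivedConstants, ModelParams, derive_constants

__all__ = [
    "NO_SWITCH",
    "SweepResult",
    "BifurcationBranch",
    "first_burst_map",
    "first_burst_continuous",
    "stable_nspb_map",
    "stable_nspb_continuous",
    "estimate_t3",
    "sweep_initial_ca",
    "sweep_gahp_gi",
    "bifurcation_scan",
    "agreement_fraction",
]

NO_SWITCH = 0

#: default integration step (ms) for comparison experiments; fine enough
#: that the within-cycle race deciding which cell fires is resolved (the
#: membrane time constant under the peak excitatory conductance is a few
#: hundredths of a ms)
DT_COMPARE = 0.001


@dataclass
class SweepResult:
    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    nspb_map: np.ndarray
    nspb_continuous: np.ndarray | None = None
    tolerance: int = 1

    @property
    def agreement(self) -> float | None:
        if self.nspb_continuous is None:
            return None
        return agreement_fraction(self.nspb_map, self.nspb_continuous, self.tolerance)

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, x in enumerate(self.axis1_values):
            for j, y in enumerate(self.axis2_values):
                row = {self.axis1_name: x, self.axis2_name: y,
                       "nspb_map": self.nspb_map[i, j]}
                if self.nspb_continuous is not None:
                    row["nspb_continuous"] = self.nspb_continuous[i, j]
                rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class BifurcationBranch:
    param: str
    values: np.ndarray
    nspb_map: np.ndarray
    nspb_continuous: np.ndarray | None = None

    def transitions(self, which: str = "map") -> np.ndarray:
        """Parameter values at which the integer branch jumps (midpoint
        of the bracketing grid cells)."""
        branch = self.nspb_map if which == "map" else self.nspb_continuous
        if branch is None:
            raise ValueError("no continuous branch stored")
        jumps = np.flatnonzero(np.diff(branch) != 0)
        return 0.5 * (self.values[jumps] + self.values[jumps + 1])

    def to_frame(self):
        import pandas as pd

        data = {self.param: self.values, "nspb_map": self.nspb_map}
        if self.nspb_continuous is not None:
            data["nspb_continuous"] = self.nspb_continuous
        return pd.DataFrame(data)


def agreement_fraction(a: np.ndarray, b: np.ndarray, tolerance: int = 1) -> float:
    """Fraction of cells where both sides agree within ``tolerance``.

    Sentinel (no-switch / unsettled) cells agree only with sentinel cells.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    sent = (a == NO_SWITCH) | (b == NO_SWITCH)
    ok = np.where(sent, (a == NO_SWITCH) & (b == NO_SWITCH),
                  np.abs(a - b) <= tolerance)
    return float(np.mean(ok))


# ---------------------------------------------------------------------------
# first-burst NSPB

def first_burst_map(c1: float, c2: float, p: ModelParams,
                    dc: DerivedConstants | None = None) -> int:
    """First-burst NSPB from the explicit formula for initial calcium
    ``(c1, c2)`` of the two cells.

    The initially active cell is the more excitable one -- the higher
    subthreshold potential with no inhibition yet, i.e. the lower-calcium
    cell.  Returns ``NO_SWITCH`` if the roles never interchange.
    """
    if dc is None:
        dc = derive_constants(p)
    v1 = vsub(c1, 0.0, p, dc)
    v2 = vsub(c2, 0.0, p, dc)
    x0, y0 = (c1, c2) if v1 >= v2 else (c2, c1)
    try:
        return nspb(x0, y0, p, dc)
    except NoSwitchError:
        return NO_SWITCH


def first_burst_continuous(c1: float, c2: float, p: ModelParams,
                           dt: float = DT_COMPARE, max_cycles: int = 80) -> int:
    """First-burst NSPB from a network simulation.

    Both ICs start at the reset potential with closed gates and calcium
    ``(c1, c2)``; the EC paces the competition.  The first burst is the
    first maximal run of one cell's spikes; it must be followed by the
    other cell's takeover within ``max_cycles`` EC cycles, otherwise
    ``NO_SWITCH`` is returned.
    """
    t3 = p.isi_duration()
    init = NetworkState(v=np.full(3, p.vR), Ca=np.array([c1, c2], float),
                        si=np.zeros(2), se=0.0, t=0.0)
    spikes, _, _ = simulate(p, 2, T=max_cycles * t3, dt=dt, init=init,
                            record_every=0)
    if spikes.ic_spikes().size == 0:
        return NO_SWITCH
    bursts = extract_bursts(spikes)
    if len(bursts) < 2:  # interchange never observed
        return NO_SWITCH
    return int(bursts["nspb"].iloc[0])


# ---------------------------------------------------------------------------
# long-run (stable) NSPB

def stable_nspb_map(p: ModelParams, dc: DerivedConstants | None = None,
                    start: MapState | None = None, steps: int = 200) -> int:
    """Terminal burst count after ``steps`` map iterations."""
    if dc is None:
        dc = derive_constants(p)
    if start is None:
        start = MapState(0.0, 0.5 * dc.Abar)
    _, ns = iterate_map(start, steps, p, dc)
    if len(ns) < steps:  # map became undefined before settling
        return NO_SWITCH
    return ns[-1]


def stable_nspb_continuous(p: ModelParams, T: float = 6000.0,
                           dt: float = DT_COMPARE, require_last: int = 8,
                           start_ca: tuple[float, float] | None = None) -> int:
    """Long-run NSPB of the two-cell network.

    Simulates ``T`` ms from calcium ``start_ca`` (default: one cell empty,
    the other at half the asymptotic level, matching the map experiment),
    drops the final possibly-truncated run, and requires the last
    ``require_last`` complete bursts to have equal length; returns
    ``NO_SWITCH`` if firing never settles on a constant burst count.
    """
    dc = derive_constants(p)
    if start_ca is None:
        start_ca = (0.0, 0.5 * dc.Abar)
    init = NetworkState(v=np.full(3, p.vR), Ca=np.array(start_ca, float),
                        si=np.zeros(2), se=0.0, t=0.0)
    spikes, _, _ = simulate(p, 2, T=T, dt=dt, init=init, record_every=0)
    if spikes.ic_spikes().size == 0:
        return NO_SWITCH
    bursts = extract_bursts(spikes)
    if len(bursts) < require_last + 2:
        return NO_SWITCH
    tail = bursts["nspb"].iloc[-(require_last + 1):-1]  # drop truncated last
    if tail.nunique() != 1:
        return NO_SWITCH
    return int(tail.iloc[0])


def estimate_t3(p: ModelParams, T: float = 2000.0, dt: float = DT_COMPARE) -> float:
    """Empirical inter-spike interval: median ISI within bursts of the
    active cell in a two-cell simulation."""
    dc = derive_constants(p)
    init = NetworkState(v=np.full(3, p.vR), Ca=np.array([0.0, 0.5 * dc.Abar]),
                        si=np.zeros(2), se=0.0, t=0.0)
    spikes, _, _ = simulate(p, 2, T=T, dt=dt, init=init, record_every=0)
    idx = spikes.ic_spikes()
    ids, times = spikes.ids[idx], spikes.times[idx]
    isis = [times[i + 1] - times[i] for i in range(len(ids) - 1)
            if ids[i + 1] == ids[i]]
    if not isis:
        raise RuntimeError("no within-burst inter-spike intervals observed")
    return float(np.median(isis))


# ---------------------------------------------------------------------------
# sweeps

def sweep_initial_ca(grid, p: ModelParams, dc: DerivedConstants | None = None,
                     with_continuous: bool = False, dt: float = DT_COMPARE,
                     tolerance: int = 1) -> SweepResult:
    """First-burst NSPB over a grid of initial calcium pairs.

    ``grid`` is a 1-D array of calcium values used for both axes (cell 1
    along rows, cell 2 along columns); values must lie in [0, Abar).
    """
    if dc is None:
        dc = derive_constants(p)
    grid = np.asarray(grid, float)
    if np.any(grid < 0) or np.any(grid >= dc.Abar):
        raise ValueError(f"grid must lie within [0, Abar={dc.Abar:.4g})")
    n = grid.size
    mat_map = np.empty((n, n), int)
    for i, c1 in enumerate(grid):
        for j, c2 in enumerate(grid):
            mat_map[i, j] = first_burst_map(c1, c2, p, dc)
    mat_cont = None
    if with_continuous:
        mat_cont = np.empty((n, n), int)
        for i, c1 in enumerate(grid):
            for j, c2 in enumerate(grid):
                mat_cont[i, j] = first_burst_continuous(c1, c2, p, dt=dt)
    return SweepResult("ca1_init", grid, "ca2_init", grid.copy(),
                       mat_map, mat_cont, tolerance)


def sweep_gahp_gi(gahp_values, gi_values, p: ModelParams,
                  with_continuous: bool = False, dt: float = DT_COMPARE,
                  T: float = 6000.0, tolerance: int = 1) -> SweepResult:
    """Stable NSPB over a (gAHP, gi) grid for map and network."""
    gahp_values = np.asarray(gahp_values, float)
    gi_values = np.asarray(gi_values, float)
    if np.any(gahp_values <= 0) or np.any(gi_values <= 0):
        raise ValueError("conductance grids must be positive")
    shape = (gahp_values.size, gi_values.size)
    mat_map = np.empty(shape, int)
    mat_cont = np.empty(shape, int) if with_continuous else None
    for i, ga in enumerate(gahp_values):
        for j, g in enumerate(gi_values):
            q = p.replace(gAHP=ga, gi=g)
            mat_map[i, j] = stable_nspb_map(q)
            if with_continuous:
                mat_cont[i, j] = stable_nspb_continuous(q, T=T, dt=dt)
    return SweepResult("gAHP", gahp_values, "gi", gi_values,
                       mat_map, mat_cont, tolerance)


def bifurcation_scan(param: str, values, p: ModelParams,
                     with_continuous: bool = False, dt: float = DT_COMPARE,
                     T: float = 4000.0, continuation: bool = True,
                     reverse: bool = False) -> BifurcationBranch:
    """Stable-NSPB branch along one parameter (``gAHP`` or ``gi``).

    With ``continuation=True`` (default) both systems carry their state
    from one parameter value to the next -- the standard protocol for
    following a branch of attractors.  Where burst-count solutions
    overlap (near a fold both ``k`` and ``k+1`` can be stable), a
    fresh-start scan would hop between coexisting attractors basin-
    dependently; continuation instead stays on a branch until it
    disappears, so the recorded jumps are the saddle-node points.
    ``reverse=True`` scans from high to low parameter values (the
    returned arrays are always in ascending order), which exposes the
    hysteresis loop spanned by coexisting branches.
    """
    if param not in ("gAHP", "gi"):
        raise ValueError("param must be 'gAHP' or 'gi'")
    values = np.asarray(values, float)
    if np.any(np.diff(values) <= 0):
        raise ValueError("scan values must be strictly increasing")
    order = values[::-1] if reverse else values
    branch_map = np.empty(values.size, int)
    branch_cont = np.empty(values.size, int) if with_continuous else None

    dc0 = derive_constants(p)
    map_state = MapState(0.0, 0.5 * dc0.Abar)
    net_state = NetworkState(v=np.full(3, p.vR),
                             Ca=np.array([0.0, 0.5 * dc0.Abar]),
                             si=np.zeros(2), se=0.0, t=0.0)
    for pos, val in enumerate(order):
        i = values.size - 1 - pos if reverse else pos
        q = p.replace(**{param: val})
        dcq = derive_constants(q)
        if not continuation:
            map_state = MapState(0.0, 0.5 * dcq.Abar)
        states, ns = iterate_map(map_state, 120, q, dcq)
        if len(ns) == 120:
            branch_map[i] = ns[-1]
            map_state = states[-1]
        else:
            branch_map[i] = NO_SWITCH
            map_state = MapState(0.0, 0.5 * dcq.Abar)
        if with_continuous:
            if not continuation:
                branch_cont[i] = stable_nspb_continuous(q, T=T, dt=dt)
                continue
            spikes, _, final = simulate(q, 2, T=T, dt=dt, init=net_state,
                                        record_every=0)
            final.t = 0.0
            net_state = final
            if spikes.ic_spikes().size == 0:
                branch_cont[i] = NO_SWITCH
                continue
            bursts = extract_bursts(spikes)
            tail = bursts["nspb"].iloc[-7:-1]
            branch_cont[i] = int(tail.iloc[0]) if (len(tail) == 6 and tail.nunique() == 1) else NO_SWITCH
    return BifurcationBranch(param, values, branch_map, branch_cont)
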