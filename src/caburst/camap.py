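"""Analytic discrete-map reduction of the two-cell bursting network.

The map tracks the burst-initial calcium levels ``(Cx, Cy)`` of the
active and silent inhibitory cell.  Its ingredients are

* ``vsub`` -- the quasi-steady subthreshold membrane potential as a
  rational function of calcium and synaptic inhibition,
* ``ca_active`` / ``ca_silent`` -- closed forms for calcium after ``n``
  inter-spike intervals,
* ``nspb_real`` / ``nspb`` -- the explicit number-of-spikes-per-burst
  formula, obtained by solving a quadratic in ``rho = r**n`` that encodes
  the equality of the two cells' subthreshold potentials,
* ``map_step`` -- one burst of the two-cell map,
* ``fixed_point`` -- the explicit fixed point ``D_k`` with burst count
  ``k`` and its stability test ``k-1 < n_Ca(D_k) < k``,
* ``find_gAHP_for_k`` -- inversion of the AHP conductance so that a
  prescribed burst count ``k`` is the stable one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .params import DerivedConstants, ModelParams, derive_constants

__all__ = [
    "NoSwitchError",
    "MapState",
    "FixedPointResult",
    "vsub",
    "ca_active",
    "ca_silent",
    "nspb_real",
    "nspb",
    "map_step",
    "iterate_map",
    "fixed_point",
    "find_gAHP_for_k",
]

#: quadratic coefficient below this magnitude is treated as degenerate
#: (linear equation); occurs when s0 = 0 or a0 = Abar.
_M1_TOL = 1e-12


class NoSwitchError(RuntimeError):
    """The silent cell never overtakes the active cell: no interchange.

    Raised when the quadratic for ``r**n`` has no root in (0, 1); the two
    cells either interchange within the first cycle (handled by flooring
    the burst count at 1) or never interchange at all.
    """


@dataclass(frozen=True)
class MapState:
    """Burst-initial calcium of the active (Cx) and silent (Cy) cell."""

    Cx: float
    Cy: float

    def __post_init__(self) -> None:
        if self.Cx < 0 or self.Cy < 0:
            raise ValueError("calcium levels must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.Cx, self.Cy], float)


@dataclass(frozen=True)
class FixedPointResult:
    """Fixed point D_k of the two-cell map with burst count k."""

    k: int
    point: MapState
    stable: bool
    nCa_at_point: float


def vsub(Ca: float, si_level: float, p: ModelParams, dc: DerivedConstants | None = None):
    """Quasi-steady subthreshold potential of a cell (mV).

    Balances leak, sAHP and synaptic inhibition against the applied
    current, with calcium activation ``xCa = Ca/(Ca+k1)``:

        v = EK + (gl(EL-EK) + gi*si*(EGABA-EK) + Iapp) / (gl + gAHP*xCa + gi*si)

    ``si_level`` is the inhibitory gate the cell *receives* (0 for the
    active cell, the ISI-end value for the silent cell).  Accepts array
    input for ``Ca``.
    """
    Ca = np.asarray(Ca, float)
    x = Ca / (Ca + p.k1)
    num = p.gl * (p.EL - p.EK) + p.gi * si_level * (p.EGABA - p.EK) + p.Iapp
    den = p.gl + p.gAHP * x + p.gi * si_level
    out = p.EK + num / den
    return float(out) if out.ndim == 0 else out


def ca_active(a0: float, n: int | float, dc: DerivedConstants) -> float:
    """Calcium of the active cell after ``n`` inter-spike intervals.

    Each cycle the level jumps by ``dCa`` at the spike and then decays by
    the retention factor ``r``; iterating the spike-then-decay cycle from
    the burst-initial (pre-spike) level ``a0`` gives the closed form
    ``r**n * a0 + Abar * (1 - r**n)`` with the end-of-interval asymptote
    ``Abar = dCa*r/(1-r)``.
    """
    rn = dc.r ** n
    return rn * a0 + dc.Abar * (1.0 - rn)


def ca_silent(s0: float, n: int | float, dc: DerivedConstants) -> float:
    """Calcium of the silent cell after ``n`` intervals: pure decay."""
    return s0 * dc.r ** n


def _quadratic_coeffs(x0: float, y0: float, dc: DerivedConstants):
    """Coefficients m1, m2, m3 of the quadratic in rho = r**n.

    Substituting the calcium closed forms (with the active cell's
    burst-initial level ``a0 = x0`` and the silent cell's ``s0 = y0``)
    into the potential-equality condition ``a + b*x_n = c + d*y_n`` and
    clearing denominators yields ``m1*rho**2 + m2*rho + m3 = 0``.
    """
    a0, s0 = x0, y0
    A, k1 = dc.Abar, dc.k1
    b, d, m = dc.b, dc.d, dc.m
    m1 = m * s0 * (a0 - A)
    m2 = m * (s0 * (A + k1) + k1 * (a0 - A)) - (d * (a0 - A) - b * s0)
    m3 = (A + k1) * (m * k1 - d) + b * k1
    return m1, m2, m3


def nspb_real(x0: float, y0: float, p: ModelParams, dc: DerivedConstants | None = None) -> float:
    """Real-valued burst length ``n_Ca(x0, y0)``.

    Solves the quadratic in ``rho = r**n`` for the cycle count at which
    the active cell's subthreshold potential equals the silent cell's,
    and returns ``ln(rho)/ln(r)``.  The principal ('+') root is used;
    when it is inadmissible but the '-' root is admissible, the latter
    is taken with a warning.  A root is admissible when it is positive
    and corresponds to a physical (non-negative) calcium level of the
    active cell; ``rho >= 1`` is allowed and encodes ``n_Ca <= 0``, i.e.
    the interchange condition already holds at burst onset (the burst
    still contains one spike; see :func:`nspb`).  Raises
    :class:`NoSwitchError` when no admissible root exists -- the cells
    never interchange.
    """
    if x0 < 0 or y0 < 0:
        raise ValueError("calcium levels must be non-negative")
    if dc is None:
        dc = derive_constants(p)
    m1, m2, m3 = _quadratic_coeffs(x0, y0, dc)

    def admissible(rho: float) -> bool:
        # rho must be positive, and the active cell's calcium at the
        # solution, (x0 - Abar)*rho + Abar, must be physical (>= 0);
        # roots violating this are algebraic artifacts of clearing the
        # denominators.
        if rho <= 0.0:
            return False
        return (x0 - dc.Abar) * rho + dc.Abar >= -1e-12

    if abs(m1) < _M1_TOL:
        if m2 == 0.0:
            raise NoSwitchError("degenerate equation: no interchange condition")
        rho = -m3 / m2
    else:
        disc = m2 * m2 - 4.0 * m1 * m3
        if disc < 0:
            raise NoSwitchError(
                f"negative discriminant at (x0={x0:g}, y0={y0:g}): cells never interchange"
            )
        sq = math.sqrt(disc)
        rho = (-m2 + sq) / (2.0 * m1)
        if not admissible(rho):
            alt = (-m2 - sq) / (2.0 * m1)
            if admissible(alt):
                warnings.warn(
                    "principal root of the burst-length quadratic is not "
                    "admissible; using the alternate root",
                    RuntimeWarning,
                    stacklevel=2,
                )
                rho = alt
    if not admissible(rho):
        raise NoSwitchError(
            f"no admissible root of the burst-length quadratic at (x0={x0:g}, y0={y0:g})"
        )
    return math.log(rho) / math.log(dc.r)


def _strict_ceil(x: float) -> int:
    """min{z in Z : z > x} -- the strict ceiling (3.0 -> 4)."""
    return math.floor(x) + 1


def nspb(x0: float, y0: float, p: ModelParams, dc: DerivedConstants | None = None) -> int:
    """Number of spikes per burst: strict ceiling of ``n_Ca``, at least 1.

    The active cell fires at least once by definition of a burst, so
    non-positive ``n_Ca`` (interchange condition already met at onset)
    maps to 1.  Propagates :class:`NoSwitchError`.
    """
    return max(_strict_ceil(nspb_real(x0, y0, p, dc)), 1)


def map_step(state: MapState, p: ModelParams, dc: DerivedConstants | None = None):
    """One burst of the two-cell map.

    The active cell fires ``n = nspb(Cx, Cy)`` spikes; the roles then
    swap: the new active cell is the former silent one with calcium
    ``r**n * Cy``, the new silent cell carries ``r**n * Cx + Abar*(1-r**n)``.

    Returns ``(new_state, n)``.
    """
    if dc is None:
        dc = derive_constants(p)
    n = nspb(state.Cx, state.Cy, p, dc)
    rn = dc.r ** n
    return MapState(Cx=rn * state.Cy, Cy=rn * state.Cx + dc.Abar * (1.0 - rn)), n


def iterate_map(state: MapState, steps: int, p: ModelParams,
                dc: DerivedConstants | None = None):
    """Iterate :func:`map_step`, returning the orbit as lists.

    Returns ``(states, ns)`` where ``states`` has ``len(ns)+1`` entries.
    Iteration halts early (without error) if the map becomes undefined
    (no interchange); the caller can detect this from the orbit length.
    """
    if dc is None:
        dc = derive_constants(p)
    states = [state]
    ns: list[int] = []
    for _ in range(steps):
        try:
            state, n = map_step(state, p, dc)
        except NoSwitchError:
            break
        states.append(state)
        ns.append(n)
    return states, ns


def fixed_point(k: int, p: ModelParams, dc: DerivedConstants | None = None) -> FixedPointResult:
    """Fixed point D_k of the map restricted to burst count k.

    Solves the 2x2 linear system ``(I - r**k * D) x = d_k`` with the swap
    matrix ``D = [[0,1],[1,0]]`` and offset ``d_k = (0, Abar*(1-r**k))``;
    in closed form ``D_k = (Abar*r**k/(1+r**k), Abar/(1+r**k))``.  The
    point is a stable fixed point of the full map iff
    ``k-1 < n_Ca(D_k) < k``.
    """
    if k < 1:
        raise ValueError("burst count k must be a positive integer")
    if dc is None:
        dc = derive_constants(p)
    rk = dc.r ** k
    M = np.array([[1.0, -rk], [-rk, 1.0]])
    rhs = np.array([0.0, dc.Abar * (1.0 - rk)])
    x = np.linalg.solve(M, rhs)
    point = MapState(Cx=float(x[0]), Cy=float(x[1]))
    try:
        ncap = nspb_real(point.Cx, point.Cy, p, dc)
    except NoSwitchError:
        ncap = math.inf
    stable = (k - 1) < ncap < k
    return FixedPointResult(k=k, point=point, stable=stable, nCa_at_point=ncap)


class BracketError(ValueError):
    """The gAHP bracket does not enclose the target burst count."""


def find_gAHP_for_k(k: int, p: ModelParams, bracket=(1e-3, 1e4),
                    tol: float = 1e-6, max_iter: int = 200) -> float:
    """AHP conductance for which D_k is the stable fixed point.

    ``n_Ca(D_k)`` decreases monotonically in gAHP (a stronger adaptation
    current needs less calcium to silence the active cell), and D_k
    itself depends only on ``r`` and ``Abar``, so bisection on
    ``n_Ca(D_k) - (k - 1/2)`` over the bracket converges to a gAHP at
    which ``k-1 < n_Ca(D_k) < k`` holds with margin.  Constants are
    re-derived at every evaluation.
    """

    def f(g: float) -> float:
        q = p.replace(gAHP=g)
        dcq = derive_constants(q)
        fp_ca = dcq.Abar * np.array([dcq.r ** k, 1.0]) / (1.0 + dcq.r ** k)
        try:
            n = nspb_real(float(fp_ca[0]), float(fp_ca[1]), q, dcq)
        except NoSwitchError:
            n = math.inf
        return n - (k - 0.5)

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if not (flo > 0 > fhi or flo < 0 < fhi):
        raise BracketError(
            f"no sign change of n_Ca(D_{k}) - (k - 1/2) over gAHP bracket "
            f"{bracket}: endpoint values n_Ca = {flo + k - 0.5:.4g}, {fhi + k - 0.5:.4g}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if (fm > 0) == (flo > 0):
            lo, flo = mid, fm
        else:
            hi, fhi = mid, fm
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)
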