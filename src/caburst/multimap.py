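"""Discrete map for networks of m+1 inhibitory cells and one EC.

The state vector orders cells by role: position 0 is the active cell,
positions 1..m the silent cells by ascending calcium (next-to-fire
first).  One burst decays every silent cell by ``r**n``, promotes each
one rank, and sends the former active cell to the back with calcium
``r**n * Ca[0] + Abar * (1 - r**n)`` -- an affine map built from the
cyclic permutation matrix ``E_m``.  Compositions of ``s`` such bursts
are again affine, which gives closed-form s-periodic orbits and a
stage-wise stability test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .camap import NoSwitchError, nspb, nspb_real
from .params import DerivedConstants, ModelParams, derive_constants

__all__ = [
    "OrderingWarning",
    "PeriodicOrbit",
    "cycle_matrix",
    "multi_map_step",
    "compose_maps",
    "s_periodic_point",
]


class OrderingWarning(UserWarning):
    """The rank-order assumption (former active ends with the highest
    calcium) was violated after a step."""


@dataclass(frozen=True)
class PeriodicOrbit:
    """s-periodic point of the (m+1)-cell map with burst counts n_vec."""

    n_vec: tuple[int, ...]
    point: np.ndarray
    stable: bool
    violated_index: int | None = None


def cycle_matrix(m: int) -> np.ndarray:
    """Permutation matrix E_m: (E x)_i = x_{i+1}, (E x)_m = x_0."""
    E = np.zeros((m + 1, m + 1))
    for i in range(m):
        E[i, i + 1] = 1.0
    E[m, 0] = 1.0
    return E


def _check_state(state: np.ndarray) -> np.ndarray:
    state = np.asarray(state, float)
    if state.ndim != 1 or state.size < 2:
        raise ValueError("state must be a vector of length m+1 >= 2")
    if np.any(state < 0):
        raise ValueError("calcium levels must be non-negative")
    return state


def multi_map_step(state: np.ndarray, p: ModelParams,
                   dc: DerivedConstants | None = None, resort: bool = False):
    """One burst of the (m+1)-cell map.

    The active cell (position 0) competes with the lowest-calcium silent
    cell (position 1); the burst count ``n = nspb(Ca[0], Ca[1])`` then
    drives the affine update ``r**n * E_m @ Ca + d`` with the load
    ``d = (0, ..., 0, Abar*(1 - r**n))``.

    If after the step the former active cell's calcium does not exceed
    every silent cell's, the rank-order assumption behind the map is
    broken: an :class:`OrderingWarning` is emitted and, with
    ``resort=True``, the silent ranks are re-sorted ascending.

    Returns ``(new_state, n)``.
    """
    state = _check_state(state)
    if dc is None:
        dc = derive_constants(p)
    m = state.size - 1
    n = nspb(float(state[0]), float(state[1]), p, dc)
    rn = dc.r ** n
    new = np.empty_like(state)
    new[:m] = rn * state[1:]
    new[m] = rn * state[0] + dc.Abar * (1.0 - rn)
    if m >= 1 and new[m] < np.max(new[:m]):
        warnings.warn(
            "former active cell's calcium does not exceed all silent cells': "
            "rank-order assumption violated",
            OrderingWarning,
            stacklevel=2,
        )
        if resort:
            new[1:] = np.sort(new[1:])
    return new, n


def compose_maps(n_vec, m: int, p: ModelParams, dc: DerivedConstants | None = None):
    """Affine form of s composed bursts with prescribed counts n_vec.

    Returns ``(M, offset)`` with ``M = r**(n1+..+ns) * E_m**s`` and the
    offset accumulated by pushing each burst's load through the remaining
    rotations: ``sum_i r**(n_{i+1}+..+n_s) * E_m**(s-i) @ d_{n_i}``.
    """
    n_vec = tuple(int(n) for n in n_vec)
    if len(n_vec) < 1:
        raise ValueError("n_vec must contain at least one burst count")
    if any(n < 1 for n in n_vec):
        raise ValueError("burst counts must be positive integers")
    if dc is None:
        dc = derive_constants(p)
    E = cycle_matrix(m)
    s = len(n_vec)
    M = np.linalg.matrix_power(E, s) * dc.r ** sum(n_vec)
    offset = np.zeros(m + 1)
    for i, n in enumerate(n_vec):  # i-th burst, applied first..last
        d = np.zeros(m + 1)
        d[m] = dc.Abar * (1.0 - dc.r ** n)
        tail = sum(n_vec[i + 1:])
        offset += dc.r ** tail * (np.linalg.matrix_power(E, s - 1 - i) @ d)
    return M, offset


def s_periodic_point(n_vec, m: int, p: ModelParams,
                     dc: DerivedConstants | None = None) -> PeriodicOrbit:
    """Fixed point of the s-fold composed map and its stability.

    Solves ``(I - M) x = offset`` (never singular: the spectral radius of
    ``M`` is ``r**sum(n) < 1``).  The point is a stable s-periodic orbit
    of the full map iff at every stage ``i`` of the orbit the actual
    burst-length function satisfies ``n_i - 1 < n_Ca(stage state) < n_i``;
    the first violated stage index is reported otherwise.
    """
    n_vec = tuple(int(n) for n in n_vec)
    s = len(n_vec)
    if not 1 <= s < m + 1:
        raise ValueError(f"period s={s} must satisfy 1 <= s < m+1 (m={m})")
    if dc is None:
        dc = derive_constants(p)
    M, offset = compose_maps(n_vec, m, p, dc)
    point = np.linalg.solve(np.eye(m + 1) - M, offset)
    # stage-wise stability test along the orbit
    E = cycle_matrix(m)
    state = point.copy()
    stable = True
    violated: int | None = None
    for i, n in enumerate(n_vec):
        try:
            ncap = nspb_real(float(state[0]), float(state[1]), p, dc)
        except NoSwitchError:
            ncap = math.inf
        if not (n - 1 < ncap < n):
            stable = False
            violated = i
            break
        rn = dc.r ** n
        d = np.zeros(m + 1)
        d[m] = dc.Abar * (1.0 - rn)
        state = rn * (E @ state) + d
    return PeriodicOrbit(n_vec=n_vec, point=point, stable=stable,
                         violated_index=violated)
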