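"""Shared independent oracles for the map tests.

These deliberately re-derive quantities by direct iteration/comparison
rather than through the closed forms they are used to check.
"""

import numpy as np

from caburst import derive_constants, vsub


def ca_loop(a0, n, dc):
    """n-fold iteration of one spike-then-decay cycle of the active cell."""
    ca = a0
    for _ in range(n):
        ca = (ca + dc.dCa) * dc.r
    return ca


def nspb_brute(x0, y0, p, dc=None, n_max=2000):
    """Smallest cycle count at which the active cell's end-of-interval
    subthreshold potential drops to (or below) the silent cell's.

    Returns 0 if no interchange occurs within ``n_max`` cycles.  The
    active cell receives no inhibition; the silent cell is inhibited at
    the interval-end gate level.
    """
    if dc is None:
        dc = derive_constants(p)
    ca_a, ca_s = x0, y0
    for n in range(1, n_max + 1):
        ca_a = (ca_a + dc.dCa) * dc.r
        ca_s = ca_s * dc.r
        if vsub(ca_a, 0.0, p, dc) <= vsub(ca_s, dc.siEnd, p, dc):
            return n
    return 0


def near_integer(x, tol=1e-8):
    return abs(x - round(x)) < tol


def random_states(rng, n, abar):
    return np.column_stack([rng.uniform(0.0, abar, n), rng.uniform(0.0, abar, n)])
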