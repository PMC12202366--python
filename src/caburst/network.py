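"""Continuous simulation of the nIC-1EC integrate-and-fire network.

Inhibitory cells (ICs) carry leak, a calcium-gated potassium (sAHP)
current, mutual inhibition and excitation from a single pacemaker
excitatory cell (EC).  Between spikes the membrane potential is advanced
with an exponential-Euler step (the instantaneous conductance is frozen
over dt, which is unconditionally stable under the large sAHP shunt);
the gating variables Ca, si, se obey linear decay and are updated with
their exact exponential factors.  At threshold a cell is reset, its
calcium jumps by ``dCa`` and its synaptic gate is reset to 1.

When several ICs reach threshold within the same step, the one with the
lowest calcium (the most excitable) fires and the others are held at
threshold for that step; the winner's inhibition then pulls them back
down.  Cells are refractory for ``t_ref`` ms after a spike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .params import ModelParams, ec_period

__all__ = ["NetworkState", "SpikeTrain", "SimulationError", "simulate", "extract_bursts"]


class SimulationError(RuntimeError):
    pass


@dataclass
class NetworkState:
    """Instantaneous state of the network.

    ``v`` holds the IC potentials followed by the EC potential (if an EC
    is present); ``Ca`` and ``si`` are per-IC; ``se`` is the EC's
    excitatory gate.
    """

    v: np.ndarray
    Ca: np.ndarray
    si: np.ndarray
    se: float = 0.0
    t: float = 0.0


@dataclass
class SpikeTrain:
    """Time-stamped spike events.

    ``ids`` index ICs as 0..n_ic-1; the EC, when present, is ``n_ic``.
    ``ca`` holds, for every spike, the calcium of all ICs immediately
    *before* that spike's calcium jump -- for an IC's first spike of a
    burst this is the burst-initial calcium the discrete map works with.
    """

    times: np.ndarray
    ids: np.ndarray
    ca: np.ndarray
    n_ic: int

    @property
    def events(self) -> list[tuple[float, int]]:
        return list(zip(self.times.tolist(), self.ids.tolist()))

    def ic_spikes(self) -> np.ndarray:
        return np.flatnonzero(self.ids < self.n_ic)


@njit(cache=False)
def _kernel(v, ca, si, se0, last, n_ic, has_ec, n_steps, dt, t0,
            Cm, gl, EL, vT, vR, gAHP, k1, EK, kCa, dCa, Iapp, Istim,
            gi, ge, EGABA, EAMPA, betai, betae, t_ref,
            sp_t, sp_id, sp_ca, trace, stride):
    fca = np.exp(-kCa * dt)
    fsi = np.exp(-betai * dt)
    fse = np.exp(-betae * dt)
    se = se0
    count = 0
    rec = 0
    max_spikes = sp_t.shape[0]
    n_rec = trace.shape[0]
    vinf_ec = EL + Istim / gl
    status = 0
    for step in range(n_steps):
        t = t0 + step * dt
        if stride > 0 and step % stride == 0 and rec < n_rec:
            trace[rec, 0] = t
            col = 1
            for i in range(v.shape[0]):
                trace[rec, col] = v[i]
                col += 1
            for i in range(n_ic):
                trace[rec, col] = ca[i]
                col += 1
            for i in range(n_ic):
                trace[rec, col] = si[i]
                col += 1
            trace[rec, col] = se
            rec += 1
        ssum = 0.0
        for i in range(n_ic):
            ssum += si[i]
        for i in range(n_ic):
            if t - last[i] < t_ref:
                v[i] = vR
                continue
            x = ca[i] / (ca[i] + k1)
            so = ssum - si[i]
            G = gl + gAHP * x + gi * so + ge * se
            inum = gl * EL + gAHP * x * EK + gi * so * EGABA + ge * se * EAMPA + Iapp
            vinf = inum / G
            v[i] = vinf + (v[i] - vinf) * np.exp(-G * dt / Cm)
        if has_ec:
            j = n_ic
            v[j] = vinf_ec + (v[j] - vinf_ec) * np.exp(-gl * dt / Cm)
        for i in range(n_ic):
            ca[i] *= fca
            si[i] *= fsi
        se *= fse
        tnow = t + dt
        # IC threshold crossings: lowest-calcium crosser fires, the rest
        # are held at threshold this step.
        w = -1
        for i in range(n_ic):
            if v[i] >= vT and tnow - last[i] >= t_ref:
                if w < 0 or ca[i] < ca[w] or (ca[i] == ca[w] and i < w):
                    w = i
        if w >= 0:
            for i in range(n_ic):
                if i != w and v[i] >= vT:
                    v[i] = vT
            if count >= max_spikes:
                status = -1
                break
            sp_t[count] = tnow
            sp_id[count] = w
            for i in range(n_ic):
                sp_ca[count, i] = ca[i]
            count += 1
            v[w] = vR
            ca[w] += dCa
            si[w] = 1.0
            last[w] = tnow
        if has_ec and v[n_ic] >= vT:
            if count >= max_spikes:
                status = -1
                break
            sp_t[count] = tnow
            sp_id[count] = n_ic
            for i in range(n_ic):
                sp_ca[count, i] = ca[i]
            count += 1
            v[n_ic] = vR
            se = 1.0
        if (step & 16383) == 0:
            for i in range(v.shape[0]):
                if not np.isfinite(v[i]):
                    status = -2
            if status != 0:
                break
    return count, rec, se, status


def simulate(p: ModelParams, n_ic: int, T: float, dt: float = 0.01,
             init: NetworkState | None = None, with_ec: bool = True,
             record_every: float | None = None):
    """Integrate the network for ``T`` ms.

    Parameters
    ----------
    p : model parameters.
    n_ic : number of inhibitory cells (0 simulates the EC alone).
    T, dt : total simulated time and step (ms).  ``dt`` must resolve the
        inter-spike interval (``dt <= t3/50``).
    init : optional initial state; by default all potentials start at the
        reset ``vR`` with zero calcium and closed synaptic gates.
    with_ec : include the pacemaker EC (index ``n_ic``).
    record_every : trace sampling interval in ms (``None`` records ~2000
        points; 0 disables the trace).

    Returns
    -------
    (SpikeTrain, trace DataFrame, final NetworkState)
    """
    if n_ic < 0 or (n_ic == 0 and not with_ec):
        raise ValueError("need at least one cell")
    if T <= 0 or dt <= 0:
        raise ValueError("T and dt must be positive")
    t3 = p.isi_duration() if (with_ec or p.t3 is not None) else ec_period(p)
    if dt > t3 / 50.0:
        raise SimulationError(
            f"dt = {dt} ms is too coarse: must be <= t3/50 = {t3 / 50.0:.4g} ms"
        )

    n_cells = n_ic + (1 if with_ec else 0)
    if init is None:
        v = np.full(n_cells, p.vR)
        Ca = np.zeros(n_ic)
        si = np.zeros(n_ic)
        se = 0.0
        t0 = 0.0
    else:
        v = np.asarray(init.v, float).copy()
        Ca = np.asarray(init.Ca, float).copy()
        si = np.asarray(init.si, float).copy()
        se = float(init.se)
        t0 = float(init.t)
        if v.shape[0] != n_cells or Ca.shape[0] != n_ic or si.shape[0] != n_ic:
            raise ValueError("initial state shape does not match n_ic/with_ec")
        if np.any(Ca < 0) or np.any(si < 0) or np.any(si > 1) or not 0 <= se <= 1:
            raise ValueError("initial gates/calcium out of range")

    n_steps = int(round(T / dt))
    min_isi = max(p.t_ref, 10.0 * dt, 0.5)
    max_spikes = int(n_cells * T / min_isi) + 64

    if record_every is None:
        stride = max(n_steps // 2000, 1)
    elif record_every == 0:
        stride = 0
    else:
        stride = max(int(round(record_every / dt)), 1)
    n_rec = (n_steps + stride - 1) // stride if stride > 0 else 0
    trace = np.empty((n_rec, 1 + n_cells + 2 * n_ic + 1))

    sp_t = np.empty(max_spikes)
    sp_id = np.empty(max_spikes, np.int64)
    sp_ca = np.empty((max_spikes, n_ic))
    last = np.full(n_ic, -1e18)

    count, rec, se_out, status = _kernel(
        v, Ca, si, se, last, n_ic, with_ec, n_steps, dt, t0,
        p.Cm, p.gl, p.EL, p.vT, p.vR, p.gAHP, p.k1, p.EK, p.kCa, p.dCa,
        p.Iapp, p.Istim, p.gi, p.ge, p.EGABA, p.EAMPA, p.betai, p.betae,
        p.t_ref, sp_t, sp_id, sp_ca, trace, stride,
    )
    if status == -1:
        raise SimulationError(
            f"spike buffer overflow ({max_spikes} spikes): pathologically fast firing"
        )
    if status == -2:
        raise SimulationError("non-finite membrane potential encountered")

    spikes = SpikeTrain(times=sp_t[:count].copy(), ids=sp_id[:count].copy(),
                        ca=sp_ca[:count].copy(), n_ic=n_ic)
    cols = ["time_ms"]
    cols += [f"v_ic{i}" for i in range(n_ic)]
    if with_ec:
        cols += ["v_ec"]
    cols += [f"ca_ic{i}" for i in range(n_ic)]
    cols += [f"si_ic{i}" for i in range(n_ic)]
    cols += ["se"]
    trace_df = pd.DataFrame(trace[:rec], columns=cols)
    final = NetworkState(v=v, Ca=Ca, si=si, se=se_out, t=t0 + n_steps * dt)
    return spikes, trace_df, final


def extract_bursts(spikes: SpikeTrain, n_ic: int | None = None) -> pd.DataFrame:
    """Partition IC spikes into bursts (maximal runs of one active cell).

    Returns a DataFrame with one row per burst: ``burst`` (index),
    ``cell`` (active IC), ``nspb`` (run length), ``t_start`` (first spike
    time) and ``ca0_<i>`` -- every IC's calcium just before the burst's
    first spike, i.e. the burst-initial calcium vector the discrete map
    evolves.
    """
    if n_ic is None:
        n_ic = spikes.n_ic
    idx = spikes.ic_spikes()
    if idx.size == 0:
        raise ValueError("spike train contains no IC spikes")
    ids = spikes.ids[idx]
    times = spikes.times[idx]
    ca = spikes.ca[idx]
    # run-length encode
    breaks = np.flatnonzero(np.diff(ids) != 0)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [ids.size]))
    rows = {
        "burst": np.arange(starts.size),
        "cell": ids[starts],
        "nspb": ends - starts,
        "t_start": times[starts],
    }
    for i in range(n_ic):
        rows[f"ca0_{i}"] = ca[starts, i]
    return pd.DataFrame(rows)
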