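"""Model constants, derived map constants, and configuration I/O.

The model is a small network of integrate-and-fire inhibitory cells (ICs)
with a calcium-gated potassium (sAHP) adaptation current, paced by one
excitatory cell (EC).  All quantities live in a single self-consistent
model-unit system (voltages in mV, time in ms, calcium in model uM,
conductances and currents in matching model units); no unit conversion is
performed anywhere in the package.

Two parameter sets are exposed:

``ModelParams()``
    the canonical defaults of the biophysical model.

``paced_params()``
    the reference configuration used for map-vs-network comparison
    experiments, in which the excitatory drive is calibrated so that the
    EC paces exactly one IC spike per cycle (see docs/methods.md for the
    pacing inequalities that fix this calibration).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path


class InvalidParameterError(ValueError):
    """A model parameter violates a positivity or ordering constraint."""


class NoFiringError(RuntimeError):
    """The excitatory cell is subthreshold and never fires."""


@dataclass(frozen=True)
class ModelParams:
    """All biophysical constants of the network model.

    Attributes
    ----------
    Cm : membrane capacitance.
    gl, EL : leak conductance and reversal potential (mV).
    vT, vR : spike threshold and reset potential (mV).
    gAHP, k1, EK : sAHP maximal conductance, half-activation calcium
        level, and potassium reversal potential.  The sAHP current is
        ``gAHP * (v - EK) * Ca / (Ca + k1)``.
    kCa, dCa : calcium decay rate (1/ms) and calcium increment per spike.
    Iapp, Istim : applied currents to ICs and to the EC.
    gi, EGABA, betai : IC->IC inhibitory conductance, reversal (mV) and
        gate decay rate (1/ms).  The slow inhibition is potassium-mediated,
        hence the default reversal coincides with EK.
    ge, EAMPA, betae : EC->IC excitatory conductance, reversal (mV) and
        gate decay rate (1/ms).
    t3 : inter-spike interval (ms) used by the discrete map; ``None``
        means "derive from the EC pacemaker period" (see ``isi_duration``).
    t_ref : absolute refractory period (ms) of the integrate-and-fire
        cells in the continuous simulator.
    """

    Cm: float = 1.0
    gl: float = 0.18
    EL: float = -60.0
    vT: float = -50.0
    vR: float = -75.0
    gAHP: float = 50.0
    k1: float = 10.0
    EK: float = -90.0
    kCa: float = 0.001
    dCa: float = 1.0
    Iapp: float = 0.2
    Istim: float = 2.0
    gi: float = 25.0
    ge: float = 4.0
    EGABA: float = -90.0
    EAMPA: float = 0.0
    betai: float = 0.1
    betae: float = 2.0
    t3: float | None = None
    t_ref: float = 2.0

    def __post_init__(self) -> None:
        for name in ("Cm", "gl", "k1", "kCa", "dCa", "betai", "betae"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        for name in ("gAHP", "gi", "ge", "t_ref"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if not self.vR < self.vT:
            raise InvalidParameterError("vR must be below the threshold vT")
        if not (self.EK < self.EL < self.vT):
            raise InvalidParameterError("reversal ordering EK < EL < vT violated")
        if self.t3 is not None and not self.t3 > 0:
            raise InvalidParameterError("t3 must be strictly positive when given")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def isi_duration(self) -> float:
        """Inter-spike interval t3 of the active cell: explicit value if
        configured, otherwise the EC pacemaker period."""
        if self.t3 is not None:
            return self.t3
        return ec_period(self)


@dataclass(frozen=True)
class DerivedConstants:
    """Map-level constants derived from :class:`ModelParams`.

    ``r`` is the per-cycle calcium retention factor ``exp(-kCa*t3)``.
    ``Abar`` is the asymptotic *end-of-interval* calcium level an
    eternally active cell approaches, ``dCa*r/(1-r)``: every map
    quantity samples calcium just before a spike, at the end of an
    inter-spike interval, which is where the two cells' excitabilities
    are compared (just after a spike the asymptote is ``Abar + dCa =
    dCa/(1-r)``).  ``siEnd`` is the inhibitory gate value at the end of
    an inter-spike interval, ``exp(-betai*t3)``.

    ``a, b, c, d`` are the four rational coefficients that recast the
    subthreshold-potential equality between active and silent cells as
    ``a + b*x_n = c + d*y_n`` (x, y = calcium activation of the two
    cells); ``m = (-a - b + c + d) / k1`` is the combination entering
    the quadratic whose root gives the burst length.
    """

    r: float
    Abar: float
    siEnd: float
    a: float
    b: float
    c: float
    d: float
    m: float
    t3: float
    k1: float
    dCa: float


def ec_period(p: ModelParams) -> float:
    """Closed-form firing period of the excitatory pacemaker cell.

    The EC obeys ``Cm v' = -gl (v - EL) + Istim`` with threshold/reset,
    a plain leaky integrate-and-fire cell, so its period is
    ``(Cm/gl) * ln((vinf - vR)/(vinf - vT))`` with ``vinf = EL + Istim/gl``.
    """
    vinf = p.EL + p.Istim / p.gl
    if vinf <= p.vT:
        raise NoFiringError(
            f"EC is subthreshold: EL + Istim/gl = {vinf:.3f} mV <= vT = {p.vT} mV"
        )
    return (p.Cm / p.gl) * math.log((vinf - p.vR) / (vinf - p.vT))


def derive_constants(p: ModelParams) -> DerivedConstants:
    """Compute all discrete-map constants from the biophysical parameters.

    The inhibitory gate of the cell that fired last is evaluated at the
    end of the inter-spike interval (``siEnd``); the active cell receives
    no self-inhibition, so its coefficients ``a, b`` carry no ``gi`` term.
    """
    t3 = p.isi_duration()
    r = math.exp(-p.kCa * t3)
    Abar = p.dCa * r / (1.0 - r)
    siEnd = math.exp(-p.betai * t3)

    den_active = p.gl * (p.EL - p.EK) + p.Iapp
    den_silent = p.gl * (p.EL - p.EK) + p.gi * siEnd * (p.EGABA - p.EK) + p.Iapp
    a = p.gl / den_active
    b = p.gAHP / den_active
    c = (p.gl + p.gi * siEnd) / den_silent
    d = p.gAHP / den_silent
    m = (-a - b + c + d) / p.k1
    return DerivedConstants(
        r=r, Abar=Abar, siEnd=siEnd, a=a, b=b, c=c, d=d, m=m,
        t3=t3, k1=p.k1, dCa=p.dCa,
    )


def paced_params(**overrides) -> ModelParams:
    """Reference configuration for map-vs-network comparisons.

    Relative to the canonical defaults, the calcium decay rate is set to
    0.008/ms (the fast value the model explores) and the excitatory
    conductance to 18, the midpoint of the pacing window within which a
    single EC spike reliably triggers exactly one spike of the most
    excitable IC while the winner's inhibition silences the rest (the
    window is derived analytically in docs/methods.md).  In this regime
    the network realises the cycle-by-cycle competition the discrete map
    describes.
    """
    base = dict(kCa=0.008, ge=18.0)
    base.update(overrides)
    return ModelParams(**base)


# ---------------------------------------------------------------------------
# configuration I/O

_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}


def load_config(path: str | Path) -> ModelParams:
    """Read a JSON config with one key per :class:`ModelParams` field.

    Unknown keys are an error, so a typo cannot silently fall back to a
    default value.
    """
    with open(path) as fh:
        raw = json.load(fh)
    unknown = set(raw) - _FIELDS
    if unknown:
        raise InvalidParameterError(
            f"unknown config keys: {sorted(unknown)}; valid keys: {sorted(_FIELDS)}"
        )
    return ModelParams(**raw)


def save_config(p: ModelParams, path: str | Path) -> None:
    """Write the full parameter set as JSON (every field explicit)."""
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(p), fh, indent=2)
        fh.write("\n")


def write_default_config(path: str | Path, paced: bool = False) -> None:
    """Write the canonical (or paced comparison) configuration to JSON."""
    save_config(paced_params() if paced else ModelParams(), path)
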