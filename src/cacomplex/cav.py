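"""CaV single-channel gating and whole-cell CaV current.

A CaV is modeled as a 3-state chain C (closed) <-> O (open) -> B
(inactivated/blocked) -> C.  Voltage-dependent activation is parameterized
through a Boltzmann steady state mInf(V) and a time constant tauM, from
which the microscopic rates follow as

    alpha = mInf / tauM,   beta = 1/tauM - alpha.

Inactivation is Ca2+-dependent: the O -> B rate delta is first order in the
local Ca2+ at the channel's own inactivation sensor (distance rInact from
the pore), and B -> C reactivation proceeds at the constant rate gamma.
Activation is much faster than inactivation, which separates the two
processes in time and yields the reduced two-ODE description (activation
variable mCaV plus inactivated fraction b; the non-inactivated fraction is
h = 1 - b).

Default kinetics: the activation pair (Vhalf = -18 mV, slope = 8 mV) is
a steep high-voltage-activated CaV curve, keeping the resting open
probability below 1% at -60 mV as single-channel recordings show,
with tauM = 1 ms; gamma and the inactivation coefficient are set so
that inactivation is two orders of magnitude slower than activation
(tau_inact ~ 100 ms at 0 mV), preserving the time-scale separation the
reductions rely on.
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, model_validator

from . import constants as k
from .markov import GeneratorModel
from .nanodomain import NanodomainParams, point_source_concentration

CAV3_LABELS = ("C", "O", "B")


class CaVParams(BaseModel):
    """CaV gating parameters (mV, ms, nm; deltaCoeff in 1/(uM*ms))."""

    model_config = {"frozen": True}

    VhalfM: float = -18.0
    slopeM: float = 8.0
    tauM: float = 1.0
    gamma: float = 0.002
    deltaCoeff: float = 2.5e-4
    rInact: float = 7.0
    NCaV: int = 1000

    @model_validator(mode="after")
    def _check(self) -> "CaVParams":
        if self.slopeM <= 0 or self.tauM <= 0 or self.rInact <= 0:
            raise ValueError("slopeM, tauM and rInact must be positive")
        if self.gamma < 0 or self.deltaCoeff < 0:
            raise ValueError("gamma and deltaCoeff must be non-negative")
        return self


class CaVState(BaseModel):
    """Reduced CaV state: activation mCaV and inactivated fraction b."""

    mCaV: float
    b: float

    @model_validator(mode="after")
    def _check(self) -> "CaVState":
        if not (0.0 <= self.mCaV <= 1.0 and 0.0 <= self.b <= 1.0):
            raise ValueError("mCaV and b must lie in [0, 1]")
        return self

    @property
    def h(self) -> float:
        return 1.0 - self.b


def cav_activation_steady(V: float, params: CaVParams) -> tuple[float, float]:
    """Boltzmann steady-state activation mInf(V) and time constant tau (ms)."""
    mInf = 1.0 / (1.0 + math.exp(-(V - params.VhalfM) / params.slopeM))
    return mInf, params.tauM


def cav_rates(V: float, params: CaVParams) -> tuple[float, float]:
    """Opening/closing rates (alpha, beta) in 1/ms from (mInf, tau)."""
    mInf, tau = cav_activation_steady(V, params)
    alpha = mInf / tau
    beta = 1.0 / tau - alpha
    return alpha, beta


def inactivation_rate(V: float, params: CaVParams, nano: NanodomainParams) -> float:
    """O->B rate delta = deltaCoeff * Ca at the channel's own sensor (rInact)."""
    ca = point_source_concentration(V, params.rInact, nano)
    return params.deltaCoeff * ca


def cav_inactivation_rhs(
    b: float, V: float, params: CaVParams, nano: NanodomainParams
) -> float:
    """db/dt = mInf*delta - (mInf*delta + gamma) * b.

    The inactivation rate is weighted by the activation steady state: only
    the activatable (and thus opening) fraction sees the open-channel
    nanodomain.  Fixed point: b_inf = mInf*delta / (mInf*delta + gamma).
    """
    if not 0.0 <= b <= 1.0:
        raise ValueError("b must lie in [0, 1]")
    mInf, _ = cav_activation_steady(V, params)
    delta = inactivation_rate(V, params, nano)
    return mInf * delta - (mInf * delta + params.gamma) * b


def cav_3state_generator(
    V: float, params: CaVParams, nano: NanodomainParams
) -> GeneratorModel:
    """Generator of the 3-state C/O/B chain at fixed V.

    C->O = alpha, O->C = beta, O->B = delta (at the open-channel nanodomain
    Ca2+), B->C = gamma.
    """
    alpha, beta = cav_rates(V, params)
    delta = inactivation_rate(V, params, nano)
    Q = np.array(
        [
            [-alpha, alpha, 0.0],
            [beta, -(beta + delta), delta],
            [params.gamma, 0.0, -params.gamma],
        ]
    )
    return GeneratorModel(state_labels=CAV3_LABELS, Q=Q)


def whole_cell_cav_current(
    V: float, mCaV: float, hCaV: float, NCaV: int, params: CaVParams, nano: NanodomainParams
) -> float:
    """Whole-cell CaV current NCaV * gCa_single * mCaV * hCaV * (V - VCa), pA."""
    if not (0.0 <= mCaV <= 1.0 and 0.0 <= hCaV <= 1.0):
        raise ValueError("mCaV and hCaV must lie in [0, 1]")
    return NCaV * nano.gCaSingle * mCaV * hCaV * (V - nano.VCa) * k.PS_MV_TO_PA
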