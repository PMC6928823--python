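"""Steady-state Ca2+ nanodomains around open CaV channels.

An open CaV acts as a point source of Ca2+ at the inner mouth of the pore.
With an unsaturable mobile buffer the steady-state concentration profile is
the excess-buffer approximation (EBA),

    Ca(r) = |i_Ca| / (8 pi r D_Ca F) * exp(-r / lambda),
    lambda = sqrt(D_Ca / (kB+ * [B]_total)),

where i_Ca = gCa_single * (V - VCa) is the single-channel current (Ohm's
law) and the factor 2 for the divalent charge is folded into the 8*pi
denominator (source strength i/(2F) spread over 4*pi*D*r).  Concentrations
from several open channels superpose linearly on top of the background
level Cac (linear buffer approximation).

The default buffer parameters are calibrated so that a single open CaV with
gCa_single = 2.8 pS, VCa = 60 mV and D_Ca = 0.22 um^2/ms produces ~19 uM at
the BK sensor distance r = 13 nm when V = 0 mV, which pins the space
constant at lambda ~= 53.5 nm.
"""

from __future__ import annotations

import math

from pydantic import BaseModel, model_validator

from . import constants as k


class NanodomainParams(BaseModel):
    """Physical and buffer parameters of the Ca2+ nanodomain.

    Units: DCa um^2/ms, F C/mol, kBplus 1/(uM*ms), Btotal uM,
    gCaSingle pS, VCa mV, Cac and Cab uM.
    """

    model_config = {"frozen": True}

    DCa: float = 0.22
    F: float = k.FARADAY
    kBplus: float
    Btotal: float = 100.0
    gCaSingle: float = 2.8
    VCa: float = 60.0
    Cac: float = 0.2
    Cab: float = 0.2

    @model_validator(mode="after")
    def _check(self) -> "NanodomainParams":
        for name in ("DCa", "F", "kBplus", "Btotal", "gCaSingle"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.Cac < 0:
            raise ValueError("Cac must be non-negative")
        if self.Cab != self.Cac:
            raise ValueError("Cab must equal Cac (inactivated domain sees background Ca)")
        return self


def space_constant(params: NanodomainParams) -> float:
    """EBA space constant lambda = sqrt(DCa / (kB+ * Btotal)) in nm."""
    product = params.kBplus * params.Btotal  # 1/ms
    if product <= 0:
        raise ValueError("kBplus * Btotal must be positive")
    lam_um = math.sqrt(params.DCa / product)
    return lam_um / k.NM_TO_UM


def single_channel_current(V: float, params: NanodomainParams) -> float:
    """Single-CaV current gCa*(V - VCa) in pA (negative = inward)."""
    return params.gCaSingle * (V - params.VCa) * k.PS_MV_TO_PA


def point_source_concentration(V: float, r: float, params: NanodomainParams) -> float:
    """Ca2+ contribution (uM) of one open CaV at distance r (nm), membrane at V (mV).

    Strictly decreasing in r; zero at V = VCa.  An outward driving force
    (V > VCa) is not modeled and raises ``ValueError``.
    """
    if r <= 0:
        raise ValueError("sensor distance r must be positive")
    if V > params.VCa:
        raise ValueError("V > VCa: outward single-channel current is not modeled")
    i_amp = abs(single_channel_current(V, params)) * k.PA_TO_A
    r_m = r * k.NM_TO_M
    d_m2s = params.DCa * k.UM2_PER_MS_TO_M2_PER_S
    prefactor = i_amp / (8.0 * math.pi * r_m * d_m2s * params.F)  # mol/m^3
    lam_nm = space_constant(params)
    return prefactor * k.MOL_PER_M3_TO_UM * math.exp(-r / lam_nm)


def sensor_concentration(n_open: int, V: float, r: float, params: NanodomainParams) -> float:
    """Ca2+ (uM) at a sensor r nm from a cluster with ``n_open`` open CaVs.

    Linear superposition of identical single-channel nanodomains on top of
    the background level Cac.
    """
    if n_open < 0 or int(n_open) != n_open:
        raise ValueError("n_open must be a non-negative integer")
    if n_open == 0:
        return params.Cac
    return params.Cac + n_open * point_source_concentration(V, r, params)


def calibrated_buffer_product(
    target_ca: float = 19.0,
    r: float = 13.0,
    V: float = 0.0,
    DCa: float = 0.22,
    gCaSingle: float = 2.8,
    VCa: float = 60.0,
) -> float:
    """kB+ * Btotal (1/ms) such that one open CaV gives ``target_ca`` uM at (V, r).

    Solves target = P(r) * exp(-r/lambda) for lambda, where P(r) is the
    unbuffered point-source value, then returns DCa / lambda^2.
    """
    i_amp = abs(gCaSingle * (V - VCa) * k.PS_MV_TO_PA) * k.PA_TO_A
    r_m = r * k.NM_TO_M
    prefactor = (
        i_amp / (8.0 * math.pi * r_m * DCa * k.UM2_PER_MS_TO_M2_PER_S * k.FARADAY)
    ) * k.MOL_PER_M3_TO_UM
    if target_ca >= prefactor:
        raise ValueError("target concentration exceeds the unbuffered value")
    lam_nm = -r / math.log(target_ca / prefactor)
    lam_um = lam_nm * k.NM_TO_UM
    return DCa / lam_um**2


def default_nanodomain_params() -> NanodomainParams:
    """Default parameter set, buffer product calibrated to the 19-uM anchor."""
    product = calibrated_buffer_product()
    btotal = 100.0
    return NanodomainParams(kBplus=product / btotal, Btotal=btotal)
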