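"""Pituitary-lactotroph electrical model with stoichiometry-dependent BK current.

Membrane potential follows

    C dV/dt = -(ICa + IK + ISK + IBK + Ileak),

with the standard lactotroph current set: an instantaneously activating
Ca2+ current ICa = gCa mInf(V)(V - VCa), a delayed-rectifier IK with
first-order gating nK, an SK current gated by cytosolic Ca2+ c through
c^2/(c^2 + ks^2), a passive leak, and the BK current driven by the
BK_Ca-CaV complex model: IBK = gBK mBK(n) (V - VK), where gBK =
NBK*gBK_single and mBK(n) is the open probability of a BK channel in a
complex with n non-inactivating CaVs.  Cytosolic Ca2+ follows
dc/dt = -fc (kappa ICa + kclear c).

Three interchangeable descriptions of mBK(n) are available: ``fullODE``
(master equation of the 2(n+1)-state complex chain), ``qss`` (single-ODE
quasi-steady-state reduction with CaV activation kinetics) and ``instant``
(QSS reduction in the instantaneous-CaV limit).  With one CaV per BK
channel the model spikes continuously; with 2-4 CaVs the leftward shift
and strengthening of BK activation convert spiking into pseudo-plateau
bursting.

The qss/instant reduction coefficients are precomputed on a (V, mCaV)
grid and interpolated bilinearly inside the right-hand side; the tables
are exact linear solves at the nodes (resolution 0.5 mV x 0.025).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.integrate import solve_ivp
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import find_peaks

from .bk import (
    BKRateParams,
    ComplexConfig,
    complex_generator_k,
    mbk_k_coeffs,
    mbk_k_coeffs_instant,
)
from .cav import CaVParams, cav_activation_steady
from .nanodomain import NanodomainParams, default_nanodomain_params
from .traces import Trace

BK_VARIANTS = ("fullODE", "qss", "instant")


class WholeCellParams(BaseModel):
    """Lactotroph model parameters (pF, nS, mV, ms, uM)."""

    model_config = ConfigDict(frozen=True)

    C: float = 10.0
    gK: float = 4.0
    gSK: float = 2.0
    gl: float = 0.2
    Vl: float = -50.0
    Vhalf_n: float = -5.0
    slope_n: float = 10.0
    tau_n: float = 30.0
    ks: float = 0.4
    sk_exp: float = 2.0
    fc: float = 0.01
    kappa: float = 0.0015  # uM per fC: current-to-concentration conversion
    kclear: float = 0.12
    complex: ComplexConfig = ComplexConfig(n=1)
    bk: BKRateParams = BKRateParams()
    cav: CaVParams = CaVParams()
    nano: NanodomainParams = default_nanodomain_params()
    bk_variant: str = "qss"

    @model_validator(mode="after")
    def _check(self) -> "WholeCellParams":
        if self.C <= 0 or not (0 < self.fc <= 1):
            raise ValueError("C must be positive and fc in (0, 1]")
        if min(self.gK, self.gSK, self.gl) < 0:
            raise ValueError("conductances must be non-negative")
        if self.bk_variant not in BK_VARIANTS:
            raise ValueError(f"bk_variant must be one of {BK_VARIANTS}")
        return self

    @property
    def gCa(self) -> float:
        """Whole-cell CaV conductance NCaV * gCa_single, nS."""
        return self.cav.NCaV * self.nano.gCaSingle * 1e-3

    @property
    def gBK(self) -> float:
        """Whole-cell BK conductance NBK * gBK_single, nS."""
        return self.complex.NBK * self.complex.gBKSingle * 1e-3


@dataclass
class _BKTables:
    """Interpolated (tau, mInf) of the BK reduction on a (V, mCaV) grid."""

    tau: RegularGridInterpolator | None
    m_inf: RegularGridInterpolator | None
    tau_1d: tuple[np.ndarray, np.ndarray] | None  # (vgrid, values) for instant
    m_inf_1d: tuple[np.ndarray, np.ndarray] | None


_TABLE_CACHE: dict = {}


def _bk_tables(params: WholeCellParams, n: int) -> _BKTables:
    key = (params.bk, params.cav, params.nano, n, params.bk_variant)
    hit = _TABLE_CACHE.get(key)
    if hit is not None:
        return hit
    vgrid = np.arange(-100.0, 60.0 + 1e-9, 0.5)
    if params.bk_variant == "instant":
        vals = np.array(
            [mbk_k_coeffs_instant(V, n, params.bk, params.cav, params.nano) for V in vgrid]
        )
        tables = _BKTables(None, None, (vgrid, vals[:, 0]), (vgrid, vals[:, 1]))
    else:
        mgrid = np.linspace(0.0, 1.0, 41)
        tau = np.empty((len(vgrid), len(mgrid)))
        mi = np.empty_like(tau)
        for a, V in enumerate(vgrid):
            for b, m in enumerate(mgrid):
                tau[a, b], mi[a, b] = mbk_k_coeffs(V, n, m, params.bk, params.cav, params.nano)
        tables = _BKTables(
            RegularGridInterpolator((vgrid, mgrid), tau, bounds_error=False, fill_value=None),
            RegularGridInterpolator((vgrid, mgrid), mi, bounds_error=False, fill_value=None),
            None,
            None,
        )
    _TABLE_CACHE[key] = tables
    return tables


def membrane_currents(
    V: float, nK: float, c: float, mBK: float, params: WholeCellParams
) -> dict[str, float]:
    """All membrane currents (pA) at the given state."""
    mInf, _ = cav_activation_steady(V, params.cav)
    ICa = params.gCa * mInf * (V - params.nano.VCa)
    IK = params.gK * nK * (V - params.complex.VK)
    sk = c**params.sk_exp / (c**params.sk_exp + params.ks**params.sk_exp)
    ISK = params.gSK * sk * (V - params.complex.VK)
    IBK = params.gBK * mBK * (V - params.complex.VK)
    Il = params.gl * (V - params.Vl)
    return {"ICa": ICa, "IK": IK, "ISK": ISK, "IBK": IBK, "Ileak": Il}


def lactotroph_rhs(state: np.ndarray, params: WholeCellParams) -> np.ndarray:
    """Time derivatives of the whole-cell model state.

    State layout: [V, nK, c, <BK block>], where the BK block is a single
    mBK for the qss/instant variants or the 2(n+1) complex-state
    probabilities for fullODE.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError("state must be finite")
    n = params.complex.n
    return _rhs(0.0, state, params, n, _bk_tables(params, n))


def _bk_open(state: np.ndarray, params: WholeCellParams, n: int) -> float:
    if params.bk_variant == "fullODE":
        return float(np.clip(state[3 + n + 1 : 3 + 2 * (n + 1)].sum(), 0.0, 1.0))
    return float(np.clip(state[3], 0.0, 1.0))


def _rhs(t, state, params: WholeCellParams, n: int, tables: _BKTables):
    V, nK, c = state[0], state[1], state[2]
    mBK = _bk_open(state, params, n)
    cur = membrane_currents(V, nK, c, mBK, params)
    dV = -(cur["ICa"] + cur["IK"] + cur["ISK"] + cur["IBK"] + cur["Ileak"]) / params.C
    n_inf = 1.0 / (1.0 + np.exp(-(V - params.Vhalf_n) / params.slope_n))
    dn = (n_inf - nK) / params.tau_n
    dc = -params.fc * (params.kappa * cur["ICa"] + params.kclear * c)
    out = np.empty_like(state)
    out[0], out[1], out[2] = dV, dn, dc

    if params.bk_variant == "fullODE":
        model = complex_generator_k(V, n, params.bk, params.cav, params.nano)
        p = state[3:]
        out[3:] = model.Q.T @ p
    elif params.bk_variant == "qss":
        mCaV = float(np.clip(state[4], 0.0, 1.0))
        pt = (V, mCaV)
        tau = float(tables.tau(pt))
        m_inf = float(tables.m_inf(pt))
        out[3] = (m_inf - state[3]) / tau
        mInf, tauM = cav_activation_steady(V, params.cav)
        out[4] = (mInf - state[4]) / tauM
    else:  # instant
        vg, tv = tables.tau_1d
        _, mv = tables.m_inf_1d
        tau = float(np.interp(V, vg, tv))
        m_inf = float(np.interp(V, vg, mv))
        out[3] = (m_inf - state[3]) / tau
    return out


def initial_state(params: WholeCellParams, V0: float = -60.0) -> np.ndarray:
    n = params.complex.n
    mInf, _ = cav_activation_steady(V0, params.cav)
    n_inf = 1.0 / (1.0 + np.exp(-(V0 - params.Vhalf_n) / params.slope_n))
    base = [V0, n_inf, 0.1]
    if params.bk_variant == "fullODE":
        from math import comb

        p = np.zeros(2 * (n + 1))
        for i in range(n + 1):
            p[i] = comb(n, i) * (1 - mInf) ** (n - i) * mInf**i
        return np.array(base + list(p))
    if params.bk_variant == "qss":
        return np.array(base + [0.0, mInf])
    return np.array(base + [0.0])


def simulate_wholecell(
    params: WholeCellParams,
    t_end: float,
    *,
    transient: float = 2000.0,
    dt_out: float = 0.05,
    V0: float = -60.0,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> Trace:
    """Deterministic whole-cell simulation.

    Integrates for ``transient + t_end`` ms and returns the post-transient
    window on a uniform ``dt_out`` grid (time rebased to 0).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    n = params.complex.n
    tables = _bk_tables(params, n)
    y0 = initial_state(params, V0)
    t_total = transient + t_end
    grid = np.arange(0.0, t_total + dt_out / 2, dt_out)
    sol = solve_ivp(
        _rhs,
        (0.0, t_total),
        y0,
        t_eval=grid,
        args=(params, n, tables),
        method="LSODA",
        rtol=rtol,
        atol=atol,
        max_step=5.0,
    )
    if not sol.success:
        raise RuntimeError(f"whole-cell integration failed: {sol.message}")
    V = sol.y[0]
    nK = sol.y[1]
    c = sol.y[2]
    mBK = np.array([_bk_open(sol.y[:, j], params, n) for j in range(sol.y.shape[1])])
    cur = {kname: np.empty_like(V) for kname in ("ICa", "IK", "ISK", "IBK", "Ileak")}
    for j in range(len(V)):
        cj = membrane_currents(V[j], nK[j], c[j], mBK[j], params)
        for kname in cur:
            cur[kname][j] = cj[kname]
    tr = Trace(
        t=sol.t,
        channels={"V": V, "nK": nK, "c": c, "mBK": mBK, **cur},
        meta={
            "variant": params.bk_variant,
            "n": n,
            "transient_ms": transient,
            "dt_out_ms": dt_out,
        },
    )
    return tr.after(transient)


@dataclass
class PatternClassification:
    label: str  # spiking | bursting | quiescent
    n_bursts: int
    n_events: int
    events_per_burst: float  # mean oscillations per burst (nan if no burst)
    plateau_fraction: float
    thresholds: dict


def classify_pattern(
    trace: Trace,
    *,
    v_plateau: float = -35.0,
    t_plateau: float = 60.0,
    v_event: float = -20.0,
    min_prominence: float = 1.0,
) -> PatternClassification:
    """Classify a voltage trace as spiking, bursting or quiescent.

    A burst is a maximal interval with V > ``v_plateau`` lasting at least
    ``t_plateau`` ms and containing >= 2 local maxima; spiking consists of
    events (local maxima above ``v_event``) separated by drops below
    ``v_plateau``.
    """
    if len(trace.t) < 2:
        raise ValueError("trace too short to classify")
    V = trace["V"]
    dt = trace.dt
    thresholds = {
        "v_plateau": v_plateau,
        "t_plateau": t_plateau,
        "v_event": v_event,
        "min_prominence": min_prominence,
    }
    above = V > v_plateau
    plateau_fraction = float(above.mean())
    # maximal intervals above the plateau threshold
    edges = np.diff(above.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(V))
    peaks, _ = find_peaks(V, prominence=min_prominence)
    event_peaks = peaks[V[peaks] > v_event]
    n_bursts = 0
    burst_events = []
    spike_events = 0
    for s, e in zip(starts, ends):
        in_iv = peaks[(peaks >= s) & (peaks < e)]
        dur = (e - s) * dt
        if dur >= t_plateau and len(in_iv) >= 2:
            n_bursts += 1
            burst_events.append(len(in_iv))
        else:
            spike_events += int(np.any((event_peaks >= s) & (event_peaks < e)))
    if n_bursts >= 2:
        label = "bursting"
    elif spike_events >= 2 or len(event_peaks) >= 2:
        label = "spiking"
    else:
        label = "quiescent"
    return PatternClassification(
        label=label,
        n_bursts=n_bursts,
        n_events=int(len(event_peaks)),
        events_per_burst=float(np.mean(burst_events)) if burst_events else float("nan"),
        plateau_fraction=plateau_fraction,
        thresholds=thresholds,
    )
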