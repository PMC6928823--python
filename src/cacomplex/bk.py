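"""BK_Ca gating, BK_Ca-CaV complex Markov chains and their ODE reductions.

The BK_Ca channel is a 2-state unit, X (closed) <-> Y (open), with
voltage- and Ca2+-dependent transition rates in separable form

    k+ = w+(V) f+(Ca),   k- = w-(V) f-(Ca),
    w+-(V) = omega * exp(+-V / (2 sV)),

so that the steady open probability is a Boltzmann function of V with a
Ca-independent slope sV and a Ca-dependent half-activation voltage
V1/2(Ca) = sV * ln(f-/f+), which shifts leftward as Ca rises.  The Ca
factors are a Hill pair with midpoint caHalf and exponent caExp plus a
small floor so the rates stay positive:

    f+(Ca) = fFloor + (1-fFloor) * Ca^e / (Ca^e + caHalf^e),
    f-(Ca) = fFloor + (1-fFloor) * caHalf^e / (Ca^e + caHalf^e).

In a BK_Ca-CaV complex the Ca seen by the BK sensor (distance rBK from
each CaV pore) switches with the number of open CaVs: background Cac with
none open, Cac + i * (single nanodomain) with i open.  Coupling the
2-state BK unit with the CaV gating units gives the complex chains, which
are then collapsed to a single activation ODE per complex by quasi-steady
state (QSS) elimination; the instantaneous-CaV limit gives closed-form
coefficients.
"""

from __future__ import annotations

import math
from functools import lru_cache
from math import comb

import numpy as np
from pydantic import BaseModel, model_validator
from scipy.integrate import solve_ivp

from . import constants as const
from .cav import CaVParams, cav_activation_steady, cav_rates, inactivation_rate
from .markov import GeneratorModel
from .nanodomain import NanodomainParams, sensor_concentration

SIX_STATE_LABELS = ("CX", "OX", "BX", "CY", "OY", "BY")


class BKRateParams(BaseModel):
    """Separable BK_Ca rate parameters (ms, mV, uM; rBK in nm)."""

    model_config = {"frozen": True}

    omega: float = 0.2
    sV: float = 8.0
    caHalf: float = 100.0
    caExp: float = 3.0
    fFloor: float = 1e-6
    rBK: float = 13.0

    @model_validator(mode="after")
    def _check(self) -> "BKRateParams":
        if self.omega <= 0 or self.sV <= 0 or self.caHalf <= 0:
            raise ValueError("omega, sV and caHalf must be positive")
        if self.caExp < 1:
            raise ValueError("caExp must be >= 1")
        if not 0 <= self.fFloor < 1:
            raise ValueError("fFloor must lie in [0, 1)")
        return self


class ComplexConfig(BaseModel):
    """Whole-cell BK population and complex stoichiometry."""

    model_config = {"frozen": True}

    n: int = 1
    inactivating: bool = False
    NBK: int = 1000
    gBKSingle: float = 100.0  # pS
    VK: float = -75.0

    @model_validator(mode="after")
    def _check(self) -> "ComplexConfig":
        if self.n < 1 or self.NBK < 1 or self.gBKSingle <= 0:
            raise ValueError("n >= 1, NBK >= 1 and gBKSingle > 0 required")
        return self


def bk_rates(V: float, Ca: float, params: BKRateParams) -> tuple[float, float]:
    """Opening and closing rates (k+, k-) in 1/ms at (V, Ca)."""
    if Ca < 0:
        raise ValueError("Ca must be non-negative")
    wp = params.omega * math.exp(V / (2.0 * params.sV))
    wm = params.omega * math.exp(-V / (2.0 * params.sV))
    cae = Ca**params.caExp
    hill = cae / (cae + params.caHalf**params.caExp)
    fp = params.fFloor + (1.0 - params.fFloor) * hill
    fm = params.fFloor + (1.0 - params.fFloor) * (1.0 - hill)
    return wp * fp, wm * fm


def bk_open_steady(V: float, Ca: float, params: BKRateParams) -> float:
    kp, km = bk_rates(V, Ca, params)
    return kp / (kp + km)


def _vertical_rates(
    V: float, n_open: int, bk: BKRateParams, nano: NanodomainParams
) -> tuple[float, float]:
    """BK rates at the sensor Ca with ``n_open`` open CaVs at distance rBK."""
    ca = sensor_concentration(n_open, V, bk.rBK, nano)
    return bk_rates(V, ca, bk)


def complex_generator_1to1(
    V: float,
    bk: BKRateParams,
    cav: CaVParams,
    nano: NanodomainParams,
) -> GeneratorModel:
    """6-state generator of the 1:1 BK_Ca-CaV complex at fixed V.

    States (CX, OX, BX, CY, OY, BY): CaV closed/open/inactivated paired
    with BK closed (X) or open (Y).  CaV rates are identical in the X and
    Y rows; BK rates use Cac in the C and B columns and the open-channel
    nanodomain Ca in the O column.
    """
    alpha, beta = cav_rates(V, cav)
    delta = inactivation_rate(V, cav, nano)
    gamma = cav.gamma
    kc_p, kc_m = bk_rates(V, nano.Cac, bk)
    ko_p, ko_m = _vertical_rates(V, 1, bk, nano)
    kb_p, kb_m = bk_rates(V, nano.Cab, bk)

    Q = np.zeros((6, 6))
    idx = {s: i for i, s in enumerate(SIX_STATE_LABELS)}

    def add(a: str, b: str, rate: float) -> None:
        Q[idx[a], idx[b]] += rate

    for row in ("X", "Y"):
        add("C" + row, "O" + row, alpha)
        add("O" + row, "C" + row, beta)
        add("O" + row, "B" + row, delta)
        add("B" + row, "C" + row, gamma)
    add("CX", "CY", kc_p)
    add("CY", "CX", kc_m)
    add("OX", "OY", ko_p)
    add("OY", "OX", ko_m)
    add("BX", "BY", kb_p)
    add("BY", "BX", kb_m)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return GeneratorModel(state_labels=SIX_STATE_LABELS, Q=Q)


def pY_from_6state(p: np.ndarray) -> float:
    """BK open probability pCY + pOY + pBY from a 6-state distribution."""
    p = np.asarray(p, dtype=float)
    if p.shape != (6,) or abs(p.sum() - 1.0) > 1e-8 or np.any(p < -1e-12):
        raise ValueError("p must be a distribution over the 6 complex states")
    return float(p[3:].sum())


def complex_k_labels(k: int) -> tuple[str, ...]:
    """State labels of the k-CaV (non-inactivating) complex chain."""
    return tuple(
        f"C{k - i}O{i}{bkstate}" for bkstate in ("X", "Y") for i in range(k + 1)
    )


def complex_generator_k(
    V: float,
    k: int,
    bk: BKRateParams,
    cav: CaVParams,
    nano: NanodomainParams,
) -> GeneratorModel:
    """Generator of the 2(k+1)-state chain: k non-inactivating CaVs + BK.

    State (i, X/Y): i open CaVs, BK closed/open.  Horizontal CaV moves
    carry binomial combinatorics ((k-i)*alpha up, i*beta down); vertical BK
    moves use the sensor Ca with i open CaVs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    alpha, beta = cav_rates(V, cav)
    m = 2 * (k + 1)
    Q = np.zeros((m, m))
    X = lambda i: i  # noqa: E731
    Y = lambda i: k + 1 + i  # noqa: E731
    for i in range(k + 1):
        if i < k:
            Q[X(i), X(i + 1)] += (k - i) * alpha
            Q[Y(i), Y(i + 1)] += (k - i) * alpha
        if i > 0:
            Q[X(i), X(i - 1)] += i * beta
            Q[Y(i), Y(i - 1)] += i * beta
        kp, km = _vertical_rates(V, i, bk, nano)
        Q[X(i), Y(i)] += kp
        Q[Y(i), X(i)] += km
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return GeneratorModel(state_labels=complex_k_labels(k), Q=Q)


def mbk1_coeffs(
    V: float, mCaV: float, bk: BKRateParams, cav: CaVParams, nano: NanodomainParams
) -> tuple[float, float]:
    """(tauBK, mBKinf) of the single-ODE reduction for the 1:1 complex.

    tauBK = (alpha+beta+kc-) / ((ko+ + ko-)(kc- + alpha) + beta*kc-),
    mBKinf = mCaV * ko+ * tauBK.
    """
    if not 0.0 <= mCaV <= 1.0:
        raise ValueError("mCaV must lie in [0, 1]")
    alpha, beta = cav_rates(V, cav)
    _, kc_m = bk_rates(V, nano.Cac, bk)
    ko_p, ko_m = _vertical_rates(V, 1, bk, nano)
    tau = (alpha + beta + kc_m) / ((ko_p + ko_m) * (kc_m + alpha) + beta * kc_m)
    return tau, mCaV * ko_p * tau


def mbk1_coeffs_instant(
    V: float, bk: BKRateParams, cav: CaVParams, nano: NanodomainParams
) -> tuple[float, float]:
    """(tauBK, mBKinf) of the 1:1 reduction in the fast-CaV limit."""
    mInf, _ = cav_activation_steady(V, cav)
    _, kc_m = bk_rates(V, nano.Cac, bk)
    ko_p, ko_m = _vertical_rates(V, 1, bk, nano)
    denom = kc_m - mInf * (kc_m - ko_p - ko_m)
    if denom <= 0:
        raise ValueError("degenerate time-constant denominator")
    tau = 1.0 / denom
    return tau, mInf * ko_p * tau


def mbk_k_coeffs(
    V: float,
    k: int,
    mCaV: float,
    bk: BKRateParams,
    cav: CaVParams,
    nano: NanodomainParams,
) -> tuple[float, float]:
    """(tauBK, mBKinf) of the single-ODE QSS reduction for k CaVs.

    Obtained by a linear solve of the quasi-steady-state system for the
    open-BK occupancies at given (V, mCaV): the closed-BK occupancies are
    binomial(k, mCaV) minus the open-BK ones, the cumulative open-BK
    variables below the top level are set to equilibrium, and the remaining
    scalar ODE for mBK = sum of open-BK occupancies has the relaxation form
    dmBK/dt = (mBKinf - mBK)/tauBK.  Reduces to :func:`mbk1_coeffs` at k=1.

    As in the closed-form k=1 reduction, the opening rate of a complex with
    no open CaVs (kc+, at background Ca) is neglected here; the full Markov
    chains keep it, and it is checked to be negligible.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 <= mCaV <= 1.0:
        raise ValueError("mCaV must lie in [0, 1]")
    alpha, beta = cav_rates(V, cav)
    kp = np.empty(k + 1)
    km = np.empty(k + 1)
    for i in range(k + 1):
        kp[i], km[i] = _vertical_rates(V, i, bk, nano)
    kp[0] = 0.0  # kc+ ~ 0 at background Ca, as in the closed-form reduction
    b = np.array(
        [comb(k, i) * (1 - mCaV) ** (k - i) * mCaV**i for i in range(k + 1)]
    )
    a = kp + km
    # QSS equations E_i = 0 for i = 0..k-1 in the raw open-BK occupancies y_j
    A = np.zeros((k + 1, k + 1))
    c = np.zeros(k + 1)
    for i in range(k):
        A[i, i] -= (k - i) * alpha
        A[i, i + 1] += (i + 1) * beta
        A[i, : i + 1] -= a[: i + 1]
        c[i] = float(kp[: i + 1] @ b[: i + 1])
    A[k, :] = 1.0  # normalization row: sum_j y_j = mBK
    rhs_u = np.concatenate([-c[:k], [0.0]])
    rhs_v = np.concatenate([np.zeros(k), [1.0]])
    u = np.linalg.solve(A, rhs_u)
    v = np.linalg.solve(A, rhs_v)
    S = float(kp @ b)
    decay = float(a @ v)
    tau = 1.0 / decay
    m_inf = (S - float(a @ u)) * tau
    return tau, m_inf


def mbk_k_coeffs_instant(
    V: float, k: int, bk: BKRateParams, cav: CaVParams, nano: NanodomainParams
) -> tuple[float, float]:
    """(tauBK, mBKinf) for k CaVs in the instantaneous-activation limit.

    The CaV open count is binomial(k, mInf(V)) and the BK vertical rates are
    averaged over it:

        tauBK  = [sum_i C(k,i)(1-mInf)^(k-i) mInf^i (koi+ + koi-)
                  + (1-mInf)^k kc-]^-1      (i = 1..k),
        mBKinf = sum_i C(k,i)(1-mInf)^(k-i) mInf^i koi+ * tauBK.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mInf, _ = cav_activation_steady(V, cav)
    acc_rate = 0.0
    acc_open = 0.0
    for i in range(1, k + 1):
        w = comb(k, i) * (1 - mInf) ** (k - i) * mInf**i
        kp, km = _vertical_rates(V, i, bk, nano)
        acc_rate += w * (kp + km)
        acc_open += w * kp
    _, kc_m = bk_rates(V, nano.Cac, bk)
    acc_rate += (1 - mInf) ** k * kc_m
    tau = 1.0 / acc_rate
    return tau, acc_open * tau


def pY_mixture(h: float, mBK: dict[int, float], n: int) -> float:
    """BK open probability with inactivating CaVs:

    pY(n) = sum_{k=1..n} C(n,k) h^k (1-h)^(n-k) mBK(k).
    """
    if not 0.0 <= h <= 1.0:
        raise ValueError("h must lie in [0, 1]")
    total = 0.0
    for kk in range(1, n + 1):
        total += comb(n, kk) * h**kk * (1 - h) ** (n - kk) * mBK[kk]
    return total


def ibk_current(V: float, pY: float, config: ComplexConfig) -> float:
    """Whole-cell BK current NBK * gBK_single * pY * (V - VK) in pA."""
    if not 0.0 <= pY <= 1.0:
        raise ValueError("pY must lie in [0, 1]")
    return config.NBK * config.gBKSingle * pY * (V - config.VK) * const.PS_MV_TO_PA


# ---------------------------------------------------------------------------
# Trajectories of the reduction ladder on piecewise-constant voltage protocols


def _v_of_protocol(protocol):
    bounds = np.concatenate([[0.0], np.cumsum([d for d, _ in protocol])])

    def v_at(t: float) -> float:
        i = int(np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, len(protocol) - 1))
        return float(protocol[i][1])

    return v_at, bounds


def full_ode_open_probability(
    protocol,
    k: int,
    bk: BKRateParams,
    cav: CaVParams,
    nano: NanodomainParams,
    grid: np.ndarray,
    *,
    p0: np.ndarray | None = None,
) -> np.ndarray:
    """BK open probability from the full 2(k+1)-state master equation
    (exact matrix-exponential propagation on the step protocol)."""
    from .markov import solve_master_equation_protocol

    q_of = lambda V: complex_generator_k(V, k, bk, cav, nano)  # noqa: E731
    if p0 is None:
        p0 = np.zeros(2 * (k + 1))
        p0[0] = 1.0
    probs = solve_master_equation_protocol(q_of, protocol, p0, grid)
    return probs[:, k + 1 :].sum(axis=1)


def qss_open_probability(
    protocol,
    k: int,
    bk: BKRateParams,
    cav: CaVParams,
    nano: NanodomainParams,
    grid: np.ndarray,
    *,
    instant: bool = False,
    m0: float | None = None,
) -> np.ndarray:
    """BK open probability from the single-ODE QSS reduction (optionally in
    the instantaneous-CaV limit) along a step protocol."""
    v_at, _ = _v_of_protocol(protocol)

    if instant:
        def rhs(t, y):
            V = v_at(t)
            tau, m_inf = mbk_k_coeffs_instant(V, k, bk, cav, nano)
            return [(m_inf - y[0]) / tau]

        y0 = [0.0 if m0 is None else m0]
    else:
        def rhs(t, y):
            V = v_at(t)
            mInf, tauM = cav_activation_steady(V, cav)
            tau, m_inf = mbk_k_coeffs(V, k, min(max(y[1], 0.0), 1.0), bk, cav, nano)
            return [(m_inf - y[0]) / tau, (mInf - y[1]) / tauM]

        mInf0, _ = cav_activation_steady(v_at(0.0), cav)
        y0 = [0.0 if m0 is None else m0, mInf0]

    sol = solve_ivp(
        rhs,
        (grid[0], grid[-1]),
        y0,
        t_eval=grid,
        method="LSODA",
        rtol=1e-8,
        atol=1e-10,
        max_step=1.0,
    )
    if not sol.success:
        raise RuntimeError(f"QSS integration failed: {sol.message}")
    return np.clip(sol.y[0], 0.0, 1.0)
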