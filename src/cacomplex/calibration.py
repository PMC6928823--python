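"""Calibration of separable BK gating rates from Boltzmann-style data,
plus synthetic fixture generators (gating datasets and voltage waveforms).

Steady-state open probabilities pInf(V, Ca) and time constants tau(V, Ca)
of a 2-state channel determine the microscopic rates uniquely:

    k+ = pInf / tau,    k- = (1 - pInf) / tau.

If the rates are separable, k+- = w+-(V) f+-(Ca), their logarithm is
additive in V and Ca, so fitting is done in log-rate space and
separability is scored as the variance fraction explained by the additive
(row + column) decomposition of the log-rate tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .bk import BKRateParams, bk_rates
from .traces import Protocol, Trace, sample_protocol

GATING_COLUMNS = ("V_mV", "Ca_uM", "pInf", "tau_ms")


def rates_from_boltzmann(gating: pd.DataFrame) -> pd.DataFrame:
    """Pointwise rates from a gating table with columns (V_mV, Ca_uM, pInf, tau_ms).

    Returns the table with kPlus and kMinus columns added.
    """
    missing = [c for c in GATING_COLUMNS if c not in gating.columns]
    if missing:
        raise ValueError(f"gating table lacks columns {missing}")
    if not ((gating["pInf"] > 0) & (gating["pInf"] < 1)).all():
        raise ValueError("pInf must lie strictly in (0, 1)")
    if not (gating["tau_ms"] > 0).all():
        raise ValueError("tau_ms must be positive")
    out = gating.copy()
    out["kPlus"] = out["pInf"] / out["tau_ms"]
    out["kMinus"] = (1.0 - out["pInf"]) / out["tau_ms"]
    return out


def separability_score(rates: pd.DataFrame) -> float:
    """Fraction of log-rate variance explained by the additive V + Ca model,
    minimized over the two rate tables (1 = perfectly separable)."""
    scores = []
    for col in ("kPlus", "kMinus"):
        piv = rates.pivot_table(index="V_mV", columns="Ca_uM", values=col, aggfunc="mean")
        L = np.log(piv.to_numpy())
        L0 = L - L.mean()
        resid = L0 - L0.mean(axis=1, keepdims=True) - L0.mean(axis=0, keepdims=True)
        total = float(np.sum(L0**2))
        scores.append(1.0 - float(np.sum(resid**2)) / total if total > 0 else 1.0)
    return min(scores)


@dataclass
class SeparableFit:
    """Result of fitting the separable BK rate family."""

    params: BKRateParams
    residuals: pd.DataFrame  # per-point log-rate residuals
    separability: float
    cost: float
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Separable BK rate fit (log-rate least squares)",
            f"  omega  = {p.omega:.5g} /ms",
            f"  sV     = {p.sV:.5g} mV",
            f"  caHalf = {p.caHalf:.5g} uM",
            f"  caExp  = {p.caExp:.5g}",
            f"  fFloor = {p.fFloor:.3g}",
            f"  separability score = {self.separability:.4f}",
            f"  residual SSQ (log space) = {self.cost:.3g}",
        ]
        lines += [f"  WARNING: {w}" for w in self.warnings]
        return "\n".join(lines)


def _pack(p: BKRateParams) -> np.ndarray:
    return np.array(
        [np.log(p.omega), np.log(p.sV), np.log(p.caHalf), np.log(p.caExp), np.log(p.fFloor)]
    )


def _unpack(x: np.ndarray) -> BKRateParams:
    x = np.clip(x, -60.0, 60.0)
    return BKRateParams(
        omega=float(np.exp(x[0])),
        sV=float(np.exp(x[1])),
        caHalf=float(np.exp(x[2])),
        caExp=float(max(np.exp(x[3]), 1.0)),
        fFloor=float(min(np.exp(x[4]), 0.5)),
    )


def fit_separable_rates(rates: pd.DataFrame) -> SeparableFit:
    """Fit the separable rate family to pointwise (kPlus, kMinus) tables.

    Requires at least 3 Ca levels and 5 voltages.  Fitting minimizes the
    log-rate residuals; the returned diagnostics include per-point
    residuals and the separability score (warning below 0.9).
    """
    if rates["Ca_uM"].nunique() < 3 or rates["V_mV"].nunique() < 5:
        raise ValueError("need >= 3 Ca levels and >= 5 voltages")
    V = rates["V_mV"].to_numpy(dtype=float)
    Ca = rates["Ca_uM"].to_numpy(dtype=float)
    logkp = np.log(rates["kPlus"].to_numpy(dtype=float))
    logkm = np.log(rates["kMinus"].to_numpy(dtype=float))

    def resid(x: np.ndarray) -> np.ndarray:
        p = _unpack(x)
        kp = np.empty_like(V)
        km = np.empty_like(V)
        for i in range(len(V)):
            kp[i], km[i] = bk_rates(V[i], Ca[i], p)
        return np.concatenate([np.log(kp) - logkp, np.log(km) - logkm])

    # data-driven initialization: sV from the voltage slope of ln(k+/k-)
    dlk = logkp - logkm
    A = np.vstack([V, np.ones_like(V)]).T
    slope = float(np.linalg.lstsq(A, dlk, rcond=None)[0][0])
    sv0 = 1.0 / max(slope, 1e-3)
    om0 = float(np.exp(0.5 * np.mean(logkp + logkm)))
    starts = [
        _pack(BKRateParams(omega=om0, sV=sv0, caHalf=float(np.median(Ca)), caExp=2.0, fFloor=1e-5)),
        _pack(BKRateParams(omega=om0, sV=sv0, caHalf=float(np.max(Ca)), caExp=3.0, fFloor=1e-6)),
        _pack(BKRateParams()),
    ]
    best = None
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("separable-rate fit failed from all starting points")
    params = _unpack(best.x)
    r = best.fun
    npts = len(V)
    res_df = rates[["V_mV", "Ca_uM"]].copy()
    res_df["resid_log_kPlus"] = r[:npts]
    res_df["resid_log_kMinus"] = r[npts:]
    score = separability_score(rates)
    warnings = []
    if score < 0.9:
        warnings.append(f"data look non-separable (score {score:.3f} < 0.9)")
    return SeparableFit(
        params=params,
        residuals=res_df,
        separability=score,
        cost=2.0 * best.cost,  # least_squares cost is half the SSQ
        warnings=warnings,
    )


DEFAULT_V_GRID = tuple(np.arange(-80.0, 80.0 + 1e-9, 10.0))
DEFAULT_CA_GRID = (1.0, 4.0, 10.0, 30.0, 100.0)


def generate_gating_fixture(
    truth: BKRateParams,
    v_grid=DEFAULT_V_GRID,
    ca_grid=DEFAULT_CA_GRID,
    noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic gating dataset (pInf, tau vs V at several Ca levels).

    Multiplicative log-normal noise of relative scale ``noise`` is applied
    to the underlying opening/closing rates independently, which keeps the
    derived pInf inside (0, 1) and makes tau log-normally perturbed;
    seed-reproducible.
    """
    if noise < 0:
        raise ValueError("noise must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for ca in ca_grid:
        for v in v_grid:
            kp, km = bk_rates(float(v), float(ca), truth)
            if noise > 0:
                kp = kp * rng.lognormal(0.0, noise)
                km = km * rng.lognormal(0.0, noise)
            rows.append({
                "V_mV": v, "Ca_uM": ca,
                "pInf": kp / (kp + km), "tau_ms": 1.0 / (kp + km),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Voltage waveform fixtures

SPIKING_CYCLE: Protocol = [(10.0, -10.0), (240.0, -60.0)]  # 4 Hz square APs

# 0.5 Hz plateau bursts: 800 ms near -25 mV with square ripples
BURSTING_CYCLE: Protocol = (
    [(100.0, -20.0), (100.0, -30.0)] * 4 + [(1200.0, -60.0)]
)


def generate_voltage_fixture(
    pattern: str, *, t_end: float = 10000.0, dt: float = 0.5
) -> tuple[Protocol, Trace]:
    """Canned piecewise-constant voltage waveform emulating lactotroph activity.

    ``spiking``: 4 Hz square action potentials, 10 ms at -10 mV from a
    -60 mV baseline (time above -35 mV: 4%).  ``bursting``: 0.5 Hz
    plateaus, 800 ms alternating -20/-30 mV (square ripples) from -60 mV
    (time above -35 mV: 40%).  Returns the protocol (for exact stochastic
    simulation) and a sampled trace.
    """
    if pattern == "spiking":
        cycle = SPIKING_CYCLE
    elif pattern == "bursting":
        cycle = BURSTING_CYCLE
    else:
        raise ValueError("pattern must be 'spiking' or 'bursting'")
    cycle_len = sum(d for d, _ in cycle)
    n_cycles = int(np.ceil(t_end / cycle_len))
    protocol = list(cycle) * n_cycles
    # trim to t_end
    out: Protocol = []
    acc = 0.0
    for d, v in protocol:
        if acc + d >= t_end - 1e-9:
            out.append((t_end - acc, v))
            break
        out.append((d, v))
        acc += d
    tr = sample_protocol(out, dt=dt)
    tr.meta["pattern"] = pattern
    return out, tr
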