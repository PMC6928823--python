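"""Uniformly sampled named time series and piecewise-constant voltage protocols."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

Protocol = list[tuple[float, float]]


@dataclass
class Trace:
    """Uniformly sampled time series of named signals (t in ms)."""

    t: np.ndarray
    channels: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if len(self.t) >= 2:
            dts = np.diff(self.t)
            if np.any(dts <= 0) or not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time grid must be strictly increasing and equispaced")
        for name, v in self.channels.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.t.shape:
                raise ValueError(f"channel {name!r} length mismatch")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            self.channels[name] = v

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def after(self, t0: float) -> "Trace":
        """Sub-trace with t >= t0 (e.g. to discard a transient), time rebased to 0."""
        mask = self.t >= t0 - 1e-9
        return Trace(
            t=self.t[mask] - self.t[mask][0],
            channels={k: v[mask] for k, v in self.channels.items()},
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t_ms": self.t})
        for name, v in self.channels.items():
            df[name] = v
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: dict | None = None) -> "Trace":
        t = df["t_ms"].to_numpy(dtype=float)
        channels = {c: df[c].to_numpy(dtype=float) for c in df.columns if c != "t_ms"}
        return cls(t=t, channels=channels, meta=meta or {})


def protocol_duration(protocol: Protocol) -> float:
    return float(sum(d for d, _ in protocol))


def sample_protocol(protocol: Protocol, dt: float = 0.5) -> Trace:
    """Sample a piecewise-constant voltage protocol on a uniform grid
    (left-continuous hold within each segment)."""
    total = protocol_duration(protocol)
    t = np.arange(0.0, total + dt / 2, dt)
    bounds = np.concatenate([[0.0], np.cumsum([d for d, _ in protocol])])
    vs = np.array([v for _, v in protocol])
    idx = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, len(vs) - 1)
    return Trace(t=t, channels={"V": vs[idx]}, meta={"protocol": list(protocol)})


def repeat_protocol(cycle: Protocol, n_cycles: int) -> Protocol:
    return list(cycle) * n_cycles


def step_protocol(v_hold: float, v_step: float, t_hold: float, t_step: float) -> Protocol:
    """Simple hold-then-step voltage-clamp protocol."""
    return [(t_hold, v_hold), (t_step, v_step)]
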