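"""Uniformly sampled current/voltage traces and their on-disk format.

Traces are stored as two-column delimited text (time ms, value) with a JSON
sidecar (<path>.json) holding dt, unit, stimulus times and the condition
label, so every file is self-describing and diffable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Trace", "read_trace", "write_trace", "TraceFormatError"]


class TraceFormatError(ValueError):
    pass


@dataclass(frozen=True)
class Trace:
    t0: float
    dt: float
    samples: np.ndarray
    unit: str = "pA"
    stim_times: tuple = ()
    label: str = ""

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 1 or len(s) == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(s)):
            raise ValueError("samples must be finite")
        object.__setattr__(self, "samples", s)
        object.__setattr__(self, "stim_times", tuple(float(x) for x in self.stim_times))
        t_end = self.t0 + self.dt * (len(s) - 1)
        for st in self.stim_times:
            if not (self.t0 <= st <= t_end):
                raise ValueError(f"stimulus time {st} ms outside record")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.samples))

    @property
    def duration(self) -> float:
        return self.dt * (len(self.samples) - 1)

    def slice(self, t_lo: float, t_hi: float) -> "Trace":
        m = (self.times >= t_lo) & (self.times <= t_hi)
        if not np.any(m):
            raise ValueError(f"empty slice [{t_lo}, {t_hi}] ms")
        return Trace(t0=float(self.times[m][0]), dt=self.dt,
                     samples=self.samples[m], unit=self.unit,
                     stim_times=tuple(s for s in self.stim_times
                                      if t_lo <= s <= t_hi),
                     label=self.label)

    def replace(self, **kw) -> "Trace":
        return replace(self, **kw)


def write_trace(trace: Trace, path) -> None:
    path = Path(path)
    df = pd.DataFrame({"time_ms": trace.times, "value": trace.samples})
    df.to_csv(path, index=False, float_format="%.17g")
    meta = dict(t0=trace.t0, dt=trace.dt, unit=trace.unit,
                stim_times=list(trace.stim_times), label=trace.label)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_trace(path) -> Trace:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise TraceFormatError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # ragged rows etc.
        raise TraceFormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] != 2:
        raise TraceFormatError("trace file must have exactly two columns")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if len(t) > 1:
        steps = np.diff(t)
        if np.any(steps <= 0) or np.max(np.abs(steps - meta["dt"])) > 1e-6 * meta["dt"]:
            raise TraceFormatError("time column is not uniformly increasing at dt")
    return Trace(t0=float(meta["t0"]), dt=float(meta["dt"]),
                 samples=df.iloc[:, 1].to_numpy(dtype=float),
                 unit=meta.get("unit", "pA"),
                 stim_times=tuple(meta.get("stim_times", ())),
                 label=meta.get("label", ""))
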