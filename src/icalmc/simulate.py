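"""Paced-protocol simulation engine for gate-based and hybrid cell models.

A protocol is a train of square stimulus pulses (default: −52 A/F for 1 ms
at 1 Hz, 11 pulses).  Integration uses the stiff multistep LSODA solver
with the maximum step capped at 0.1 ms, sampled on a uniform 0.1 ms output
grid; each stimulus edge starts a fresh integration segment so the solver
never steps across the discontinuity.

Two protocol modes exist:

* ``FULL`` — the unmodified model.
* ``SCI`` (Suppressed Calcium Inactivation) — calcium sensitivity removed:
  gate models run with fcass ≡ 1, Markov-chain hybrids evaluate their
  calcium-dependence function at a frozen css value throughout.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .gate_models import CellModelSpec, build_gate_model

__all__ = [
    "ProtocolSpec",
    "IntegratorSettings",
    "Trace",
    "run_protocol",
    "extract_window",
    "generate_target",
    "integrate_ode",
]

TRACE_COLUMNS = ("t_ms", "V_mV", "Cai_mM", "css_mM", "ICaL_ApF", "O")


class SimulationError(RuntimeError):
    """Integrator failure; carries the last valid time reached."""

    def __init__(self, message: str, last_valid_time: float | None = None):
        super().__init__(message)
        self.last_valid_time = last_valid_time


@dataclass(frozen=True)
class ProtocolSpec:
    """Pacing protocol definition."""

    pacing_frequency: float = 1.0       # Hz
    n_pulses: int = 11
    stimulus_amplitude: float = -52.0   # A/F
    stimulus_duration: float = 1.0      # ms
    mode: str = "FULL"                  # FULL or SCI
    sci_frozen_css: float | None = None  # mM; None -> model's initial css

    def __post_init__(self):
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.pacing_frequency <= 0:
            raise ValueError("pacing_frequency must be positive")
        if self.mode not in ("FULL", "SCI"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.pacing_frequency

    @property
    def total_time_ms(self) -> float:
        return self.n_pulses * self.period_ms

    def last_pulse_window(self) -> tuple[float, float]:
        """The fitness/biomarker window: the final paced beat."""
        return (self.n_pulses - 1) * self.period_ms, self.total_time_ms


@dataclass(frozen=True)
class IntegratorSettings:
    """LSODA settings; the 0.1 ms max step mirrors the output grid."""

    max_step: float = 0.1   # ms
    rtol: float = 1e-6
    atol: float = 1e-8
    output_dt: float = 0.1  # ms


@dataclass
class Trace:
    """Uniformly sampled time series of one simulation."""

    times: np.ndarray       # ms, strictly increasing
    V: np.ndarray           # mV
    Cai: np.ndarray         # mM
    css: np.ndarray         # mM
    ICaL: np.ndarray        # A/F
    O: np.ndarray           # dimensionless
    meta: dict = field(default_factory=dict)
    states: np.ndarray | None = None  # optional full state history

    def __post_init__(self):
        arrays = [np.asarray(a, dtype=float)
                  for a in (self.times, self.V, self.Cai, self.css,
                            self.ICaL, self.O)]
        n = arrays[0].shape[0]
        if any(a.shape != (n,) for a in arrays):
            raise ValueError("trace arrays must share one length")
        if np.any(np.diff(arrays[0]) <= 0):
            raise ValueError("times must be strictly increasing")
        (self.times, self.V, self.Cai, self.css, self.ICaL, self.O) = arrays

    def __len__(self) -> int:
        return len(self.times)

    @property
    def output_dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(zip(TRACE_COLUMNS,
                                     (self.times, self.V, self.Cai,
                                      self.css, self.ICaL, self.O))))

    def to_csv(self, path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.17g")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(self.meta, indent=1, sort_keys=True))

    @classmethod
    def from_csv(cls, path) -> "Trace":
        path = Path(path)
        df = pd.read_csv(path, float_precision="round_trip")
        meta = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(*(df[c].to_numpy() for c in TRACE_COLUMNS), meta=meta)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for a in (self.times, self.V, self.Cai, self.css, self.ICaL, self.O):
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()


def integrate_ode(fun, y0, t_eval, settings: IntegratorSettings = IntegratorSettings(),
                  args: tuple = ()) -> np.ndarray:
    """Integrate dy/dt = fun(y, t, *args) on t_eval with the protocol engine.

    Thin wrapper over the stiff multistep solver used by :func:`run_protocol`;
    exposed so scalar test problems exercise the exact same engine.
    """
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    out, info = odeint(fun, y0, np.asarray(t_eval, dtype=float), args=args,
                       rtol=settings.rtol, atol=settings.atol,
                       hmax=settings.max_step, mxstep=1000000,
                       full_output=True)
    if info["message"] != "Integration successful.":
        raise SimulationError(
            f"integrator failed: {info['message']}",
            last_valid_time=float(info["tcur"][-1]) if len(info["tcur"]) else None)
    if not np.all(np.isfinite(out)):
        raise SimulationError("integrator produced non-finite values")
    return out


def _grid(t0: float, t1: float, dt: float) -> np.ndarray:
    n = int(round((t1 - t0) / dt))
    return t0 + dt * np.arange(n + 1)


def run_protocol(model: CellModelSpec,
                 protocol: ProtocolSpec = ProtocolSpec(),
                 settings: IntegratorSettings = IntegratorSettings(),
                 keep_states: bool = False) -> Trace:
    """Simulate a paced protocol and return the sampled trace.

    SCI encoding passed to the kernels: gate models receive a 0/1 flag;
    hybrid models receive the frozen css (≤ 0 meaning "not frozen").
    With ``keep_states`` the full state history is attached to the trace.
    """
    sci = protocol.mode == "SCI"
    if model.variant == "gate":
        sci_arg = 1.0 if sci else 0.0
    else:
        if sci:
            frozen = protocol.sci_frozen_css
            if frozen is None:
                frozen = float(model.initial_state[model.index("CaSS")])
            if frozen <= 0:
                raise ValueError("sci_frozen_css must be positive")
            sci_arg = frozen
        else:
            sci_arg = -1.0

    dt = settings.output_dt
    period = protocol.period_ms
    dur = protocol.stimulus_duration
    grid = _grid(0.0, protocol.total_time_ms, dt)
    states = np.empty((grid.size, model.n_states))
    states[0] = model.initial_state

    y = model.initial_state.copy()
    pos = 0  # index of the last written grid point
    for k in range(protocol.n_pulses):
        for (seg_a, seg_b, stim) in (
                (k * period, k * period + dur, protocol.stimulus_amplitude),
                (k * period + dur, (k + 1) * period, 0.0)):
            # grid points strictly inside (seg_a, seg_b], plus both endpoints
            lo = int(np.searchsorted(grid, seg_a + 1e-9))
            hi = int(np.searchsorted(grid, seg_b + 1e-9))
            ts = np.concatenate(([seg_a], grid[lo:hi]))
            if ts[-1] < seg_b - 1e-9:
                ts = np.append(ts, seg_b)
                extra_end = True
            else:
                extra_end = False
            out = integrate_ode(model.rhs_kernel, y, ts, settings,
                                args=(stim, sci_arg, model.params))
            y = out[-1].copy()
            sampled = out[1:-1] if extra_end else out[1:]
            states[pos + 1: pos + 1 + sampled.shape[0]] = sampled
            pos += sampled.shape[0]

    assert pos == grid.size - 1
    sci_flag = sci and model.variant == "gate"
    v = states[:, model.index("V")]
    cai = states[:, model.index("Cai")]
    css = states[:, model.index("CaSS")]
    o = model.opening_fraction(states, sci=sci_flag)
    ical = model.ical(states, sci=sci_flag)
    meta = {
        "model_id": model.model_id,
        "variant": model.variant,
        "protocol": {k: v_ for k, v_ in asdict(protocol).items()},
        "settings": asdict(settings),
        "schema_version": "1",
    }
    return Trace(grid, v, cai, css, ical, o, meta=meta,
                 states=states if keep_states else None)


def extract_window(trace: Trace, t0: float, t1: float) -> Trace:
    """Sub-trace on [t0, t1] (endpoints included on the output grid)."""
    if t0 >= t1:
        raise ValueError("t0 must be < t1")
    eps = 1e-9
    if t0 < trace.times[0] - eps or t1 > trace.times[-1] + eps:
        raise ValueError("window outside trace span")
    mask = (trace.times >= t0 - eps) & (trace.times <= t1 + eps)
    meta = dict(trace.meta)
    meta["window_ms"] = [t0, t1]
    return Trace(trace.times[mask], trace.V[mask], trace.Cai[mask],
                 trace.css[mask], trace.ICaL[mask], trace.O[mask], meta=meta,
                 states=None if trace.states is None else trace.states[mask])


def _target_key(model_id: str, protocol: ProtocolSpec,
                settings: IntegratorSettings) -> str:
    blob = json.dumps([model_id, asdict(protocol), asdict(settings)],
                      sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def generate_target(model_id: str,
                    protocol: ProtocolSpec = ProtocolSpec(),
                    settings: IntegratorSettings = IntegratorSettings(),
                    cache_dir=None) -> Trace:
    """Reference I_CaL trace of the gate-based model on the fitness window.

    Deterministic; when ``cache_dir`` is given the window trace is cached on
    disk keyed by a content hash of (model, protocol, settings) so fitting
    runs reuse it.
    """
    key = _target_key(model_id, protocol, settings)
    if cache_dir is not None:
        cached = Path(cache_dir) / f"target_{model_id}_{key}.csv"
        if cached.exists():
            return Trace.from_csv(cached)
    trace = run_protocol(build_gate_model(model_id), protocol, settings)
    t0, t1 = protocol.last_pulse_window()
    target = extract_window(trace, t0, t1)
    target.meta["target_key"] = key
    target.meta["content_hash"] = target.content_hash()
    if cache_dir is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        target.to_csv(cached)
    return target
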