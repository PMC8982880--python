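"""Seven-state Markov-chain model of the L-type calcium current.

The chain replaces the four Hodgkin–Huxley gates (d, f, f2, fcass) of the
TP and ST models.  Each HH gate g with steady state g∞ and time constant
τg defines a pair of elementary rates

    g+ = g∞/τg        (closed → open)
    g- = (1 − g∞)/τg  (open → closed)

and these eight rates are wired onto a seven-state topology with three
layers:

* main layer   C ↔ C' ↔ O          — activation (d-gate rates),
* top layer    If, If'             — fast inactivation (f-gate rates)
  plus calcium-dependent inactivation through the function f(c),
* bottom layer If2, If2'           — slow inactivation (f2-gate rates).

Eleven dimensionless scaling parameters x0..x10 adapt the chain to each
target model: x0, x1 shape the calcium-dependence function

    f(c) = 1 / (1 + (x0·c̄p / c)^(3·x1)),

x2, x3, x4 multiply f on the three calcium edges C→If, C'→If', O→If',
x5/x6 scale the top-layer f-gate rates, x7/x8 the d-gate rates and
x9/x10 the bottom-layer f2-gate rates.  The open-state probability is the
opening fraction: I_CaL = O × Imax with the unchanged driving force.

The wiring is data (a :class:`TransitionTable`), not code, so alternative
topologies can be explored by editing the shipped JSON edge list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit
from scipy.linalg import null_space

from . import gate_models as gm
from .gate_models import (
    CellModelSpec, ConfigurationError, gate_rates,
    _d_gate, _f_gate, _f2_gate, _base_rhs, _driving_force, _y_gate_rhs,
)

__all__ = [
    "MC_STATES",
    "X_BOUNDS",
    "CBAR_P_DEFAULT",
    "MCParameterSet",
    "TransitionEdge",
    "TransitionTable",
    "default_transition_table",
    "hh_gate_to_rates",
    "f_ca",
    "build_generator",
    "mc_rhs",
    "stationary_distribution",
    "assemble_hybrid",
]

MC_STATES = ("C", "Cp", "O", "If", "Ifp", "If2", "If2p")
OPEN_STATE = MC_STATES.index("O")

X_BOUNDS = (0.1, 5.9)        # the DE search box for every x_i
N_PARAMS = 11

# Reference calcium constant of f(c) (mM).  Set to the half-inactivation
# subspace calcium of the target models' own calcium gate (fcass), the scale
# at which their calcium-dependent inactivation actually operates; with
# x0 ∈ [0.1, 5.9] the fitted midpoint spans 0.005-0.3 mM.  Fixed, never
# fitted; config-exposed.
CBAR_P_DEFAULT = 0.05

RATE_KINDS = ("d+", "d-", "f+", "f-", "f2+", "f2-", "ca")
_KIND_INDEX = {k: i for i, k in enumerate(RATE_KINDS)}
SCALE_NAMES = tuple(f"x{i}" for i in range(N_PARAMS)) + ("1",)

F_FORMS = ("hill3x", "hill3_pow")  # exponent 3·x1 vs outer power x1


class ModelDefinitionError(ValueError):
    """The transition table produced an invalid (negative) rate."""


# ----------------------------------------------------------------------
# Elementary conversions
# ----------------------------------------------------------------------

def hh_gate_to_rates(g_inf, tau):
    """Convert an HH gate (g∞, τ) into the rate pair (g+, g−).

    g+ = g∞/τ drives C→O of the two-state gate chain, g− = (1−g∞)/τ the
    reverse; the pair preserves g∞ = g+/(g+ + g−) and τ = 1/(g+ + g−).
    """
    g_inf = np.asarray(g_inf, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    if np.any(g_inf < 0) or np.any(g_inf > 1):
        raise ValueError("g_inf must lie in [0, 1]")
    g_plus = g_inf / tau
    g_minus = (1.0 - g_inf) / tau
    if g_plus.ndim == 0:
        return float(g_plus), float(g_minus)
    return g_plus, g_minus


def f_ca(c, x0: float, x1: float, cbar_p: float = CBAR_P_DEFAULT,
         form: str = "hill3x"):
    """Calcium-dependence function f(c) ∈ (0, 1), increasing in c.

    ``hill3x`` (default): f = 1/(1 + (x0·c̄p/c)^(3·x1)), which reduces to
    the classical Hill-3 form at x0 = x1 = 1.  ``hill3_pow`` applies x1 as
    an outer power instead: f = 1/(1 + (x0·c̄p/c)^3)^x1.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("calcium concentration must be positive "
                         "(SCI mode must freeze a positive value, never 0)")
    if x0 <= 0 or x1 <= 0 or cbar_p <= 0:
        raise ValueError("x0, x1 and cbar_p must be positive")
    ratio = x0 * cbar_p / c
    with np.errstate(over="ignore"):
        if form == "hill3x":
            out = 1.0 / (1.0 + ratio ** (3.0 * x1))
        elif form == "hill3_pow":
            out = 1.0 / (1.0 + ratio ** 3.0) ** x1
        else:
            raise ConfigurationError(f"unknown f(c) form {form!r}")
    return float(out) if out.ndim == 0 else out


# ----------------------------------------------------------------------
# Parameters and wiring
# ----------------------------------------------------------------------

@dataclass
class MCParameterSet:
    """The 11 fitted scaling parameters plus fixed constants.

    ``enforce_bounds`` applies the DE search box [0.1, 5.9]; manual
    exploration may relax it.
    """

    x: np.ndarray
    cbar_p: float = CBAR_P_DEFAULT
    f_form: str = "hill3x"
    enforce_bounds: bool = False

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        if self.x.shape != (N_PARAMS,):
            raise ValueError(f"expected {N_PARAMS} parameters, got {self.x.shape}")
        if self.f_form not in F_FORMS:
            raise ConfigurationError(f"unknown f(c) form {self.f_form!r}")
        if self.enforce_bounds and (np.any(self.x < X_BOUNDS[0])
                                    or np.any(self.x > X_BOUNDS[1])):
            raise ValueError(f"parameters outside the search box {X_BOUNDS}")

    @classmethod
    def ones(cls, **kw) -> "MCParameterSet":
        return cls(np.ones(N_PARAMS), **kw)

    def to_dict(self) -> dict:
        d = {f"x{i}": float(v) for i, v in enumerate(self.x)}
        d["cbar_p"] = self.cbar_p
        d["f_form"] = self.f_form
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MCParameterSet":
        x = np.array([d[f"x{i}"] for i in range(N_PARAMS)], dtype=float)
        return cls(x, cbar_p=d.get("cbar_p", CBAR_P_DEFAULT),
                   f_form=d.get("f_form", "hill3x"))


@dataclass(frozen=True)
class TransitionEdge:
    from_state: str
    to_state: str
    rate_kind: str       # one of RATE_KINDS
    scale_name: str      # "x0".."x10" or "1"

    def __post_init__(self):
        if self.from_state not in MC_STATES or self.to_state not in MC_STATES:
            raise ConfigurationError(f"unknown state in edge {self}")
        if self.rate_kind not in RATE_KINDS:
            raise ConfigurationError(f"unknown rate kind {self.rate_kind!r}")
        if self.scale_name not in SCALE_NAMES:
            raise ConfigurationError(f"unknown scale {self.scale_name!r}")


@dataclass
class TransitionTable:
    """Edge list of the seven-state chain."""

    edges: tuple

    def __post_init__(self):
        self.edges = tuple(e if isinstance(e, TransitionEdge)
                           else TransitionEdge(**e) for e in self.edges)

    def __len__(self) -> int:
        return len(self.edges)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            [{"from": e.from_state, "to": e.to_state,
              "rate_kind": e.rate_kind, "scale_name": e.scale_name}
             for e in self.edges], indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path) -> "TransitionTable":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        raw = json.loads(text)
        return cls(tuple(TransitionEdge(r["from"], r["to"], r["rate_kind"],
                                        r["scale_name"]) for r in raw))

    def packed(self) -> np.ndarray:
        """(n_edges, 4) float array: from, to, kind, scale index (11 = one)."""
        out = np.empty((len(self.edges), 4))
        for i, e in enumerate(self.edges):
            out[i] = (MC_STATES.index(e.from_state), MC_STATES.index(e.to_state),
                      _KIND_INDEX[e.rate_kind],
                      N_PARAMS if e.scale_name == "1"
                      else int(e.scale_name[1:]))
        return out


_DEFAULT_TABLE_PATH = Path(__file__).parent / "data" / "transition_table.json"


def default_transition_table() -> TransitionTable:
    """The shipped wiring of the seven-state chain (three-layer topology)."""
    if _DEFAULT_TABLE_PATH.exists():
        return TransitionTable.from_json(_DEFAULT_TABLE_PATH)
    return TransitionTable(_DEFAULT_EDGES)


def _e(a, b, kind, scale):
    return TransitionEdge(a, b, kind, scale)


_DEFAULT_EDGES = (
    # main layer: two-step activation on d-gate rates
    _e("C", "Cp", "d+", "x7"), _e("Cp", "C", "d-", "x8"),
    _e("Cp", "O", "d+", "x7"), _e("O", "Cp", "d-", "x8"),
    # within-layer transitions mirror the main layer (d-gate rates)
    _e("If", "Ifp", "d+", "x7"), _e("Ifp", "If", "d-", "x8"),
    _e("If2", "If2p", "d+", "x7"), _e("If2p", "If2", "d-", "x8"),
    # top layer: f-gate inactivation/recovery
    _e("C", "If", "f-", "x6"), _e("If", "C", "f+", "x5"),
    _e("Cp", "Ifp", "f-", "x6"), _e("Ifp", "Cp", "f+", "x5"),
    _e("O", "Ifp", "f-", "x6"), _e("Ifp", "O", "f+", "x5"),
    # calcium-dependent inactivation edges (rate = x_i · f(c))
    _e("C", "If", "ca", "x2"),
    _e("Cp", "Ifp", "ca", "x3"),
    _e("O", "Ifp", "ca", "x4"),
    # bottom layer: f2-gate inactivation/recovery
    _e("C", "If2", "f2-", "x10"), _e("If2", "C", "f2+", "x9"),
    _e("Cp", "If2p", "f2-", "x10"), _e("If2p", "Cp", "f2+", "x9"),
    _e("O", "If2p", "f2-", "x10"), _e("If2p", "O", "f2+", "x9"),
)


# ----------------------------------------------------------------------
# Generator assembly (reference Python path)
# ----------------------------------------------------------------------

def _elementary_rates(model_id: str, v: float):
    """The six voltage-dependent rates (d±, f±, f2±) at voltage v (1/ms)."""
    rates = {}
    for gate, kinds in (("d", ("d+", "d-")), ("f", ("f+", "f-")),
                        ("f2", ("f2+", "f2-"))):
        g_inf, tau = gate_rates(model_id, gate, v)
        gp, gmn = hh_gate_to_rates(g_inf, tau)
        rates[kinds[0]] = gp
        rates[kinds[1]] = gmn
    return rates


def build_generator(v: float, c: float, params: MCParameterSet,
                    table: TransitionTable | None = None,
                    model_id: str = "TP") -> np.ndarray:
    """7×7 generator matrix Q (1/ms) at fixed voltage and calcium.

    Columns sum to zero (probability conservation); d(occupancy)/dt = Q·p.
    """
    if table is None:
        table = default_transition_table()
    rates = _elementary_rates(model_id, v)
    rates["ca"] = f_ca(c, params.x[0], params.x[1], params.cbar_p,
                       params.f_form)
    q = np.zeros((7, 7))
    for e in table.edges:
        scale = 1.0 if e.scale_name == "1" else params.x[int(e.scale_name[1:])]
        rate = scale * rates[e.rate_kind]
        if rate < 0:
            raise ModelDefinitionError(
                f"negative rate on edge {e.from_state}->{e.to_state}")
        i, j = MC_STATES.index(e.from_state), MC_STATES.index(e.to_state)
        q[j, i] += rate
        q[i, i] -= rate
    return q


def mc_rhs(occupancy, v: float, c: float, params: MCParameterSet,
           table: TransitionTable | None = None,
           model_id: str = "TP") -> np.ndarray:
    """d(occupancy)/dt = Q(v, c)·p; derivatives sum to zero."""
    p = np.asarray(occupancy, dtype=float)
    if p.shape != (7,):
        raise ValueError("occupancy must have 7 entries")
    if np.any(p < -1e-6) or np.any(p > 1 + 1e-6) or abs(p.sum() - 1) > 1e-6:
        raise ValueError("occupancy violates probability constraints")
    return build_generator(v, c, params, table, model_id) @ p


def stationary_distribution(v: float, c: float, params: MCParameterSet,
                            table: TransitionTable | None = None,
                            model_id: str = "TP") -> np.ndarray:
    """Stationary occupancy at fixed (v, c): the null space of Q."""
    q = build_generator(v, c, params, table, model_id)
    ns = null_space(q)
    if ns.shape[1] != 1:
        raise ModelDefinitionError("generator null space is not 1-dimensional")
    p = ns[:, 0]
    p = p / p.sum()
    if np.any(p < -1e-10):
        raise ModelDefinitionError("stationary distribution has negative mass")
    return np.clip(p, 0.0, None) / np.clip(p, 0.0, None).sum()


# ----------------------------------------------------------------------
# Hybrid cell models (numba kernels)
# ----------------------------------------------------------------------
# params packing: [x0..x10, cbar_p, f_form_flag, (from,to,kind,scale)*n]

def _pack_params(params: MCParameterSet, table: TransitionTable) -> np.ndarray:
    head = np.concatenate([params.x, [params.cbar_p],
                           [float(F_FORMS.index(params.f_form))]])
    return np.concatenate([head, table.packed().ravel()])


@njit(cache=True)
def _f_ca_scalar(c, x0, x1, cbar_p, form_flag):
    ratio = x0 * cbar_p / c
    if form_flag == 0.0:
        return 1.0 / (1.0 + ratio ** (3.0 * x1))
    return 1.0 / (1.0 + ratio ** 3.0) ** x1


@njit(cache=True)
def _mc_block(y, dy, base_n, v, c_eff, params, st_model):
    """Add the Markov-chain occupancy derivatives to dy[base_n:base_n+7]."""
    d_inf, tau_d = _d_gate(v)
    f_inf, tau_f = _f_gate(v)
    f2_inf, tau_f2 = _f2_gate(v)
    kinds = np.empty(7)
    kinds[0] = d_inf / tau_d
    kinds[1] = (1.0 - d_inf) / tau_d
    kinds[2] = f_inf / tau_f
    kinds[3] = (1.0 - f_inf) / tau_f
    kinds[4] = f2_inf / tau_f2
    kinds[5] = (1.0 - f2_inf) / tau_f2
    kinds[6] = _f_ca_scalar(c_eff, params[0], params[1], params[11], params[12])
    n_edges = (params.shape[0] - 13) // 4
    for k in range(n_edges):
        off = 13 + 4 * k
        i = int(params[off])
        j = int(params[off + 1])
        kind = int(params[off + 2])
        sidx = int(params[off + 3])
        scale = 1.0 if sidx >= 11 else params[sidx]
        flux = scale * kinds[kind] * y[base_n + i]
        dy[base_n + i] -= flux
        dy[base_n + j] += flux


@njit(cache=True)
def _tp_mc_kernel(y, t, i_stim, sci_arg, params):
    dy = np.zeros(22)
    v, css = y[0], y[5]
    o = y[15 + 2]
    i_cal = o * _driving_force(v, css)
    _base_rhs(y, dy, i_cal, i_stim, False, 0.0)
    c_eff = sci_arg if sci_arg > 0.0 else css
    _mc_block(y, dy, 15, v, c_eff, params, False)
    return dy


@njit(cache=True)
def _st_mc_kernel(y, t, i_stim, sci_arg, params):
    dy = np.zeros(23)
    v, css = y[0], y[5]
    yg = y[15]
    o = y[16 + 2]
    i_cal = o * _driving_force(v, css)
    _base_rhs(y, dy, i_cal, i_stim, True, yg)
    dy[15] = _y_gate_rhs(v, yg)
    c_eff = sci_arg if sci_arg > 0.0 else css
    _mc_block(y, dy, 16, v, c_eff, params, True)
    return dy


def assemble_hybrid(model_id: str, params: MCParameterSet,
                    table: TransitionTable | None = None) -> CellModelSpec:
    """Hybrid cell model: the gate block replaced by the 7-state chain.

    The four gate ODEs are removed and seven occupancy ODEs appended;
    I_CaL = O × Imax with the original conductance and driving force, and
    the calcium argument of f(c) is the subspace calcium css.  Initial
    occupancy is the stationary distribution at the model's initial
    (V, css), so pre-pacing transients wash out during conditioning beats.
    """
    model_id = str(model_id).upper()
    if table is None:
        table = default_transition_table()
    base = gm.build_gate_model(model_id)
    n_drop = 4
    base_names = base.state_names[:-n_drop]
    base_init = base.initial_state[:-n_drop]
    v0 = base_init[0]
    css0 = base.initial_state[base.index("CaSS")]
    occ0 = stationary_distribution(v0, css0, params, table, model_id)
    kernel = _tp_mc_kernel if model_id == "TP" else _st_mc_kernel
    return CellModelSpec(
        model_id=model_id,
        variant="mc",
        state_names=tuple(base_names) + MC_STATES,
        initial_state=np.concatenate([base_init, occ0]),
        rhs_kernel=kernel,
        params=_pack_params(params, table),
        open_index=len(base_names) + OPEN_STATE,
    )
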