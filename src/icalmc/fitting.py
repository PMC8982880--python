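"""Ensemble calibration of the Markov-chain parameters.

The objective is the relative error between the hybrid model's I_CaL trace
and the gate-based model's trace over the final paced beat (the fitness
window, [10 s, 11 s] at the default 1 Hz × 11 pulses):

    F(x) = sqrt( Σ (I_MC(x,t) − I_HH(t))²  /  Σ I_HH(t)² )

(the ``relative_L2`` mode — a well-defined percentage that is robust where
the diastolic current is near zero).  A ``literal_per_sample`` mode sums
per-sample relative squared errors with an epsilon floor on the
denominator instead.

Calibration is Differential Evolution (rand/1/exp, weight 0.8, crossover
0.9) over the 11-dimensional box [0.1, 5.9]^11, initialized by Latin
hypercube sampling.  Every objective evaluation — not just survivors — is
archived with its generation, so a pop × generations run yields exactly
pop·generations archived individuals for ensemble selection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .markov_ical import (MCParameterSet, TransitionTable, X_BOUNDS,
                          N_PARAMS, assemble_hybrid, default_transition_table)
from .simulate import (ProtocolSpec, IntegratorSettings, Trace, run_protocol,
                       extract_window, generate_target)

__all__ = [
    "FitnessConfig",
    "Individual",
    "Archive",
    "WORST_FITNESS",
    "fitness_F",
    "overall_fitness",
    "latin_hypercube_init",
    "differential_evolution",
    "evaluate_archive",
    "MCFitnessEvaluator",
]

log = logging.getLogger("icalmc.fitting")

WORST_FITNESS = 1e9   # recorded when a parameter set fails to simulate


class DegenerateTargetError(ValueError):
    """The target trace is identically zero."""


@dataclass(frozen=True)
class FitnessConfig:
    """How Eq-style trace errors are computed."""

    window: tuple = (10000.0, 11000.0)   # ms
    mode: str = "relative_L2"            # or "literal_per_sample"
    epsilon_floor: float = 0.01          # fraction of peak |target|

    def __post_init__(self):
        if self.mode not in ("relative_L2", "literal_per_sample"):
            raise ValueError(f"unknown fitness mode {self.mode!r}")


def fitness_F(trace_mc: Trace, trace_target: Trace,
              config: FitnessConfig = FitnessConfig()) -> float:
    """Relative I_CaL error F between a candidate and the target trace.

    Both traces must already be on the same sampling grid over the window.
    Returns a fraction (0.09 ≡ 9%); 0 iff the traces are identical.
    """
    if len(trace_mc) != len(trace_target) or not np.allclose(
            trace_mc.times - trace_mc.times[0],
            trace_target.times - trace_target.times[0], atol=1e-9):
        raise ValueError("traces must share one sampling grid")
    i_mc = trace_mc.ICaL
    i_t = trace_target.ICaL
    peak = np.max(np.abs(i_t))
    if peak == 0:
        raise DegenerateTargetError("target I_CaL is identically zero")
    diff2 = (i_mc - i_t) ** 2
    if config.mode == "relative_L2":
        return float(np.sqrt(diff2.sum() / (i_t ** 2).sum()))
    floor = (config.epsilon_floor * peak) ** 2
    denom = np.maximum(i_t ** 2, floor)
    return float((diff2 / denom).sum())


def overall_fitness(f_full: float, f_sci: float) -> float:
    """Combined two-protocol error OF = sqrt(F_full² + F_sci²)."""
    if f_full < 0 or f_sci < 0:
        raise ValueError("fitness components must be non-negative")
    return float(np.hypot(f_full, f_sci))


def latin_hypercube_init(n: int, bounds=None, seed: int | None = None) -> np.ndarray:
    """n stratified samples of the search box (one per stratum per axis)."""
    if bounds is None:
        bounds = [X_BOUNDS] * N_PARAMS
    bounds = np.asarray(bounds, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=bounds.shape[0], seed=seed)
    unit = sampler.random(n)
    return qmc.scale(unit, bounds[:, 0], bounds[:, 1])


@dataclass
class Individual:
    """One parameter set with its fitness bookkeeping."""

    x: np.ndarray
    F_full: float | None = None
    F_sci: float | None = None
    generation: int = 0
    eval_id: int = 0

    @property
    def OF(self) -> float | None:
        if self.F_full is None or self.F_sci is None:
            return None
        return overall_fitness(self.F_full, self.F_sci)

    def params(self, **kw) -> MCParameterSet:
        return MCParameterSet(self.x.copy(), **kw)


@dataclass
class Archive:
    """Every objective evaluation of one DE run, plus run metadata."""

    individuals: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.individuals)

    def best(self, key: str = "F_full") -> Individual:
        vals = [getattr(ind, key) for ind in self.individuals]
        return self.individuals[int(np.argmin(
            [np.inf if v is None else v for v in vals]))]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ind in self.individuals:
            row = {"eval_id": ind.eval_id, "generation": ind.generation}
            row.update({f"x{i}": ind.x[i] for i in range(N_PARAMS)})
            row["F_full"] = np.nan if ind.F_full is None else ind.F_full
            row["F_sci"] = np.nan if ind.F_sci is None else ind.F_sci
            row["OF"] = np.nan if ind.OF is None else ind.OF
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.17g")
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(self.meta, indent=1, sort_keys=True, default=str))

    @classmethod
    def from_csv(cls, path) -> "Archive":
        path = Path(path)
        df = pd.read_csv(path, float_precision="round_trip")
        meta = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        inds = []
        for _, r in df.iterrows():
            inds.append(Individual(
                x=np.array([r[f"x{i}"] for i in range(N_PARAMS)]),
                F_full=None if np.isnan(r["F_full"]) else float(r["F_full"]),
                F_sci=None if np.isnan(r["F_sci"]) else float(r["F_sci"]),
                generation=int(r["generation"]), eval_id=int(r["eval_id"])))
        return cls(inds, meta)


def _safe_eval(objective, x) -> float:
    try:
        f = float(objective(x))
        if not np.isfinite(f):
            raise ValueError("non-finite fitness")
        return f
    except Exception as exc:  # noqa: BLE001 - a bad individual must not kill the run
        log.warning("objective failed at x=%s: %s", np.round(x, 3), exc)
        return WORST_FITNESS


def differential_evolution(objective, bounds=None, pop_size: int = 100,
                           generations: int = 50, seed: int = 0,
                           weight: float = 0.8, crossover: float = 0.9,
                           stop_at: float | None = None,
                           fitness_key: str = "F_full") -> Archive:
    """DE/rand/1/exp over a box, archiving every evaluation.

    Generation 1 is the Latin-hypercube initial population; each subsequent
    generation evaluates exactly ``pop_size`` trial vectors (clipped to the
    box), so a completed run archives pop_size × generations individuals.
    ``stop_at`` ends the run after the first generation whose best fitness
    reaches the threshold (best-so-far fitness is non-increasing, so later
    generations cannot change whether the threshold was reached).
    """
    if pop_size < 5:
        raise ValueError("pop_size must be >= 5")
    if bounds is None:
        bounds = [X_BOUNDS] * N_PARAMS
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    d = bounds.shape[0]
    rng = np.random.default_rng(seed)

    archive = Archive(meta={
        "pop_size": pop_size, "generations": generations, "seed": seed,
        "weight": weight, "crossover": crossover, "strategy": "rand/1/exp",
        "bounds": bounds.tolist(), "stop_at": stop_at,
        "fitness_key": fitness_key,
    })

    def record(x, f, gen):
        ind = Individual(x=x.copy(), generation=gen,
                         eval_id=len(archive.individuals))
        setattr(ind, fitness_key, f)
        archive.individuals.append(ind)

    pop = latin_hypercube_init(pop_size, bounds, seed=seed)
    fit = np.empty(pop_size)
    for i in range(pop_size):
        fit[i] = _safe_eval(objective, pop[i])
        record(pop[i], fit[i], 1)

    for gen in range(2, generations + 1):
        if stop_at is not None and fit.min() <= stop_at:
            break
        for i in range(pop_size):
            r1, r2, r3 = _pick_three(rng, pop_size, i)
            mutant = np.clip(pop[r1] + weight * (pop[r2] - pop[r3]), lo, hi)
            trial = pop[i].copy()
            j = int(rng.integers(d))
            length = 1
            while length < d and rng.random() < crossover:
                length += 1
            for k in range(length):
                trial[(j + k) % d] = mutant[(j + k) % d]
            f_trial = _safe_eval(objective, trial)
            record(trial, f_trial, gen)
            if f_trial <= fit[i]:
                pop[i] = trial
                fit[i] = f_trial

    archive.meta["best_fitness"] = float(fit.min())
    archive.meta["completed_generations"] = archive.individuals[-1].generation
    return archive


def _pick_three(rng, n, exclude):
    idx = []
    while len(idx) < 3:
        c = int(rng.integers(n))
        if c != exclude and c not in idx:
            idx.append(c)
    return idx


# ----------------------------------------------------------------------
# The simulation-backed objective
# ----------------------------------------------------------------------

class MCFitnessEvaluator:
    """F(x) for the hybrid model against a gate-based target trace."""

    def __init__(self, model_id: str, protocol: ProtocolSpec = ProtocolSpec(),
                 settings: IntegratorSettings = IntegratorSettings(),
                 fitness: FitnessConfig | None = None,
                 table: TransitionTable | None = None,
                 target: Trace | None = None, cache_dir=None,
                 cbar_p: float | None = None, f_form: str = "hill3x"):
        self.model_id = str(model_id).upper()
        self.protocol = protocol
        self.settings = settings
        self.table = table if table is not None else default_transition_table()
        self.fitness = fitness or FitnessConfig(window=protocol.last_pulse_window())
        self.target = target if target is not None else generate_target(
            self.model_id, protocol, settings, cache_dir=cache_dir)
        self.param_kw = {"f_form": f_form}
        if cbar_p is not None:
            self.param_kw["cbar_p"] = cbar_p

    def simulate(self, x) -> Trace:
        params = MCParameterSet(np.asarray(x, dtype=float), **self.param_kw)
        model = assemble_hybrid(self.model_id, params, self.table)
        trace = run_protocol(model, self.protocol, self.settings)
        return extract_window(trace, *self.fitness.window)

    def __call__(self, x) -> float:
        return fitness_F(self.simulate(x), self.target, self.fitness)


def evaluate_archive(archive: Archive, evaluator, key: str = "F_sci") -> Archive:
    """Fill in the fitness under another protocol for every individual.

    ``evaluator`` maps a parameter vector to a fitness value; failures are
    recorded as the worst possible fitness rather than aborting.
    """
    for ind in archive.individuals:
        setattr(ind, key, _safe_eval(evaluator, ind.x))
    archive.meta[f"evaluated_{key}"] = True
    return archive
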