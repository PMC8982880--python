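"""Population-of-models analysis of the calibration archive.

After a DE run, the archive of all evaluations is distilled into a
*population of solutions*: either the best n by the single-protocol error F
(the study-level default is the best 300 of 5000, equivalent to a ~16%
tolerance), a fitness threshold, or the best n by the two-protocol overall
fitness OF.  This module also provides the trace biomarkers used to judge
populations (APD50/APD90 measured from the action-potential peak, and the
calcium transient extrema, reported in μM), the MAPE summary of a
population against the reference model, descriptive parameter statistics,
a Pareto front over (F_full, F_sci), and variance-based Sobol sensitivity
of any objective over the parameter box.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .fitting import Archive, Individual, overall_fitness
from .markov_ical import N_PARAMS, X_BOUNDS
from .simulate import Trace

__all__ = [
    "Population",
    "BiomarkerSet",
    "SobolResult",
    "select_population",
    "pareto_front",
    "apd",
    "calcium_features",
    "biomarkers",
    "mape",
    "parameter_stats",
    "sobol_indices",
    "elbow_index",
]

log = logging.getLogger("icalmc.ensemble")

SELECTION_CRITERIA = ("top_n_by_F", "top_n_by_OF", "threshold_F")


class UnrepolarizedBeatError(RuntimeError):
    """The action potential never crossed the repolarization level."""


@dataclass
class Population:
    """A selected subset of an archive, sorted by the selection value."""

    members: list
    selection_criterion: str
    n: int | None = None
    threshold: float | None = None
    source: str = ""

    def __len__(self) -> int:
        return len(self.members)

    def parameter_matrix(self) -> np.ndarray:
        return np.array([m.x for m in self.members])


def _criterion_value(ind: Individual, criterion: str) -> float:
    if criterion == "top_n_by_OF":
        v = ind.OF
    else:
        v = ind.F_full
    return np.inf if v is None else float(v)


def select_population(archive: Archive, criterion: str = "top_n_by_F",
                      n: int | None = 300,
                      threshold: float | None = None) -> Population:
    """Tolerance- or rank-based selection of the population of solutions.

    Ties are broken by eval_id so selection is deterministic; asking for
    more members than the archive holds returns the whole archive with a
    warning.
    """
    if criterion not in SELECTION_CRITERIA:
        raise ValueError(f"unknown selection criterion {criterion!r}")
    key = lambda ind: (_criterion_value(ind, criterion), ind.eval_id)
    ordered = sorted(archive.individuals, key=key)
    if criterion == "threshold_F":
        if threshold is None:
            raise ValueError("threshold_F selection needs a threshold")
        members = [i for i in ordered
                   if _criterion_value(i, criterion) <= threshold]
    else:
        if n is None:
            raise ValueError(f"{criterion} selection needs n")
        if n > len(ordered):
            log.warning("requested %d members from an archive of %d; "
                        "returning all", n, len(ordered))
            n = len(ordered)
        members = ordered[:n]
    return Population(members, criterion, n=n, threshold=threshold,
                      source=str(archive.meta.get("seed", "")))


def pareto_front(points) -> np.ndarray:
    """Non-dominated subset of points in (F_full, F_sci) (minimization).

    A point is kept iff no other point is ≤ in both coordinates and < in
    at least one.  Returns the kept points sorted by the first coordinate.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (n, 2) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    kept = []
    best_y = np.inf
    for idx in order:
        y = pts[idx, 1]
        if y < best_y:
            kept.append(idx)
            best_y = y
    return pts[sorted(kept, key=lambda i: (pts[i, 0], pts[i, 1]))]


def apd(trace: Trace, decay_fraction: float) -> float:
    """Action-potential duration from the AP peak to a decay fraction (ms).

    The repolarization level is V_peak − decay_fraction·(V_peak − V_dia),
    where V_dia is the pre-stimulus diastolic voltage (the first sample of
    the analyzed beat window); the crossing is linearly interpolated.
    """
    if not 0 < decay_fraction < 1:
        raise ValueError("decay_fraction must be in (0, 1)")
    t, v = trace.times, trace.V
    v_dia = v[0]
    i_peak = int(np.argmax(v))
    v_peak = v[i_peak]
    level = v_peak - decay_fraction * (v_peak - v_dia)
    below = np.nonzero(v[i_peak:] < level)[0]
    if below.size == 0:
        raise UnrepolarizedBeatError(
            f"no {decay_fraction:.0%} repolarization before the window end")
    i = i_peak + int(below[0])
    t_cross = t[i - 1] + (level - v[i - 1]) * (t[i] - t[i - 1]) / (v[i] - v[i - 1])
    return float(t_cross - t[i_peak])


def calcium_features(trace: Trace) -> tuple[float, float]:
    """([Ca]i min, [Ca]i peak) over the window, in μM."""
    return float(trace.Cai.min() * 1000.0), float(trace.Cai.max() * 1000.0)


@dataclass(frozen=True)
class BiomarkerSet:
    """AP and calcium-transient features of one analyzed beat."""

    APD50: float   # ms
    APD90: float   # ms
    CaiMin: float  # μM
    CaiPeak: float # μM

    def __post_init__(self):
        if not (0 < self.APD50 <= self.APD90):
            raise ValueError("requires 0 < APD50 <= APD90")
        if not (0 < self.CaiMin <= self.CaiPeak):
            raise ValueError("requires 0 < CaiMin <= CaiPeak")

    def as_dict(self) -> dict:
        return {"APD50": self.APD50, "APD90": self.APD90,
                "CaiMin": self.CaiMin, "CaiPeak": self.CaiPeak}


def biomarkers(trace: Trace) -> BiomarkerSet:
    """All four biomarkers of one beat window."""
    lo, hi = calcium_features(trace)
    return BiomarkerSet(APD50=apd(trace, 0.5), APD90=apd(trace, 0.9),
                        CaiMin=lo, CaiPeak=hi)


def mape(population_features, reference_feature: float) -> float:
    """Mean absolute percentage error of a population feature (%).

    MAPE = (100/n) Σ |feature_x − feature_ref| / feature_ref.
    """
    vals = np.asarray(population_features, dtype=float)
    if vals.size == 0:
        raise ValueError("population is empty")
    if reference_feature == 0:
        raise ValueError("reference feature must be nonzero")
    return float(100.0 * np.mean(np.abs(vals - reference_feature)
                                 / abs(reference_feature)))


def parameter_stats(population: Population,
                    quantiles=(0.25, 0.5, 0.75)) -> pd.DataFrame:
    """Descriptive statistics of each fitted parameter across a population."""
    if len(population) == 0:
        raise ValueError("population is empty")
    x = population.parameter_matrix()
    rows = {}
    rows["min"] = x.min(axis=0)
    rows["max"] = x.max(axis=0)
    rows["mean"] = x.mean(axis=0)
    rows["sd"] = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    for q in quantiles:
        rows[f"q{int(q * 100)}"] = np.quantile(x, q, axis=0)
    return pd.DataFrame(rows, index=[f"x{i}" for i in range(x.shape[1])])


def elbow_index(sorted_values) -> int:
    """Max-distance-to-chord elbow of an ascending fitness curve.

    Optional diagnostic for choosing a population size: the index of the
    point farthest from the straight line joining the first and last
    sorted fitness values.
    """
    v = np.asarray(sorted_values, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("need at least 3 sorted values")
    x = np.arange(v.size, dtype=float)
    x0, y0, x1, y1 = 0.0, v[0], float(v.size - 1), v[-1]
    # distance of each point to the chord
    num = np.abs((y1 - y0) * x - (x1 - x0) * v + x1 * y0 - y1 * x0)
    return int(np.argmax(num / np.hypot(y1 - y0, x1 - x0)))


# ----------------------------------------------------------------------
# Sobol sensitivity (Saltelli sampling, Jansen estimators)
# ----------------------------------------------------------------------

@dataclass
class SobolResult:
    """First- and total-order variance-based sensitivity indices."""

    first_order: np.ndarray
    total_order: np.ndarray
    n_samples: int
    seed: int
    estimator: str = "saltelli-jansen"
    n_rejected: int = 0

    def __post_init__(self):
        self.first_order = np.asarray(self.first_order, dtype=float)
        self.total_order = np.asarray(self.total_order, dtype=float)


def sobol_indices(objective, bounds=None, n_samples: int = 1024,
                  seed: int = 0, max_reject_fraction: float = 0.01) -> SobolResult:
    """Sobol indices of ``objective`` over a box (Saltelli scheme).

    Uses a scrambled Sobol' sequence for the two base matrices A and B and
    the d cross matrices AB_i; the total cost is n_samples·(d + 2)
    evaluations.  First-order indices use the Saltelli 2010 estimator,
    total-order the Jansen estimator.  Failing evaluations reject the whole
    sample row; more than ``max_reject_fraction`` rejected rows aborts.
    """
    if bounds is None:
        bounds = [X_BOUNDS] * N_PARAMS
    bounds = np.asarray(bounds, dtype=float)
    d = bounds.shape[0]
    sampler = qmc.Sobol(d=2 * d, scramble=True, seed=seed)
    base = sampler.random(n_samples)
    a = qmc.scale(base[:, :d], bounds[:, 0], bounds[:, 1])
    b = qmc.scale(base[:, d:], bounds[:, 0], bounds[:, 1])

    def eval_rows(x):
        out = np.empty(x.shape[0])
        for i, row in enumerate(x):
            try:
                out[i] = float(objective(row))
            except Exception as exc:  # noqa: BLE001 - rejected row, not fatal
                log.warning("sobol objective failed: %s", exc)
                out[i] = np.nan
        return out

    f_a = eval_rows(a)
    f_b = eval_rows(b)
    f_ab = np.empty((d, n_samples))
    for i in range(d):
        ab = a.copy()
        ab[:, i] = b[:, i]
        f_ab[i] = eval_rows(ab)

    ok = np.isfinite(f_a) & np.isfinite(f_b) & np.all(np.isfinite(f_ab), axis=0)
    n_rej = int(n_samples - ok.sum())
    if n_rej > max_reject_fraction * n_samples:
        raise RuntimeError(f"{n_rej}/{n_samples} sample rows rejected")
    f_a, f_b, f_ab = f_a[ok], f_b[ok], f_ab[:, ok]

    var = np.var(np.concatenate([f_a, f_b]), ddof=0)
    if var == 0:
        raise ValueError("objective variance is zero over the box")
    first = np.array([np.mean(f_b * (f_ab[i] - f_a)) / var for i in range(d)])
    total = np.array([0.5 * np.mean((f_a - f_ab[i]) ** 2) / var
                      for i in range(d)])
    return SobolResult(first, total, n_samples=n_samples, seed=seed,
                       n_rejected=n_rej)
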