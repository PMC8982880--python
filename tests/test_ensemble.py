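"""Population selection, biomarkers and sensitivity tests."""

import numpy as np
import pytest

from icalmc.ensemble import (
    BiomarkerSet, Population, UnrepolarizedBeatError, apd, biomarkers,
    calcium_features, elbow_index, mape, parameter_stats, pareto_front,
    select_population, sobol_indices,
)
from icalmc.fitting import Archive, Individual
from icalmc.markov_ical import N_PARAMS
from icalmc.simulate import Trace

RNG = np.random.default_rng(7)


def _archive(f_values, f_sci=None):
    inds = []
    for k, f in enumerate(f_values):
        ind = Individual(x=RNG.uniform(0.1, 5.9, N_PARAMS), F_full=float(f),
                         generation=1 + k // 10, eval_id=k)
        if f_sci is not None:
            ind.F_sci = float(f_sci[k])
        inds.append(ind)
    return Archive(inds, {"seed": 0})


# ----------------------------------------------------------------------
# Selection
# ----------------------------------------------------------------------

def test_selection_matches_sort_oracle():
    f = RNG.uniform(0.05, 2.0, 500)
    arch = _archive(f)
    pop = select_population(arch, "top_n_by_F", n=30)
    oracle = np.sort(f)[:30]
    np.testing.assert_allclose(sorted(m.F_full for m in pop.members), oracle)
    # worst selected member defines the effective tolerance
    assert max(m.F_full for m in pop.members) == pytest.approx(oracle[-1])


def test_selection_identity_and_overflow():
    arch = _archive(RNG.uniform(0, 1, 50))
    assert len(select_population(arch, "top_n_by_F", n=50)) == 50
    assert len(select_population(arch, "top_n_by_F", n=999)) == 50


def test_threshold_selection():
    f = np.linspace(0.0, 1.0, 101)
    pop = select_population(_archive(f), "threshold_F", threshold=0.16)
    assert len(pop) == 17
    assert all(m.F_full <= 0.16 for m in pop.members)


def test_selection_tie_break_deterministic():
    arch = _archive(np.zeros(20))
    pop = select_population(arch, "top_n_by_F", n=5)
    assert [m.eval_id for m in pop.members] == [0, 1, 2, 3, 4]


def test_of_reranking_orders_by_overall_fitness():
    f_full = np.array([0.09, 0.15, 0.30])
    f_sci = np.array([0.40, 0.10, 0.05])
    pop = select_population(_archive(f_full, f_sci), "top_n_by_OF", n=3)
    ofs = [m.OF for m in pop.members]
    assert ofs == sorted(ofs)
    assert pop.members[0].F_full == pytest.approx(0.15)


def test_best_overall_dominates_best_full_on_sci():
    """The Pareto logic of re-ranking: min-OF trades F_full for F_sci."""
    f_full = RNG.uniform(0.05, 0.5, 300)
    f_sci = np.clip(0.4 - 0.5 * f_full + RNG.normal(0, 0.05, 300), 0.01, None)
    arch = _archive(f_full, f_sci)
    best_f = select_population(arch, "top_n_by_F", n=1).members[0]
    best_of = select_population(arch, "top_n_by_OF", n=1).members[0]
    assert best_of.F_sci <= best_f.F_sci
    assert best_of.F_full >= best_f.F_full


# ----------------------------------------------------------------------
# Pareto front
# ----------------------------------------------------------------------

def _pareto_oracle(pts):
    keep = []
    for i, p in enumerate(pts):
        dominated = False
        for j, q in enumerate(pts):
            if i != j and q[0] <= p[0] and q[1] <= p[1] and (
                    q[0] < p[0] or q[1] < p[1]):
                dominated = True
                break
        if not dominated:
            keep.append(p)
    return np.unique(np.array(keep), axis=0)


def test_pareto_examples():
    pts = np.array([[1, 2], [2, 1], [2, 2]])
    np.testing.assert_array_equal(pareto_front(pts), [[1, 2], [2, 1]])
    np.testing.assert_array_equal(pareto_front([[3.0, 4.0]]), [[3.0, 4.0]])


def test_pareto_matches_brute_force_oracle():
    for trial in range(5):
        pts = RNG.uniform(0, 1, size=(200, 2))
        front = np.unique(pareto_front(pts), axis=0)
        np.testing.assert_allclose(front, _pareto_oracle(pts))


# ----------------------------------------------------------------------
# Biomarkers
# ----------------------------------------------------------------------

def _triangle_beat():
    """Rest −80 mV, instantaneous peak +40, linear decay over 300 ms."""
    t = np.arange(0.0, 500.0, 0.1)
    v = np.full_like(t, -80.0)
    decay = (t >= 1.0) & (t < 301.0)
    v[decay] = 40.0 - (t[decay] - 1.0) * 120.0 / 300.0
    v[t < 1.0] = -80.0
    v[np.searchsorted(t, 1.0)] = 40.0
    cai = np.full_like(t, 1e-4)
    return Trace(t, v, cai, cai, np.zeros_like(t), np.zeros_like(t))


def test_apd_linear_geometry():
    beat = _triangle_beat()
    assert apd(beat, 0.5) == pytest.approx(150.0, abs=0.2)
    assert apd(beat, 0.9) == pytest.approx(270.0, abs=0.2)


def test_apd_refinement_invariance(tp_full_beat):
    """APD is grid-converged: 5x coarser sampling moves it < 0.2 ms."""
    coarse = Trace(tp_full_beat.times[::5], tp_full_beat.V[::5],
                   tp_full_beat.Cai[::5], tp_full_beat.css[::5],
                   tp_full_beat.ICaL[::5], tp_full_beat.O[::5])
    assert abs(apd(coarse, 0.9) - apd(tp_full_beat, 0.9)) < 0.2


def test_apd_unrepolarized_beat_raises():
    t = np.arange(0.0, 100.0, 0.1)
    v = np.where(t < 1.0, -80.0, 40.0)
    tr = Trace(t, v, np.full_like(t, 1e-4), np.full_like(t, 1e-4),
               np.zeros_like(t), np.zeros_like(t))
    with pytest.raises(UnrepolarizedBeatError):
        apd(tr, 0.9)


def test_calcium_features_constant_trace():
    t = np.arange(0.0, 10.0, 0.1)
    tr = Trace(t, np.zeros_like(t), np.full_like(t, 1e-4),
               np.full_like(t, 1e-4), np.zeros_like(t), np.zeros_like(t))
    assert calcium_features(tr) == (pytest.approx(0.1), pytest.approx(0.1))


def test_calcium_features_match_dense_scan(tp_full_beat):
    lo, hi = calcium_features(tp_full_beat)
    assert lo == pytest.approx(min(c for c in tp_full_beat.Cai) * 1000)
    assert hi == pytest.approx(max(c for c in tp_full_beat.Cai) * 1000)


def test_biomarker_set_invariants(tp_full_beat):
    bm = biomarkers(tp_full_beat)
    assert 0 < bm.APD50 <= bm.APD90
    assert 0 < bm.CaiMin <= bm.CaiPeak
    with pytest.raises(ValueError):
        BiomarkerSet(APD50=300, APD90=250, CaiMin=0.1, CaiPeak=0.8)


# ----------------------------------------------------------------------
# MAPE and parameter statistics
# ----------------------------------------------------------------------

def test_mape_examples_and_oracle():
    assert mape([2.0, 2.0, 2.0], 2.0) == 0.0
    assert mape([2.0, 4.0], 2.0) == pytest.approx(50.0)
    vals = RNG.uniform(0.5, 2.0, 100)
    ref = 1.3
    direct = 100.0 * sum(abs(v - ref) / ref for v in vals) / len(vals)
    assert mape(vals, ref) == pytest.approx(direct, abs=1e-12)
    with pytest.raises(ValueError):
        mape(vals, 0.0)


def test_parameter_stats_against_direct_recomputation():
    arch = _archive(RNG.uniform(0, 1, 40))
    pop = select_population(arch, "top_n_by_F", n=40)
    stats = parameter_stats(pop)
    x = pop.parameter_matrix()
    np.testing.assert_allclose(stats["mean"], x.mean(axis=0))
    np.testing.assert_allclose(stats["sd"], x.std(axis=0, ddof=1))
    np.testing.assert_allclose(stats["min"], x.min(axis=0))
    assert np.all(stats["min"] >= 0.1) and np.all(stats["max"] <= 5.9)


def test_parameter_stats_constant_population():
    ind = Individual(x=np.full(N_PARAMS, 2.0), F_full=0.1, eval_id=0)
    pop = Population([ind, ind, ind], "top_n_by_F")
    assert np.all(parameter_stats(pop)["sd"] == 0.0)


def test_elbow_detector_on_piecewise_curve():
    linear = np.linspace(0.0, 1.0, 50)
    expo = 1.0 + np.expm1(np.linspace(0, 4, 30))
    idx = elbow_index(np.concatenate([linear, expo]))
    assert 40 <= idx <= 65  # near the junction


# ----------------------------------------------------------------------
# Sobol sensitivity (analytic oracles)
# ----------------------------------------------------------------------

def test_sobol_single_factor_model():
    res = sobol_indices(lambda x: x[0], bounds=[(0, 1)] * 4,
                        n_samples=1024, seed=1)
    assert res.first_order[0] == pytest.approx(1.0, abs=0.05)
    np.testing.assert_allclose(res.first_order[1:], 0.0, atol=0.05)
    np.testing.assert_allclose(res.total_order[1:], 0.0, atol=0.05)


def test_sobol_linear_variance_split():
    # Y = X1 + 2 X2 on the unit box: S1:S2 = 1:4, no interactions
    res = sobol_indices(lambda x: x[0] + 2.0 * x[1], bounds=[(0, 1)] * 2,
                        n_samples=2048, seed=2)
    assert res.first_order[0] == pytest.approx(0.2, abs=0.05)
    assert res.first_order[1] == pytest.approx(0.8, abs=0.05)
    np.testing.assert_allclose(res.total_order, res.first_order, atol=0.05)


def test_sobol_ishigami_closed_form():
    a, b = 7.0, 0.1

    def ishigami(x):
        return (np.sin(x[0]) + a * np.sin(x[1]) ** 2
                + b * x[2] ** 4 * np.sin(x[0]))

    # closed-form variance decomposition
    v1 = 0.5 * (1 + b * np.pi ** 4 / 5) ** 2
    v2 = a ** 2 / 8
    v13 = b ** 2 * np.pi ** 8 * 8 / 225
    var = v1 + v2 + v13
    res = sobol_indices(ishigami, bounds=[(-np.pi, np.pi)] * 3,
                        n_samples=4096, seed=3)
    assert res.first_order[0] == pytest.approx(v1 / var, abs=0.05)
    assert res.first_order[1] == pytest.approx(v2 / var, abs=0.05)
    assert res.first_order[2] == pytest.approx(0.0, abs=0.05)
    assert res.total_order[0] == pytest.approx((v1 + v13) / var, abs=0.05)
    assert res.total_order[1] == pytest.approx(v2 / var, abs=0.05)
    assert res.total_order[2] == pytest.approx(v13 / var, abs=0.05)


def test_sobol_totals_dominate_firsts():
    def model(x):
        return x[0] * x[1] + x[2]

    res = sobol_indices(model, bounds=[(0, 1)] * 3, n_samples=1024, seed=4)
    assert np.all(res.total_order >= res.first_order - 0.05)
    assert np.all(res.first_order > -0.05) and np.all(res.first_order < 1.05)


def test_sobol_rejects_on_failure_rate():
    def flaky(x):
        if x[0] > 0.3:
            raise RuntimeError("boom")
        return x[0]

    with pytest.raises(RuntimeError):
        sobol_indices(flaky, bounds=[(0, 1)] * 2, n_samples=256, seed=5)


def test_sobol_deterministic_given_seed():
    f = lambda x: x[0] ** 2 + x[1]
    a = sobol_indices(f, bounds=[(0, 1)] * 2, n_samples=256, seed=6)
    b = sobol_indices(f, bounds=[(0, 1)] * 2, n_samples=256, seed=6)
    np.testing.assert_array_equal(a.first_order, b.first_order)
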