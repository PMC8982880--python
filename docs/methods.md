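# Methods

## Scope

`icalmc` studies whether a Markov-chain (MC) description of the L-type
calcium channel can stand in for the Hodgkin–Huxley (HH) gate product of
two human cardiac cell models — the ten Tusscher–Panfilov epicardial
ventricular model (TP) and the Stewart et al. Purkinje model (ST) — and
whether an *ensemble* of MC parameter sets is more robust than the single
best fit when the data-generating protocol changes. There is no external
data anywhere: the gate-based models themselves generate every target
trace.

## The cell models

Both models are transcribed in full (19 states for TP, 20 for ST; the ST
extras are the funny-current gate y and an algebraic sustained outward
current). They share the calcium subsystem (SR release/uptake/leak,
subspace diffusion, rapid-buffering approximation), the sodium gates and
the I_CaL formulation

    I_CaL = d·f·f2·fcass × Imax(V, css),

with Imax the Goldman-type driving force; its removable singularity at
V = 15 mV is evaluated by series expansion. Where the literature carries
two printed variants of the τ_f/τ_f2 time constants (journal text vs the
authors' distributed source code), the code variants are used for both
models: they reproduce the reference final-beat biomarkers of the ST model
to better than 1%, while the journal variants miss its APD50 by >10%.

Units are ms, mV, mM and A/F internally; calcium biomarkers are reported
in μM.

### Initial states and conditioning

ST ships with its published full-precision state vector, which needs no
conditioning. The TP model's widely circulated "steady-state" vector is
rounded to 2–3 significant digits and is not a fixed point of the paced
equations: from it, APD90 still drifts by ~5 ms over hundreds of beats.
The package therefore ships, as the TP default, the state reached after
100 conditioning beats at 1 Hz from the model's original resting state
(stored at full precision; the resting vector remains available as
`TP_RESTING_STATE`). This conditioned state reproduces the reference
final-beat biomarkers of both protocols within 2% (APD) and 5% (calcium);
longer conditioning slowly trades APD accuracy against calcium-transient
amplitude through the model's intrinsic Na⁺/K⁺ drift, which is a property
of the TP model itself, not of the integrator.

## The Markov chain

Each HH gate g (steady state g∞, time constant τ) converts exactly into a
two-state chain with rates g+ = g∞/τ (closed→open) and g− = (1 − g∞)/τ:
the two-state occupancy ODE *is* the gate ODE, which anchors the
construction. Seven states are arranged in three layers:

    If  ↔ If′        top (fast, f-gate + calcium inactivation)
    C   ↔ C′  ↔  O   main (activation, d-gate)
    If2 ↔ If2′       bottom (slow, f2-gate inactivation)

Edges and their scaling parameters (the shipped
`data/transition_table.json`):

* main-layer and within-layer horizontal transitions use the d-gate rates,
  d+ scaled by x7, d− by x8;
* vertical top-layer edges use the f-gate rates: inactivation f− × x6 on
  C→If, C′→If′, O→If′; recovery f+ × x5 on the reverse edges;
* three additional calcium edges carry rate x_i · f(c): C→If (x2),
  C′→If′ (x3), O→If′ (x4);
* vertical bottom-layer edges mirror the top with f2-rates, f2− × x10 and
  f2+ × x9.

The wiring is data, not code: the chain is assembled from a JSON edge list
(from, to, rate kind ∈ {d±, f±, f2±, ca}, scale ∈ {x2..x10, 1}), so
alternative topologies are a file edit. The generator matrix has
non-negative off-diagonals and zero column sums by construction; all seven
occupancies are integrated with no algebraic closure, so conservation
drift (monitored in tests at ≤ 1e−6 over 11 s) is a genuine accuracy
diagnostic rather than an imposed constraint.

### The calcium-dependence function

Calcium inactivation enters through

    f(c) = 1 / (1 + (x0·c̄p / c)^(3·x1)),      c = css,

increasing in c, with Hill midpoint x0·c̄p. Two readings of the printed
exponent are possible; the adopted one makes x1 a steepness multiplier of
a Hill-3 law (the alternative outer-power reading is available via
`f_form="hill3_pow"`). The reference constant c̄p is fixed at 0.05 mM, the
half-inactivation subspace calcium of the target models' own fcass gate —
the scale at which calcium inactivation demonstrably operates in TP/ST
(css spans ~0.0002–1.9 mM over a beat and fcass traverses its whole range).
With a μM-scale constant, as used by rabbit-model chains whose
submembrane-calcium units differ, the fitted midpoint cannot reach this
working range even at the search-box ceiling of x0 and calibration quality
degrades severalfold; c̄p is config-exposed for such experiments.

In hybrid (MC) cell models the four gate ODEs are removed, the seven
occupancy ODEs appended, and I_CaL = O_state × Imax with the original
conductance. Initial occupancy is the stationary distribution (null space
of the generator) at the model's initial (V, css), so chain transients
wash out during the conditioning beats.

## Protocols

A protocol is a square-pulse train: amplitude −52 A/F, duration 1 ms,
default 11 pulses at 1 Hz (all config-exposed). The analysis window is the
final beat, [10 s, 11 s] at the defaults. Two modes:

* **FULL** — the unmodified model;
* **SCI** (suppressed calcium inactivation) — gate models clamp fcass ≡ 1;
  hybrid models evaluate f(c) at a frozen calcium value throughout,
  defaulting to the model's initial diastolic css (the choice that
  mirrors fcass = 1, i.e. minimal calcium inactivation; config-exposed
  because only "constant" is prescribed).

## Calibration and the ensemble

The fitness of a parameter vector is the relative L2 error of its I_CaL
trace against the gate-based target over the window (square root of the
ratio of integrated squared error to integrated squared target). The
printed per-sample relative sum diverges wherever the diastolic target
current crosses zero and does not natively produce a percentage, so it is
retained only as a `literal_per_sample` mode with an epsilon floor
(default 1% of the peak target) for fidelity studies.

Differential Evolution (rand/1/exp, weight 0.8, crossover 0.9 — the cited
optimization library's documented defaults; config-exposed) searches the
box [0.1, 5.9]^11 from a Latin-hypercube initial population. Every
objective evaluation is archived with its generation (generation 1 = the
initial population), so pop × generations evaluations are available for
selection; a failed simulation scores the worst possible fitness instead
of aborting the run. Fixed seed ⇒ bit-identical archives. An optional
early-stop threshold ends a run after the first generation whose best
fitness reaches it — best-so-far fitness is non-increasing, so the
threshold verdict is unaffected.

The population of solutions is the best n by F (study-level default
n = 300 out of 100×50 = 5000, equivalent to a ≈16% tolerance), or all
members below a threshold; an elbow detector (max distance to the chord of
the sorted fitness curve) is provided as a diagnostic for choosing n.
Re-evaluating the archive under SCI fills the second error F|SCI, and
re-ranking by OF = sqrt(F²_full + F²_SCI) yields the overall-best ensemble
(the square-root reading is fixed by the reference values it must
reproduce: components of 15% and 10% combine to a printed 18%).

Biomarkers: APD50/APD90 are measured from the AP *peak* to 50%/90% of the
decay toward the pre-stimulus diastolic potential (the window's first
sample), with linear interpolation at the crossing — the baseline choice
is not prescribed beyond "from the AP peak", and pre-stimulus diastole is
the least ambiguous reference. Calcium features are the window extrema of
[Ca]i in μM. Population errors are summarized as MAPE against the
gate-based model's value.

## Sensitivity analysis

Sobol first- and total-order indices of F(x) over the search box use
Saltelli-type sampling on scrambled Sobol' sequences (n·(d+2) evaluations)
with the Saltelli-2010 first-order and Jansen total-order estimators,
validated against closed-form variance decompositions (single-factor,
linear and Ishigami functions) to ±0.05 at base sizes of 1–4k. Because a
full-fidelity analysis needs thousands of 11-s simulations, the CLI
defaults to a surrogate objective — 3 pulses and a 0.5 ms output grid with
the same 0.1 ms integrator cap — with `--full` available for the
calibration objective itself.

## Numerics

* Integrator: LSODA (stiff multistep) with max step 0.1 ms, rtol 1e−6,
  atol 1e−8; each stimulus edge starts a new integration segment so the
  solver never steps across the discontinuity. Halving the max step moves
  the final-beat APD90 by < 0.5 ms.
* Output grid: uniform 0.1 ms, matching the max-step bound, so windowed
  error sums are reproducible; traces are CSV with full float precision
  (`%.17g`, round-trip parsing).
* Right-hand sides are numba-compiled; the first call in a fresh
  environment pays a one-off compilation cost (tens of seconds).
* Degenerate inputs: zero/negative calcium in f(c) is an error (SCI must
  freeze a *positive* value); an all-zero fitness target is an error;
  unrepolarized beats raise rather than returning a truncated APD.
* Ties in population selection break on evaluation id; clipping keeps DE
  proposals inside the box.

## What the tests do and do not show

All targets are synthetic by design (the study is a model-replacement
exercise), so passing tests show that the chain can reproduce the
*models'* currents and downstream physiology under two protocols — they do
not validate the chain against experimental single-channel or whole-cell
recordings, where model discrepancy of a different nature (noise,
cell-to-cell variability, liquid-junction artifacts) would dominate. The
problem sizes exercised by the default test suite are scaled down from the
study level (DE populations of tens, not 100×50; Sobol on analytic
functions and reduced-fidelity objectives), chosen so the full suite runs
on one CPU in minutes; the operations are size-agnostic and the CLI runs
the study-level settings unchanged.

## Known limitations

* The exact published wiring of the seven-state chain is specified in a
  supplement that is not redistributed here; the shipped table is a
  reconstruction constrained by the documented layer/parameter roles and
  by what it must achieve (sub-16% fitness on both targets). Alternative
  wirings can be supplied as JSON without code changes.
* The TP transmural variant is epicardial only (config switch reserved);
  endo/M variants and the rabbit-model chain are out of scope.
* The chain is deterministic (occupancy ODEs); stochastic single-channel
  simulation is out of scope, though the generator assembly is reusable
  for it.
* APD measured from the AP peak is unusual (upstroke-referenced
  definitions are more common); values are not directly comparable to
  APDs reported elsewhere.
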