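# Methods

This note documents the model implemented by `markovcua`, the conventions
chosen where the published description of the original analysis is
ambiguous, and what the accompanying tests do and do not establish.

## 1. Model structure

Two strategies — proton beam therapy (PBT) and three-dimensional conformal
radiotherapy (3D-CRT) as part of definitive chemoradiotherapy for locally
advanced esophageal cancer — are compared with a decision tree whose
branches each run the same Markov cohort model.  The cohort starts fully
in the event-free state ("no late adverse events") and is propagated
through 20 cycles of 3 months (60 months total).

Seventeen health states: event-free; radiation pneumonitis (RP) Grades
1–3; pleural effusion (PE) Grades 1–3; pericardial effusion (PCE) Grades
2–3 (CTCAE has no PCE Grade 1); the overlap states RP1+PE1, RP1+PCE2 and
PCE3+PE2; pericardial drainage and pericardiotomy (one-cycle tunnel
states); resolved PCE; best supportive care (BSC, terminal care); death
(absorbing).

Transition rules are per-cycle probabilities with cycle windows:

* Onset from the event-free state is arm-specific.  RP-family onset
  (including the RP1+PE1 and RP1+PCE2 overlaps) applies in cycles 1–4
  (toxic pneumonitis arises within a year of irradiation); PE- and
  PCE-family onset applies in cycles 1–12 (the parameter table zeroes
  these rows "after the 3rd year").  With these windows and the per-cycle
  reading of the onset probabilities, the model's cumulative Grade 3
  incidences under 3D-CRT are 3.8% (RP), 9.0% (PE) and 15.4% (PCE
  including the overlap) — reproducing the source trial's 4%/9%/16% —
  and 0.5%/0%/1% under PBT.
* Recovery: RP3→RP2 with 0.25/cycle; RP2 persists with 0.25/cycle and
  otherwise improves to RP1 (the persistence row is read literally; the
  alternative reading, a 0.25 improvement probability, is available in
  the convention sweep); PE3→PE2 as a forced one-cycle episode; severe
  PCE (with or without PE2) moves to drainage with 0.1/cycle; drainage
  succeeds into PCE2 with 0.617 and otherwise proceeds to
  pericardiotomy, which always resolves.
* Survival is identical by assumption in both arms: every alive state
  carries a shared 0.0542/cycle hazard of moving to BSC, and BSC ends in
  death after exactly one cycle.  Remaining probability mass stays in
  place.  Forced one-cycle exits (tunnel states, PE3, BSC) are encoded
  as *remainder* rules that absorb whatever mass the other rules leave,
  which keeps every row stochastic under any perturbation of the
  hazard.

## 2. Outcome accrual conventions

The original analysis was built in commercial decision-tree software
whose accrual conventions are not fully published; the following defaults
were fixed by identifying which documented convention combination
reproduces its printed results, and each is exposed as a setting or
covered by `convention_sweep()`.

* **Begin-of-cycle accrual, 0-based discounting.**  The cohort occupying
  state *s* at the start of cycle *k* (stage *k* = 0…19) accrues
  `u(s)·0.25` QALYs and the state's per-cycle cost, discounted by
  `(1+r)^(−k/4)` with *r* = 0.03/year.  An optional half-cycle
  correction replaces stage-*k* occupancy with the average of stages *k*
  and *k+1* (default off).  Mass alive after the final transition stops
  accruing (horizon truncation, no terminal valuation).
* **Upfront costs** (radiotherapy fee + 1,325,370 yen
  admission/chemotherapy) are charged undiscounted at time zero.  The
  PBT fee is 2,375,000 yen (rare-cancer schedule) or 1,600,000 yen
  (non-rare); 3D-CRT costs 727,600 yen.
* **Routine follow-up** (45,615 yen/cycle in year 1, 28,480 thereafter)
  accrues in every alive, non-BSC state — except during stage 0, which
  is the chemoradiotherapy admission already covered by the upfront
  cost (setting `followup_in_first_cycle`), and except in the PE Grade 2
  states, whose published treatment costs (47,165 / 30,030 yen per
  cycle) explicitly include the follow-up fee and replace it.  The RP
  Grade 2 treatment cost (62,160 yen/cycle) stacks on top of follow-up
  (its label does not say "including"); the non-stacking reading is in
  the sweep.
* **Entry costs** — RP3 571,120; PE3 302,700; drainage 448,220;
  pericardiotomy 595,641; BSC 632,100 yen, each one hospitalization
  episode — are charged once per entering cohort fraction, at the
  arrival stage's discount factor.  Staying in a state is not a
  re-entry.
* **Tunnel-state utilities** are not published; drainage and
  pericardiotomy carry the PCE Grade 3 utility 0.63 (the patient remains
  in a decompensated cardiac state during the intervention).
  Alternatives (0.57, 0.32) are in the sweep.

Utility weights: event-free 0.91; RP 0.87/0.83/0.54; PE 0.87/0.76/0.58;
PCE 0.87/0.63; PCE3+PE2 0.57; RP1+PE1, RP1+PCE2 and resolved PCE 0.87;
BSC 0.32; death 0.  Grade ordering within each family (RP, PE, PCE) is a
validated model invariant.

## 3. Incremental analysis

`compare()` reports ΔC, ΔE, the ICER from unrounded deltas (undefined at
ΔE = 0), the net monetary benefit `NMB = wtp·ΔE − ΔC` and a dominance
classification.  The verdict rule is `NMB > 0` at the 7,500,000 yen/QALY
threshold, equivalent to ICER ≤ threshold whenever ΔE > 0.  Because the
fee is charged undiscounted at time zero and never sampled, the two fee
levels satisfy an exact algebra: `ICER(rare) − ICER(non_rare) =
775,000/ΔE`, which the tests check to machine precision.

## 4. Sensitivity analyses

**Parameter registry.**  Sensitivity analyses see the model as a flat
vector of scalars: one per state utility, per cost figure and per literal
transition probability.  Scalars published as a single figure move
jointly (the drainage probability shared by the two severe-PCE states;
the PE Grade 2 cost pair).  Three kinds of scalars are structural and
never perturbed: the radiotherapy fees (fee-schedule prices that define
the scenarios, not uncertain estimates), the shared BSC hazard (the
equal-survival assumption itself), and forced transitions (BSC→death,
remainder rules).  This scoping is what reproduces the published tornado
— nine utilities plus the 3D-CRT severe-PCE onset probability in the top
ten, with pericardial drainage as the most sensitive cost item; with
fees or the hazard included they would displace those entries.

**One-way (tornado).**  Each scalar is set to 0.8× and 1.2× its base;
values leaving the feasible region (utilities or probabilities above 1,
row sums above 1) are clamped to the boundary and flagged, never silently
rescaled.  Entries are ranked by |ICER(high) − ICER(low)| with
lexicographic tie-breaking, which pins the zero-base parameters (e.g. the
PBT severe-PE probability, 0) in a deterministic order.

**Probabilistic (PSA).**  Each scalar with base *b* is drawn from
Triangular(0.8 b, b, 1.2 b); zero stays zero; utilities and probabilities
are clamped at 1.  Utility grade ordering is enforced by redrawing a
violating family (up to 100 attempts) and then falling back to sorting
its drawn values, with the fallback flagged; rows whose drawn
probabilities exceed 1 are redrawn, then proportionally rescaled as a
flagged fallback.  By default each arm is evaluated on its **own
independent draw** of the parameter vector, as if each treatment subtree
carried its own distribution nodes — the construction that reproduces
the published acceptability fractions; `arm_correlation="shared"` applies
one common draw to both arms, in which case only the arm-specific onset
probabilities differ and the incremental-effectiveness spread collapses.
Draw *i* uses substream *i* spawned from the master seed, so extending
`n_draws` never changes earlier draws, and the rare/non-rare runs consume
identical streams (the fee is not sampled), making the non-rare CEAC
dominate the rare CEAC pointwise under a common seed.

**CEAC.**  For each willingness-to-pay *w* on a grid (default 0–20M yen
in 0.5M steps, containing the threshold exactly), the acceptability is
the fraction of draws with positive NMB, which equals the "ICER < w"
fraction whenever all draws gain QALYs.  The curve is guaranteed
monotone only under that premise; with independent per-arm draws a small
fraction of draws lose QALYs and the NMB definition is the meaningful
one.

## 5. Validation oracles

**Microsimulation.**  An individual-level simulator samples whole
trajectories from the same per-cycle matrices and re-derives all accrual
conventions independently of the cohort engine (only the matrix builder
is shared, since matrices are the object under test's input).  Cohort
and microsimulation must agree within Monte Carlo standard error; tests
check both packaged arms and a batch of random models, using a 4-SE
ceiling with ≥95–96% of comparisons within 3 SE because per-cell 3-SE
bands across hundreds of correlated comparisons would flag false alarms
by design.

**Synthetic models.**  `random_model()` generates structurally faithful
random models: graded adverse-event families with monotone utilities
drawn by construction (sorted uniforms), window-limited arm-specific
onset with row sums kept below 1 by scaling, an optional tunnel chain, a
shared terminal-care hazard, and randomized fee-schedule-like costs.  The
generator emulates the *structure* the analysis assumes — it makes no
attempt to mimic esophageal-cancer epidemiology — so green tests on
synthetic models certify the machinery (propagation, accrual, sampling,
I/O round-trips), not the clinical realism of any particular parameter
set.  With no adverse-event states the model reduces to
event-free → BSC → death, whose discounted QALY total has the geometric
closed form `Σ_k 0.25·u·(1−h)^k·(1+r)^(−k/4)`, checked to 1e-10.

## 6. Numerical choices and degenerate inputs

Matrix rows are validated to sum to 1 within 1e-12 and occupancy to 1
within 1e-10.  Row-sum feasibility under perturbation is checked at
window start points only (row sums are piecewise constant in the cycle
and locally maximal at a window start).  A literal row overcommitting a
state (negative stay probability) raises an error naming the state and
cycle.  Models that fail validation are rejected before simulation;
degenerate but simulable models (e.g. all-zero transition rows) can be
run with `check=False`.  ICERs are `None` at ΔE = 0; dominance handles
the axes explicitly.  All monetary values are float yen (integer-valued
in the packaged model); probabilities and utilities are decimal
fractions.

## 7. Problem sizes

The packaged deterministic analyses run a 17-state, 20-cycle cohort
(milliseconds).  PSA defaults to 1000 draws per fee level; the test suite
replicates the at-threshold fraction across 20 seeds of 1000 draws and
cross-validates the cohort engine against 60,000-patient
microsimulations of the packaged model plus 8,000-patient runs on 50
random models.

## 8. Known limitations

* Recurrence, metastasis and second-line therapy are outside the model
  (equal progression assumed), as are capital and facility costs and any
  currency conversion.
* The original software's exact half-cycle handling, cost-attachment
  points and onset windows are unpublished.  The defaults above
  reproduce its printed deterministic results to within ~1.7% (the
  convention sweep quantifies each choice's leverage); residual
  differences of that order should be expected against the original
  tool.
* The per-arm-independent PSA correlation structure is identified from
  the published acceptability fractions, not stated by the source; the
  shared-draw mode is provided for analysts who prefer the conventional
  common-parameter assumption.
* The BSC hazard is time-constant (geometric survival), a deliberate
  simplification of the source trial's survival curve.
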