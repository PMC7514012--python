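# Methods

## Model structure

The state vector holds concentrations (g/cm³; time unit: weeks) of twelve
network species — `M1, M2, Th1, Th2, Th17, Treg, I_alpha (TNF-α), I_12
(IL-12), I_10 (IL-10), I_gamma (IFN-γ), I_2 (IL-2), I_4 (IL-4)` — followed
by three drug compartments `D_alpha, D_12, D_10`.  The order is fixed:
configured species first (in configuration order), drugs last.

Three cytokine rate laws are built in, because they carry the drug
coupling:

* TNF-α: production by M1 and Th1, first-order decay, mass-action
  neutralization −σ_Dα·I_α·D_α.  The antibody obeys
  dD_α/dt = v_M(t) − σ_Dα·I_α·D_α − δ_Dα·D_α: the bound complex is lost
  symmetrically, so in the reduced binding-only system I − D is conserved
  (a structural invariant the tests check numerically).
* IL-12: production by M1 with saturating IL-10 suppression
  v_12M·M1/(1 + I_10/ζ_10); same antibody mechanism (σ_D12, δ_D12).
* IL-10: production by M2 and by Treg modulated by
  [1 + n_2r·I_γ/(ζ_2 + I_2)] — IFN-γ aids, IL-2 interferes.  The
  recombinant drug feeds IL-10 at rate v_D10·D_10 while the drug
  compartment follows dD_10/dt = v_M(t) − δ_D10·D_10.  Note the
  v_D10·D_10 source has no matching sink in D_10; we deliberately keep
  this form and interpret δ_D10 as *total* elimination (conversion plus
  clearance), rather than "fixing" the mass balance.  The IL-10
  production law is the one place where alternative readings of the
  Treg-modulation term are plausible; the built-in law can be replaced
  wholesale through the `replace_builtin` configuration hook if a
  different reading is wanted.

`ζ_2` (the IL-2 half-saturation in the Treg modulation factor) is housed
in the base parameters and is nominal; no external value pins it.

All other species evolve under registry terms from the configuration, in
a four-kind grammar: constant source, linear production k·X, saturating
Hill-type modulation k·X/(ζ + Y), and first-order decay.  Choosing
Y = X gives Michaelis–Menten saturation of a drive; the shipped network
uses this for the cytokine→T-cell drives (IL-12→Th1, IL-4→Th2).  This is
a deliberate structural choice: with saturating drives every production
term is bounded, so the network is globally bounded and no parameter
draw of the synthetic generator can produce runaway positive feedback
(a purely linear Th2↔IL-4 loop, by contrast, diverges once its gain
crosses 1).  IFN-γ antagonizes the Th2 arm through IL-4 production
(term c_4·Th2/(ζ_g4 + I_γ)) rather than on Th2 cells directly — the
same qualitative cross-suppression, kept compatible with the saturating
drive.

Therapy modes: `none`, `anti_tnf`, `anti_il12`, `il10`.  Exactly one mode
is active per simulation; the infusion v_M(t) is routed to that mode's
drug compartment and the other drug compartments see v_M = 0.

## Parameters and provenance

Published numeric values for the base network are not available to this
package, so the shipped set is **nominal** and every configuration value
carries a provenance tag (`nominal | transcribed | user`); transcribed values
can replace nominals in `src/ibdsim/scenarios/healthy.yaml` without code
changes.  The nominal set was designed, once, to satisfy:

* healthy steady state exactly 1.0 in every compartment (rates chosen so
  production balances decay at the unit state) — fold changes then read
  directly as concentrations;
* asymptotic stability with dominant eigenvalue ≈ −0.13/week, i.e. a
  relaxation time of roughly 7 weeks.  This motivates the default
  analysis window starting at week 14: the first ~13 weeks are dominated
  by the initial condition;
* the qualitative four-case disease taxonomy (below).

## The four patient cases and the activity taxonomy

Each case multiplies exactly ten healthy parameters — production rates of
Th1, Th2 and their polarizing cytokines — by factors documented in the
per-case scenario files.  The taxonomy classifies Th1/Th2 *pathway
activity*, not raw cell counts, because elevated Th1 cells and TNF-α are
the hallmark of every disease case and therefore cannot discriminate
between them.  Operationally:

* **Th1 axis = IFN-γ steady state** vs healthy (the pathway's effector
  cytokine; in the Th1-low cases the IFN-γ production coefficient g_1 is
  impaired while Th1 cells still accumulate);
* **Th2 axis = Th2 cell steady state** vs healthy (IL-4 tracks it in the
  shipped sets).

Shipped patterns (steady-state fold changes under the nominal set):
case 1 — IFN-γ 2.7×, Th2 0.45×, IL-4 0.19×, IL-10 0.61×; case 2 — IFN-γ
0.56×, Th2 2.2×; case 3 — IFN-γ 1.8×, Th2 2.0×, IL-4 2.1×, IL-10 2.0×
(the only case with elevated anti-inflammatory factors); case 4 — IFN-γ
0.71×, Th2 0.49×.  TNF-α and Th1 are 1.6–2.3× in all four.  In the
Th2-high cases IL-4 necessarily rises with Th2; the shipped sets treat
that coupling as part of the case definition.

## Dosing

The standard regimen doses at weeks 0, 2, 4, 8, then every 8 weeks, each
infusion a constant rate over a window.  Window membership is half-open,
[start, start+duration), so boundaries are never double-counted and the
integral of v_M is exactly rate·duration per window.  Window boundaries
are mandatory integrator breakpoints — the solver is restarted at each,
never smoothing the discontinuity.  The nominal magnitude (rate 105
conc/week over 1/7 week ≈ a one-day infusion, i.e. 15 concentration
units per dose; antibody clearance 0.35/week ≈ a two-week half-life) is
calibrated so the targeted cytokine dips below its patient steady state
and into the healthy band under treatment; no published concentration
scale constrains it, and both rate and duration are configuration knobs.

## Numerics

* Integration: LSODA (stiff-capable), rtol 1e-8 / atol 1e-10, sampled on
  a uniform 0.01-week output grid (5001 points for a 50-week run) — the
  same grid the occupancy metric counts on.  Halving the tolerances moves
  occupancies by far less than 0.1 percentage points (tested).
* Non-negativity: integration proceeds in original coordinates; values in
  (−10·atol, 0) are clipped to zero, anything lower raises a diagnostic
  error rather than being silently clipped.
* Steady states: 500-week drug-free burn-in integration followed by a
  MINPACK hybrid (damped quasi-Newton) root solve; accepted only if the
  residual max-norm is ≤ 1e-10 and the state is non-negative.  Only the
  steady state reachable from the given seed is reported; no multiple
  steady-state search is attempted.  Patient-case solves are seeded from
  the healthy steady state, which makes them effectively instantaneous.
* Treatment runs start, by default, from the patient's drug-free steady
  state with drug compartments at zero (`--init steady`); a unit-state
  start (`--init unit`) is also supported since the true initial
  condition of a patient is not observable.

## Metrics

* Healthy interval: lower/upper = healthy ∓ |patient − healthy|/2.
  Membership uses closed bounds with an absolute tolerance of
  1e-9·healthy level, so the degenerate zero-width interval (a
  compartment already at the healthy level) scores 100%, not 0% — the
  metric measures departure from health.
* Occupancy is computed by grid counting (fraction of output-grid points
  inside the band), matching the percentage granularity of the statistic;
  it is stable under grid refinement beyond the 0.01-week step.
* Ratio reports: default pairs {TNF-α, IL-12} × {IL-10, IL-4} plus
  Th1/Th2 and Th1/Treg; "pro" and "anti" group membership is
  configuration, defaulting to pro = {TNF-α, IL-12, IFN-γ, IL-2},
  anti = {IL-10, IL-4}.  Grid points where the denominator is zero are
  excluded and the pair is flagged — a reported gap, never an infinity.

## Synthetic patients

`generate_synthetic_case(taxonomy, seed, spread)` multiplies the case's
ten nominal override factors by independent log-normal noise (median 1,
log-scale s.d. `spread`, default 0.2) and rejection-samples until the
resulting steady state satisfies the taxonomy's sign pattern, with a
budget of 1000 draws (the acceptance rate is itself a useful diagnostic
and is reported on failure).  Draws are deterministic given
(taxonomy, seed, spread).  Rejection sampling was chosen over constrained
optimization for auditability.

What the generator emulates: between-patient heterogeneity of immune
rate constants around a case archetype.  What it does not emulate:
measurement noise, within-patient temporal parameter drift,
pharmacokinetic variability (no body-weight dose scaling, no two-
compartment drug distribution), or comorbidity structure.  Passing tests
therefore demonstrate internal consistency of the machinery and the
qualitative case taxonomy under nominal parameters — not quantitative
agreement with any clinical population.

## Problem sizes

Default runs integrate 15 state variables over 50 weeks (18 solver
segments under the standard schedule, ~5000 output points, well under a
second).  The acceptance script's synthetic check uses 25 draws per
taxonomy; the test suite uses 50, re-simulating each accepted draw.

## Known limitations

* All parameter values are nominal; absolute concentrations and printed
  occupancy percentages are properties of this nominal set, not
  predictions.
* No parameter estimation, no bifurcation/stability analysis beyond the
  local check of the shipped steady states, no stochastic dynamics, no
  spatial (gut-wall) structure, and no claim about which drug is
  clinically superior.
* The Th17 arm is carried as a network species but no Th17-directed
  therapy or Th17-cytokine extension (IL-17/IL-21/IL-22) is modelled.
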