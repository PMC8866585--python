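# Methods

## The rule formalism

A general rule is stored as an ordered decision table: branches of
(guard, output, actions, next-state).  Guards are evaluated in declared
order, but order carries no semantics: if several guards match a domain
point they must agree on the full triple, which `apply_rule` checks at every
evaluation, so a rule is declarative and the single-valuedness requirement
is enforced rather than assumed.  Rules over finite domains carry an
explicit input alphabet, which makes reachability (for the branching check)
and exhaustive enumeration (for the well-definedness scan, capped at 10⁴
domain points) decidable.  Stochastic or multi-valued relations can be
*represented* as explicit tuple lists and are always reported as
not-well-defined; no randomized-rule semantics is implemented.

Distinguishability is an equivalence relation per vehicle axis: a partition
for discrete axes (validated to be a partition, which gives reflexivity,
symmetry and transitivity for free) and a tolerance radius for continuous
axes.  The medium-flexibility check compares rule outputs across equivalent
input pairs: exhaustively for discrete axes, and by 256 seeded sample pairs
per continuous axis, since a continuum cannot be enumerated.  The tolerance
relation on a continuous axis is not transitive; it is used as a
neighbourhood relation, which matches the biological reading ("differences
smaller than δ are not discriminated").

Branch-count complexity uses thresholds trivial < 2 ≤ moderate < 10 ≤
sophisticated.  The thresholds are exposed in configuration
(`COMPLEXITY_THRESHOLDS`) because no canonical values exist; only the
*ordering* is meaningful.

## Heart model

**Time base.**  Stroke-indexed discrete events: after each stroke the clock
advances by 60/HR seconds, with HR computed from the pacemaker hierarchy and
the current internal state.  No membrane-level differential equations are
modelled; the electrical layer is represented at tissue level by the
hierarchy, the conduction delays and the K_ATP rule.

**Bloodstream.**  Each queue slot of a circulation delay line is the reduced
content vector of one ejected blood portion (particle masses + volume).
Compartment transit times are the queue lengths in strokes:
systemic-venous 10, pulmonary 20, coronary and systemic-arterial 10, with a
5 % coronary split of the left output.  Splits and merges are mass-exact,
so with binding and clearance disabled every particle's total mass is
conserved (verified to 1e-9 over 10³ strokes).  The coronary branch buffers
are initialised at their 5 % volume share so that merged portions keep the
baseline 70 mL stroke volume.

**Pacemaker hierarchy.**  The highest-tier functional node paces: SA
(intrinsic 100 bpm), then AV (50 bpm, inside the 40–60 band), then Purkinje
(30 bpm base, 140 bpm when excited).  Only the SA rate is autonomically
modulated:

```
rate = clamp(100 · (1 + age_factor·(1 + 0.1·T4)·(0.4·SNS + 0.5·NE + 0.7·occ)
                  + 0.1·T4 − 0.3·PNS), 20, 220)
```

where `occ` is the bound-epinephrine receptor fraction.  The gains are
defaults chosen so that a resting parasympathetic tone of 1 gives the
textbook 70 bpm resting rate and full receptor occupancy gives the 140 bpm
fight-or-flight ceiling; `age_factor` (the surviving calcium-channel
fraction, decaying 1 %/year under the aging regimen) scales sympathetic
responsiveness, which is how aging habituation blunts the norepinephrine
response.  Electrolyte overrides are applied last (high K⁺ arrests the
heart outright); open K_ATP channels divide the inter-stroke interval by
~1/0.85 and multiply contractile force by 0.8 — faster and weaker
contractions that reduce calcium-overload damage (calcium load 0.4 vs 1.0
in the damage accumulator).

**Frank–Starling curve.**  A piecewise-linear monotone table anchored at
(0,0), (50,30), (100,55), (140,70), (180,79), (220,84) so that the typical
EDV of 140 mL yields the typical SV of 70 mL (EF 0.5).  The sympathetic
shift is multiplicative and capped at EDV.  The failing variant turns
downward above 140 mL.  Anchor shapes are a design choice: the source
relation is qualitative (monotone, saturating) and any such table is
admissible.

**Epinephrine scenario.**  The released venous portion is calibrated to
140 pg/mL.  Receptor occupancy ramps linearly over strokes 40–50 — the
minimal assumption for an unspecified ramp shape — and is gated on hormone
actually delivered to the coronary bed, so a zero-injection control stays
flat at baseline.  After binding begins, circulating epinephrine is cleared
by a per-stroke retention factor of 0.7 (half-life ≈ 2 strokes), reaching
< 1 pg/mL well inside the simulated minute.

**HRV** is the standard deviation of inter-stroke intervals in ms (the
SDNN convention), over the full series by default; the quantity is named
but not defined in standard summaries, and SDNN is the conventional choice.

**Conduction timing.**  Gap = AV delay + ventricular peak offset − atrial
peak offset.  The ventricular offset is only bounded below (>150 ms) by the
physiology; the default 170 ms is the choice that reproduces the canonical
200 ms atrial→ventricular gap with the 100 ms AV delay and 70 ms atrial
offset, and is flagged as a choice.

**Remodeling.**  Modeled as metastable state transitions: the athlete
regimen doubles the exercise stroke-volume reserve so that combined with
the ~2.6× heart-rate reserve the cardiac-output gain reaches ≥ 5 (vs 2–3
from rate alone); infarcts add persistent per-region responsiveness
factors.  Split S2 is a configurable right–left stroke-time offset,
default 0.

## Flytrap model

**Closure counting.**  Required stimulations: 1 (humid, 28–36 °C), 2
(humid, moderate), 3 (dry), counted in a sliding window of 30 s — the
permissive end of the printed 20–30 s band — applied to the dry branch as
well.  Temperature bands: warm [28, 36] °C, moderate [18, 28) °C; outside
these the environment is reported unclassified rather than silently
binned, since no cold-behaviour data are modelled.  Hair identity is logged
but not used: stimulations are counted regardless of which hair bends.
Subthreshold electrical charges accumulate additively without leak (an
optional decay would be a strict extension); the closure threshold is
lower for smaller traps (1.0 / 1.5 / 2.0 charge units for
small/medium/large — direction is physiological, magnitudes are
model units).

**Sealing.**  Sealing requires continued post-closure action potentials.
The default trigger is (≥1 AP ∧ nitrogen sensing) *or* ≥3 APs from
sustained struggling.  The second disjunct is this package's design choice:
with nitrogen sensing alone, a struggling nitrogen-free object (the
robotic-fly thought experiment) could never reach the digestion stage whose
stalling the model is meant to exhibit; sustained mechanical stimulation is
itself the documented driver of tighter closure.  Stones (no movement,
0 APs) still never seal, preserving the energy-conservation rule.  A tiny
prey's escape does consume one of the ~12 lifetime closures (a closure
happened).

**Digestion.**  Stage flags are monotone in AP count with thresholds
2/3/5 and never revert within an episode.  Mass kinetics:
`mass ← mass·(1 − r·E·J)` with r = 0.05 per step, E the released fraction
of the 17-enzyme catalog, J the jasmonic-acid drive in [0,1] (initially
0.5 once JA is active).  Prey-derived potassium or chitin push J up by
0.25 per step (positive feedback); without both, J halves each step and
enzyme release stops once J < 0.05 — the stall.  Masses below 1 µg round
to zero so the loop terminates in finitely many steps; any contracting map
with these monotonicity properties would do.  Phosphatases are assigned the
nucleic-acid substrate class (phosphate esters); the lipid-transfer protein
is the one catalog entry without an acidic pH optimum.  Product allocation
defaults to 70 % retained by the digesting trap, 20 % to other traps and
roots, 10 % respired as CO₂, with the photosynthesis-capacity flag raised
at +5 weeks.

## Synthetic scenario generation

The prey fixtures (stone, organic debris, tiny prey, robotic fly,
nutrient-rich insect) carry the documented composition profiles; the
robotic fly is motile with zero potassium, chitin and nutrients.  Motile
fixtures emit pre-closure hair bends a few seconds apart and post-closure
struggle events from a seeded Poisson process at 0.2 events/s — a rate
chosen as a plausible struggle cadence, since no prey-movement statistics
are documented.  All randomness flows through one `numpy` generator seeded
from the scenario, so identical (scenario, seed) pairs produce
byte-identical logs.

What the generator does *not* emulate: real prey size/mass distributions,
diurnal temperature variation, partial or failed closures, gland-level
spatial heterogeneity, and sensory noise.  Passing tests therefore
demonstrate the correctness of the automaton logic and bookkeeping under
idealised event streams, not predictive fidelity for field data.

## Problem sizes

The shipped scenarios use 60-stroke heart runs (the worked example's one
simulated minute), 10³-stroke conservation checks, and single-trap flytrap
episodes; these sizes exercise every rule while keeping any run to seconds
on one core.

## Known limitations

No ECG synthesis, no membrane ODEs, no vascular pressure model; the rhythm
maxim ("fibrillation begets fibrillation") is carried only as a persistence
flag with no quantitative mechanism; trap closure mechanics (hydraulics,
curvature inversion) and prey attraction are out of scope.  The branching
check treats rules without a finite alphabet as having all branches
reachable, which can overcount for unreachable guards on continuous
domains.
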