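# biocomp

Discrete-event models of **biological computation**: executable *general
rules* over medium-flexible biological vehicles, with two fully worked
physiological reference models — the heart and the Venus flytrap
(*Dionaea muscipula*).

The package is for researchers and students in systems biology and the
foundations of computation who want a concrete, testable formalisation of
what it means for a biological mechanism — not just a nervous system — to
compute.

## The core formalism

A biological computation is a well-defined map

```
g : I × S → O × A × S
```

from inputs `I` (points on a *vehicle*'s axes of variation) and internal
states `S` to computational outputs `O`, physical **action** outputs `A`
(muscle contraction, hormone release, vessel dilation — definite physical
effects that are not Turing-machine effects), and a new internal state.  To
count as nontrivial computation a rule must be:

* **well-defined** — single-valued as a relation (a turbulent-flow "rule"
  fails this);
* **conditionally branching** — at least two reachable branches with
  distinct images; the distinct-branch count is a circuit-complexity
  analogue (molecular switches ≈ gates);
* **medium-flexible** — sensitive only to *biologically distinguishable*
  differences in the vehicle (Na⁺ vs K⁺, which channel proteins can tell
  apart) and insensitive to everything else (the three common potassium
  isotopes, which play the same biological role).

`biocomp.rules` implements the data model and all three checks;
`biocomp.heart` and `biocomp.flytrap` build the two reference models on top
of it; `biocomp.scenario` adds configuration, synthetic prey/stimulus
generation, and logging; `biocomp.cli` is the `biocomp` command.

### The heart

A stroke-indexed simulator: the bloodstream vehicle is the sequence of
per-stroke blood portions, each summarised by a reduced content vector
(masses of tracked particle types + volume).  Circulation compartments are
delay lines measured in strokes.  Control functions include the
SA/AV/Purkinje pacemaker hierarchy (100 / 40–60 / 20–40 bpm, Purkinje
excited ≈140), the Frank–Starling relation `SV = f(EDV)`, autonomic and
hormonal modulation, electrolyte rules, the ischemia-activated K_ATP
channel, AV conduction delay (100 ms, atrial→ventricular peak gap 200 ms),
adenosine coronary dilation, ANP release, and metastable remodeling.

### The flytrap

A counting automaton: 1 / 2 / 3 trigger-hair stimulations (within a ~30 s
window) are required for closure depending on humidity and temperature;
closure onset is 0.1–0.2 s after threshold and completes within 0.5 s; a
trap survives about a dozen closures.  Digestion is staged by action
potentials (jasmonic-acid signalling at 2 APs, enzyme gene expression at 3,
transporter activation at 5), selects suitable enzymes from a 17-enzyme
catalog, and runs a positive feedback loop sustained by prey-derived
potassium and chitin — which is why a robotic fly stalls digestion.

## Worked example

```python
from biocomp.heart import run_epinephrine_scenario

result = run_epinephrine_scenario()
print("epinephrine at stroke 30:", result.left_epinephrine[30], "pg/mL")
print("HR at saturation:", round(result.macro.HR[50]), "bpm")
print("SV at saturation:", result.macro.SV[50], "mL")
```

prints

```
epinephrine at stroke 30: 140.0 pg/mL
HR at saturation: 140 bpm
SV at saturation: 100.0 mL
```

Epinephrine released into the venous return at stroke 0 reaches the right
heart at stroke 10, the left heart at stroke 30 (where the chamber contents
jump from 0 to 140 pg/mL), and the coronary receptors at stroke 40; as
receptor occupancy ramps to saturation at stroke 50, heart rate rises from
the resting ~70 bpm to 140 bpm and stroke volume from 70 to 100 mL, after
which the circulating hormone is cleared back to essentially zero.

From the shell:

```
biocomp heart epinephrine-demo --out out/
biocomp flytrap truth-table
biocomp flytrap run --seed 7 --out out/
```

`biocomp flytrap truth-table` prints the environment × stimulation-count
closure table (1 warm+humid, 2 moderate+humid, 3 dry).

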