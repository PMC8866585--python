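"""Executable general rules over medium-flexible biological vehicles.

A biological computation is modelled here as a *general rule*

    g : I x S -> O x A x S

mapping an input (a point on a vehicle's axes of variation) and an internal
state to a computational output, a list of physical action outputs, and a new
internal state.  To count as a nontrivial computation the rule must be
well-defined (single-valued as a relation), contain conditional branching,
and be *medium-flexible*: sensitive only to biologically distinguishable
differences between vehicle values, insensitive to everything else.

This module provides the data model (:class:`Vehicle`, :class:`GeneralRule`,
:class:`ActionOutput`), the checks that formalise the three criteria above
(:func:`check_well_defined`, :func:`check_conditional_branching`,
:func:`check_medium_flexibility`), the evaluator :func:`apply_rule` and the
event-stream driver :func:`run_system`, plus a few anchoring example rules
(an NMDA-receptor AND gate, pure transport, turbulent flow).
"""

from __future__ import annotations

import csv
import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Any, Callable, Hashable, Iterable, Mapping, Sequence

import numpy as np

# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

#: Branch-count thresholds for the circuit-complexity analogue: a rule with
#: fewer than ``low`` distinct branches is trivial, with at least ``high``
#: sophisticated, in between moderate.  Exposed rather than fixed.
COMPLEXITY_THRESHOLDS: dict[str, int] = {"low": 2, "high": 10}

#: Number of seeded sample pairs per continuous axis used by the
#: medium-flexibility check (exhaustive checking is impossible on continua).
CONTINUOUS_FLEXIBILITY_SAMPLES: int = 256

#: Cap on enumerable domain size for exhaustive checks.
MAX_ENUMERABLE_DOMAIN: int = 10_000


class RuleError(Exception):
    """Base class for rule-engine errors."""


class RuleDomainError(RuleError):
    """No guard of the rule is satisfied at the queried (input, state)."""


class IllDefinedRuleError(RuleError):
    """Two satisfied guards disagree: the relation is not single-valued."""


class UnknownStateError(RuleError):
    """A relation tuple references a state outside the declared state set."""


class UndeclaredDistinguishabilityError(RuleError):
    """A guard reads a vehicle axis with no declared distinguishability."""


class UnorderedStreamError(RuleError):
    """Input-stream timestamps are not strictly increasing."""


# --------------------------------------------------------------------------
# Vehicles and distinguishability
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscreteAxis:
    """A finite axis of variation of a vehicle.

    ``partition`` is the distinguishability relation: a partition of the
    states into biologically indistinguishable classes.  ``None`` means every
    state is its own class (all differences distinguishable).
    """

    states: tuple[Hashable, ...]
    partition: tuple[frozenset, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.states) < 1:
            raise ValueError("axis must have at least one state")
        if self.partition is not None:
            flat = [s for block in self.partition for s in block]
            if len(flat) != len(set(flat)):
                raise ValueError("partition blocks overlap: not an equivalence relation")
            if set(flat) != set(self.states):
                raise ValueError("partition does not cover the axis states")

    def class_of(self, value: Hashable) -> int:
        """Index of the equivalence class containing ``value``."""
        if self.partition is None:
            return self.states.index(value)
        for k, block in enumerate(self.partition):
            if value in block:
                return k
        raise ValueError(f"value {value!r} not on axis")


@dataclass(frozen=True)
class ContinuousAxis:
    """An interval-valued axis; ``tolerance`` is the radius within which two
    values are biologically indistinguishable."""

    low: float
    high: float
    tolerance: float | None = None

    def __post_init__(self) -> None:
        if not (self.low < self.high):
            raise ValueError("continuous axis interval is empty")


Axis = DiscreteAxis | ContinuousAxis


@dataclass
class Vehicle:
    """A biological vehicle: named axes of variation with a declared
    distinguishability relation per axis."""

    name: str
    axes: dict[str, Axis]

    def distinguishability_declared(self, axis: str) -> bool:
        ax = self.axes[axis]
        if isinstance(ax, DiscreteAxis):
            return True  # None partition = discrete (all-singleton) relation
        return ax.tolerance is not None

    def equivalent(self, axis: str, a: Any, b: Any) -> bool:
        ax = self.axes[axis]
        if isinstance(ax, DiscreteAxis):
            return ax.class_of(a) == ax.class_of(b)
        if ax.tolerance is None:
            raise UndeclaredDistinguishabilityError(
                f"undeclared distinguishability on axis {axis!r}"
            )
        return abs(float(a) - float(b)) <= ax.tolerance


# --------------------------------------------------------------------------
# Rules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ActionOutput:
    """A definite physical effect that is not a Turing-machine effect, e.g.
    muscle-contraction, hormone-release or vessel-dilation."""

    kind: str
    magnitude: float
    target: str
    unit: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.magnitude):
            raise ValueError("action magnitude must be finite")


GuardFn = Callable[[Mapping[str, Any], Hashable], bool]


@dataclass(frozen=True)
class TableGuard:
    """Declarative guard: equality/membership conditions per axis, and an
    optional restriction on the internal state."""

    conditions: Mapping[str, tuple]   # axis -> admissible values
    states: tuple | None = None       # None = any state

    def __call__(self, inp: Mapping[str, Any], state: Hashable) -> bool:
        if self.states is not None and state not in self.states:
            return False
        return all(inp[axis] in values for axis, values in self.conditions.items())


@dataclass(frozen=True)
class Branch:
    guard: GuardFn
    output: Hashable
    actions: tuple[ActionOutput, ...]
    next_state: Hashable

    @property
    def image(self) -> tuple:
        return (self.output, self.actions, self.next_state)


@dataclass
class GeneralRule:
    """Decision-table representation of g: I x S -> O x A x S.

    Guards are evaluated in declared order; if several guards match the same
    domain point they must agree on the full (output, actions, next_state)
    triple — this is checked at evaluation time, so the order is
    documentation only.
    """

    name: str
    input_axes: tuple[str, ...]
    states: frozenset
    branches: tuple[Branch, ...]
    #: finite enumeration of input points (dicts axis -> value) for rules on
    #: discrete domains; enables reachability and exhaustive checks.
    input_alphabet: tuple[Mapping[str, Any], ...] | None = None

    def satisfied_branches(self, inp: Mapping[str, Any], state: Hashable) -> list[Branch]:
        return [b for b in self.branches if b.guard(inp, state)]

    # -- serialisation (table guards only) ---------------------------------
    def to_dict(self) -> dict:
        def branch_dict(b: Branch) -> dict:
            if not isinstance(b.guard, TableGuard):
                raise TypeError("only table-guard rules are serialisable")
            return {
                "guard": {
                    "inputs": {k: list(v) for k, v in b.guard.conditions.items()},
                    "states": None if b.guard.states is None else list(b.guard.states),
                },
                "output": b.output,
                "actions": [
                    {"kind": a.kind, "magnitude": a.magnitude, "target": a.target,
                     "unit": a.unit}
                    for a in b.actions
                ],
                "next_state": b.next_state,
            }

        doc = {
            "name": self.name,
            "input_space": list(self.input_axes),
            "state_space": sorted(self.states, key=repr),
            "branches": [branch_dict(b) for b in self.branches],
        }
        if self.input_alphabet is not None:
            doc["input_alphabet"] = [dict(p) for p in self.input_alphabet]
        return doc

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "GeneralRule":
        branches = []
        for bd in d["branches"]:
            g = bd["guard"]
            guard = TableGuard(
                conditions={k: tuple(v) for k, v in g.get("inputs", {}).items()},
                states=None if g.get("states") is None else tuple(g["states"]),
            )
            actions = tuple(
                ActionOutput(a["kind"], float(a["magnitude"]), a["target"],
                             a.get("unit", ""))
                for a in bd.get("actions", [])
            )
            branches.append(Branch(guard, bd["output"], actions, bd["next_state"]))
        alphabet = d.get("input_alphabet")
        if alphabet is None:
            # derive the enumerable domain from the values the guards mention
            values: dict[str, set] = {a: set() for a in d["input_space"]}
            for b in branches:
                for axis, vals in b.guard.conditions.items():  # type: ignore[union-attr]
                    values[axis].update(vals)
            if all(values[a] for a in d["input_space"]):
                alphabet = [dict(zip(d["input_space"], combo))
                            for combo in itertools.product(
                                *(sorted(values[a], key=repr)
                                  for a in d["input_space"]))]
        return cls(
            name=d.get("name", "rule"),
            input_axes=tuple(d["input_space"]),
            states=frozenset(d["state_space"]),
            branches=tuple(branches),
            input_alphabet=None if alphabet is None else tuple(alphabet),
        )


@dataclass
class RuleVerdict:
    """Report container for the computation criteria.  A flag of ``None``
    means the corresponding criterion was not evaluated; counterexamples are
    nonempty iff some evaluated flag is false."""

    well_defined: bool | None = None
    branching: bool | None = None
    branch_count: int = 0
    medium_flexible: bool | None = None
    counterexamples: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(f is not False for f in
                   (self.well_defined, self.branching, self.medium_flexible))


# --------------------------------------------------------------------------
# Core operations
# --------------------------------------------------------------------------

def _freeze(x: Any) -> Hashable:
    """Canonical hashable form of an input point or output payload."""
    if isinstance(x, Mapping):
        return tuple(sorted((k, _freeze(v)) for k, v in x.items()))
    if isinstance(x, (list, tuple)):
        return tuple(_freeze(v) for v in x)
    return x


def apply_rule(rule: GeneralRule, inp: Mapping[str, Any] | Any, state: Hashable
               ) -> tuple[Hashable, tuple[ActionOutput, ...], Hashable]:
    """Evaluate the rule at one domain point.

    Returns the (output, actions, next_state) triple of the satisfied branch.
    Raises :class:`RuleDomainError` if no guard matches and
    :class:`IllDefinedRuleError` if matching guards disagree.
    """
    if not isinstance(inp, Mapping):
        # single-axis convenience: wrap a bare value
        inp = {rule.input_axes[0]: inp}
    matched = rule.satisfied_branches(inp, state)
    if not matched:
        raise RuleDomainError(f"rule undefined at point ({dict(inp)!r}, {state!r})")
    images = {_freeze(b.image) for b in matched}
    if len(images) > 1:
        raise IllDefinedRuleError(
            f"ill-defined rule: disagreeing branches at ({dict(inp)!r}, {state!r})"
        )
    return matched[0].image


RelationTuple = tuple  # (input, state, output, actions, next_state)


def check_well_defined(relation: Sequence[RelationTuple],
                       declared_states: Iterable[Hashable] | None = None
                       ) -> RuleVerdict:
    """Check single-valuedness of a relation given as explicit tuples.

    ``relation`` is a list of (input, state, output, actions, next_state)
    tuples.  The verdict lists every (input, state) that maps to two or more
    distinct triples.
    """
    if not relation:
        raise ValueError("relation is empty")
    declared = None if declared_states is None else set(declared_states)
    seen: dict[Hashable, set] = {}
    points: dict[Hashable, tuple] = {}
    for inp, state, output, actions, next_state in relation:
        if declared is not None and (state not in declared or next_state not in declared):
            raise UnknownStateError(f"unknown state in tuple ({inp!r}, {state!r})")
        key = (_freeze(inp), _freeze(state))
        points[key] = (inp, state)
        seen.setdefault(key, set()).add(_freeze((output, actions, next_state)))
    bad = [points[k] for k, images in seen.items() if len(images) > 1]
    return RuleVerdict(well_defined=not bad, counterexamples=bad)


def rule_to_relation(rule: GeneralRule) -> list[RelationTuple]:
    """Enumerate a finite-domain rule as an explicit relation (every branch
    image at every domain point it covers)."""
    if rule.input_alphabet is None:
        raise ValueError("rule has no finite input alphabet to enumerate")
    rel: list[RelationTuple] = []
    for inp, state in itertools.product(rule.input_alphabet, rule.states):
        for b in rule.satisfied_branches(inp, state):
            rel.append((dict(inp), state, b.output, b.actions, b.next_state))
    return rel


def check_conditional_branching(rule: GeneralRule) -> tuple[bool, int]:
    """Does the rule branch?  Counts reachable branches with distinct
    (output, actions, next_state) images — the molecular-switch analogue of
    gate count in circuit complexity.

    Returns ``(branching, branch_count)`` with ``branch_count = 0`` exactly
    when ``branching`` is false (fewer than two distinct images).
    """
    if rule.input_alphabet is not None:
        reachable: list[Branch] = []
        seen_ids: set[int] = set()
        for inp, state in itertools.product(rule.input_alphabet, rule.states):
            for b in rule.satisfied_branches(inp, state):
                if id(b) not in seen_ids:
                    seen_ids.add(id(b))
                    reachable.append(b)
    else:
        reachable = list(rule.branches)
    images = {_freeze(b.image) for b in reachable}
    if len(images) < 2:
        return (False, 0)
    return (True, len(images))


def classify_complexity(branch_count: int,
                        thresholds: Mapping[str, int] = COMPLEXITY_THRESHOLDS) -> str:
    """Threshold classification of the branch-count complexity measure."""
    if branch_count < thresholds["low"]:
        return "trivial"
    if branch_count >= thresholds["high"]:
        return "sophisticated"
    return "moderate"


def _axes_read(rule: GeneralRule) -> set[str]:
    """Axes a guard may read: table guards declare them; callable guards are
    assumed to read every input axis."""
    read: set[str] = set()
    for b in rule.branches:
        if isinstance(b.guard, TableGuard):
            read |= set(b.guard.conditions)
        else:
            read |= set(rule.input_axes)
    return read


def check_medium_flexibility(rule: GeneralRule, vehicle: Vehicle, *,
                             seed: int = 0,
                             n_samples: int = CONTINUOUS_FLEXIBILITY_SAMPLES
                             ) -> RuleVerdict:
    """Is the rule sensitive only to biologically distinguishable differences?

    For every pair of inputs equivalent under the vehicle's distinguishability
    relation (at the same internal state) the rule must return identical
    triples.  Discrete axes are checked exhaustively over the enumerable
    domain; continuous axes by seeded sampling of equivalent pairs within the
    declared tolerance radius.
    """
    for axis in _axes_read(rule):
        if axis not in vehicle.axes or not vehicle.distinguishability_declared(axis):
            raise UndeclaredDistinguishabilityError(
                f"undeclared distinguishability for axis {axis!r}"
            )

    counterexamples: list = []

    def triple_at(inp: Mapping[str, Any], state: Hashable):
        try:
            return apply_rule(rule, inp, state)
        except RuleDomainError:
            return ("__undefined__",)

    # exhaustive pass over discrete axes
    discrete_axes = [a for a in rule.input_axes
                     if isinstance(vehicle.axes[a], DiscreteAxis)]
    if discrete_axes and all(isinstance(vehicle.axes[a], DiscreteAxis)
                             for a in rule.input_axes):
        points = [dict(zip(rule.input_axes,
                           vals)) for vals in itertools.product(
            *(vehicle.axes[a].states for a in rule.input_axes))]
        if len(points) * max(len(rule.states), 1) <= MAX_ENUMERABLE_DOMAIN:
            for state in rule.states:
                for p, q in itertools.combinations(points, 2):
                    if all(vehicle.equivalent(a, p[a], q[a]) for a in rule.input_axes):
                        if _freeze(triple_at(p, state)) != _freeze(triple_at(q, state)):
                            counterexamples.append(((p, state), (q, state)))

    # sampled pass for continuous axes
    rng = np.random.default_rng(seed)
    cont_axes = [a for a in rule.input_axes
                 if isinstance(vehicle.axes[a], ContinuousAxis)]
    for axis in cont_axes:
        ax: ContinuousAxis = vehicle.axes[axis]  # type: ignore[assignment]
        for _ in range(n_samples):
            point = {}
            for a in rule.input_axes:
                va = vehicle.axes[a]
                if isinstance(va, DiscreteAxis):
                    point[a] = va.states[rng.integers(len(va.states))]
                else:
                    point[a] = float(rng.uniform(va.low, va.high))
            twin = dict(point)
            delta = float(rng.uniform(-ax.tolerance, ax.tolerance))
            twin[axis] = float(np.clip(point[axis] + delta, ax.low, ax.high))
            for state in rule.states:
                if _freeze(triple_at(point, state)) != _freeze(triple_at(twin, state)):
                    counterexamples.append(((point, state), (twin, state)))

    return RuleVerdict(medium_flexible=not counterexamples,
                       counterexamples=counterexamples)


# --------------------------------------------------------------------------
# Running rules over event streams
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceStep:
    time: float
    input: Any
    output: Hashable
    actions: tuple[ActionOutput, ...]
    state: Hashable


def run_system(rule: GeneralRule, initial_state: Hashable,
               input_stream: Sequence[tuple[float, Any]]) -> list[TraceStep]:
    """Fold the rule over a timestamped input stream, threading the internal
    state.  Deterministic given the inputs; times must strictly increase."""
    state = initial_state
    trace: list[TraceStep] = []
    last_t = -math.inf
    for t, inp in input_stream:
        if t <= last_t:
            raise UnorderedStreamError(f"unordered stream at t={t}")
        last_t = t
        output, actions, state = apply_rule(rule, inp, state)
        trace.append(TraceStep(t, inp, output, actions, state))
    return trace


def trace_to_jsonl(trace: Sequence[TraceStep], path) -> None:
    with open(path, "w") as fh:
        for step in trace:
            fh.write(json.dumps({
                "time": step.time,
                "input": step.input,
                "output": step.output,
                "actions": [a.kind for a in step.actions],
                "state": step.state,
            }, default=str) + "\n")


def trace_to_csv(trace: Sequence[TraceStep], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time", "input", "output", "actions", "state"])
        for step in trace:
            w.writerow([step.time, json.dumps(step.input, default=str), step.output,
                        ";".join(a.kind for a in step.actions), step.state])


# --------------------------------------------------------------------------
# Anchoring example rules
# --------------------------------------------------------------------------

def nmda_receptor_rule() -> GeneralRule:
    """NMDA-receptor AND gate: both glycine and glutamate must bind for the
    ion channel to open."""
    axes = ("glycine", "glutamate")
    alphabet = tuple({"glycine": g, "glutamate": u}
                     for g, u in itertools.product((0, 1), repeat=2))
    open_branch = Branch(
        guard=TableGuard({"glycine": (1,), "glutamate": (1,)}),
        output="open",
        actions=(ActionOutput("ion-flux", 1.0, "postsynaptic-membrane"),),
        next_state="open",
    )
    closed_branch = Branch(
        guard=lambda inp, s: inp["glycine"] == 0 or inp["glutamate"] == 0,
        output="closed", actions=(), next_state="closed",
    )
    return GeneralRule("nmda-receptor", axes, frozenset({"open", "closed"}),
                       (open_branch, closed_branch), alphabet)


def identity_rule(alphabet: Sequence[Hashable], states: Iterable[Hashable]
                  ) -> GeneralRule:
    """x -> (x, no actions, unchanged state)."""
    # next state equals the current state; encoded via state-restricted guards
    branches = tuple(
        Branch(TableGuard({"x": (v,)}, states=(s,)), v, (), s)
        for v in alphabet for s in frozenset(states)
    )
    return GeneralRule("identity", ("x",), frozenset(states), branches,
                       tuple({"x": v} for v in alphabet))


def pure_transport_rule(alphabet: Sequence[Hashable]) -> GeneralRule:
    """Pure transport disregarding the vehicle's degrees of freedom: a
    constant rule with no conditional branching — a non-example of
    computation."""
    b = Branch(lambda inp, s: True, "moved", (), "flowing")
    return GeneralRule("pure-transport", ("x",), frozenset({"flowing"}), (b,),
                       tuple({"x": v} for v in alphabet))


def turbulent_flow_relation() -> list[RelationTuple]:
    """A purported rule for turbulent flow: one domain point, two distinct
    outcomes — ill-defined, hence non-computational."""
    return [
        ({"parcel": "p0"}, "flowing", "eddy-left", (), "flowing"),
        ({"parcel": "p0"}, "flowing", "eddy-right", (), "flowing"),
    ]
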