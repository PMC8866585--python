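"""Scenario configuration, synthetic stimulus/prey generation and run logs.

A scenario is a single structured-text (YAML or JSON) document selecting a
model (``heart``, ``flytrap`` or ``rule-check``), its parameter block, a
seed and a duration.  Runs are reproducible: the same (scenario, seed) pair
produces byte-identical logs.  Event logs are JSON-lines validated against
the schema shipped in ``biocomp/schemas/eventlog.schema.json``; per-stroke
series are written as CSV.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path
from typing import Any, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import flytrap as ft
from . import heart as ht
from .rules import check_conditional_branching, check_well_defined, rule_to_relation

# --------------------------------------------------------------------------
# Scenario configuration
# --------------------------------------------------------------------------


class Scenario(BaseModel):
    """Validated scenario document; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    model: Literal["heart", "flytrap", "rule-check"]
    seed: int = 0
    duration: int = 60                    # strokes (heart) or seconds (flytrap)
    parameters: dict[str, Any] = Field(default_factory=dict)
    outputs: dict[str, str] = Field(default_factory=dict)


def load_scenario(path: str | Path) -> Scenario:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return Scenario.model_validate(data)


#: Named presets covering the documented study conditions.
PRESETS: dict[str, dict] = {
    "epinephrine-demo": {"model": "heart", "duration": 60,
                         "parameters": {"scenario": "epinephrine"}},
    "athlete-remodel": {"model": "heart", "duration": 2,
                        "parameters": {"scenario": "athlete"}},
    "sa-failure": {"model": "heart", "duration": 10,
                   "parameters": {"scenario": "sa-failure"}},
    "trap-truth-table": {"model": "flytrap", "duration": 0,
                         "parameters": {"scenario": "truth-table"}},
    "robotic-fly": {"model": "flytrap", "duration": 600,
                    "parameters": {"scenario": "prey", "fixtures": ["robotic-fly"],
                                   "temperature": 30.0, "humidity": "humid"}},
}


# --------------------------------------------------------------------------
# Synthetic prey / stimulus generation
# --------------------------------------------------------------------------

#: Documented fixture composition profiles (relative mass quantities).
PREY_FIXTURES: dict[str, dict] = {
    "stone": dict(size="fits", motile=False, mass=50.0, digestible=False,
                  composition={}),
    "organic-debris": dict(size="fits", motile=False, mass=5.0, digestible=True,
                           composition={"carbohydrate": 3.0, "protein": 1.0,
                                        "nitrogen": 0.5}),
    "tiny-prey": dict(size="tiny", motile=True, mass=1.0, digestible=True,
                      composition={"chitin": 0.2, "protein": 0.5,
                                   "potassium": 0.1, "nitrogen": 0.2}),
    # The robot triggers closure and, by struggling, even sealing — but it
    # carries neither potassium nor chitin, so the JA feedback loop cannot be
    # sustained and digestion stalls.
    "robotic-fly": dict(size="fits", motile=True, mass=20.0, digestible=False,
                        composition={}),
    "nutrient-insect": dict(size="fits", motile=True, mass=12.0, digestible=True,
                            composition={"chitin": 3.0, "lipid": 2.0,
                                         "protein": 4.0, "nucleic-acid": 1.0,
                                         "carbohydrate": 1.0, "sodium": 0.3,
                                         "potassium": 0.5, "nitrogen": 1.2}),
}

STRUGGLE_RATE_PER_S = 0.2    # Poisson rate of post-closure struggle events


def generate_prey_stream(fixtures: Sequence[str | Mapping[str, Any]], seed: int
                         ) -> list[tuple[ft.PreyObject, list[ft.StimulusEvent]]]:
    """Generate (prey, stimulus-event) pairs for the named fixtures.

    Deterministic under ``seed``.  Motile fixtures produce pre-closure hair
    bends a few seconds apart and post-closure struggle events from a seeded
    Poisson process; still objects produce a single impact bend.
    """
    rng = np.random.default_rng(seed)
    stream: list[tuple[ft.PreyObject, list[ft.StimulusEvent]]] = []
    t0 = 0.0
    for item in fixtures:
        name = item if isinstance(item, str) else item["fixture"]
        if name not in PREY_FIXTURES:
            raise ValueError(f"unknown fixture name {name!r}")
        profile = PREY_FIXTURES[name]
        prey = ft.PreyObject(name=name, **profile)
        events: list[ft.StimulusEvent] = []
        if prey.motile:
            t = t0 + float(rng.uniform(0.5, 2.0))
            for _ in range(6):      # pre-closure bends, a few seconds apart
                events.append(ft.StimulusEvent(round(t, 3), "hair-bend",
                                               hair_id=int(rng.integers(1, 7))))
                t += float(rng.exponential(8.0))
            # post-closure struggles over one minute, Poisson at 0.2/s
            n = int(rng.poisson(STRUGGLE_RATE_PER_S * 60.0))
            for dt in np.sort(rng.uniform(0.0, 60.0, size=max(n, 1))):
                events.append(ft.StimulusEvent(round(t + float(dt), 3),
                                               "hair-bend",
                                               hair_id=int(rng.integers(1, 7))))
        else:
            events.append(ft.StimulusEvent(round(t0 + 1.0, 3), "hair-bend",
                                           hair_id=int(rng.integers(1, 7))))
        t0 = (events[-1].time if events else t0) + 120.0
        stream.append((prey, events))
    return stream


# --------------------------------------------------------------------------
# Event-log schema validation
# --------------------------------------------------------------------------

def _load_schema() -> dict:
    ref = importlib.resources.files("biocomp") / "schemas" / "eventlog.schema.json"
    return json.loads(ref.read_text())


def validate_event_log(records: Sequence[Mapping[str, Any]]) -> None:
    """Validate log records against the published schema (required keys,
    types, enums) and check strict time ordering."""
    schema = _load_schema()
    props = schema["properties"]
    required = schema["required"]
    type_map = {"number": (int, float), "string": str, "object": dict}
    last_t = -np.inf
    for rec in records:
        for key in required:
            if key not in rec:
                raise ValueError(f"log record missing key {key!r}: {rec}")
        for key, field_schema in props.items():
            if key in rec:
                if not isinstance(rec[key], type_map[field_schema["type"]]):
                    raise ValueError(f"log field {key!r} has wrong type in {rec}")
                if "enum" in field_schema and rec[key] not in field_schema["enum"]:
                    raise ValueError(f"log field {key!r} outside enum in {rec}")
        if rec["time"] < last_t:
            raise ValueError("log records out of time order")
        last_t = rec["time"]


# --------------------------------------------------------------------------
# Running scenarios
# --------------------------------------------------------------------------

def _write_jsonl(records: Sequence[Mapping[str, Any]], path: Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def _run_heart(scenario: Scenario, out_dir: Path) -> dict:
    kind = scenario.parameters.get("scenario", "epinephrine")
    events: list[dict] = []
    if kind == "epinephrine":
        cfg = ht.EpinephrineConfig(n_strokes=max(scenario.duration, 2))
        result = ht.run_epinephrine_scenario(cfg)
        frame = result.macro.to_frame()
        frame["epinephrine_pg_mL"] = result.left_epinephrine
        frame["EDV_mL"] = [s.EDV_l for s in result.strokes]
        frame.to_csv(out_dir / "strokes.csv", index=False)
        for s in result.strokes:
            events.append({"time": s.T_l, "source": "heart",
                           "kind": "stroke",
                           "payload": {"index": s.index, "SV_mL": s.SV_l}})
        sat = min(cfg.saturation, len(result.strokes) - 1)
        summary = {
            "HR_at_saturation_bpm": float(result.macro.HR[sat]),
            "SV_at_saturation_mL": float(result.macro.SV[sat]),
            "epinephrine_stroke30_pg_mL": float(result.left_epinephrine[30])
            if len(result.left_epinephrine) > 30 else 0.0,
            "HRV_ms": result.macro.HRV,
        }
    elif kind == "sa-failure":
        nodes = ht.default_nodes(sa=False)
        rate = ht.effective_heart_rate(nodes, ht.HeartInternalState())
        summary = {"escape_rate_bpm": rate}
        events.append({"time": 0.0, "source": "heart", "kind": "sa-failure",
                       "payload": {"escape_rate_bpm": rate}})
    elif kind == "athlete":
        state = ht.remodel(ht.HeartInternalState(),
                           ht.Regimen("athlete", duration=scenario.duration))
        summary = {"co_gain_exercise": ht.cardiac_output_gain(state)}
        events.append({"time": 0.0, "source": "heart", "kind": "remodel",
                       "payload": summary})
    else:
        raise ValueError(f"unknown heart scenario {kind!r}")
    return summary | {"events": events}


def _run_flytrap(scenario: Scenario, out_dir: Path) -> dict:
    kind = scenario.parameters.get("scenario", "prey")
    events: list[dict] = []
    if kind == "truth-table":
        table = flytrap_truth_table()
        table.to_csv(out_dir / "truth_table.csv", index=False)
        return {"truth_table": table.to_dict("records"), "events": events}

    env = ft.TrapEnvironment(
        temperature=float(scenario.parameters.get("temperature", 30.0)),
        humidity=scenario.parameters.get("humidity", "humid"))
    fixtures = scenario.parameters.get("fixtures", ["nutrient-insect"])
    stream = generate_prey_stream(fixtures, scenario.seed)
    outcomes = []
    trap = ft.TrapState()
    for prey, evts in stream:
        if trap.phase is ft.Phase.EXHAUSTED:
            break
        pre = [e for e in evts]
        post: list[ft.StimulusEvent] = []
        for e in pre:
            trap = ft.register_stimulus(trap, e, env)
            if trap.phase is ft.Phase.CLOSING:
                post = [x for x in pre if x.time > e.time]
                trap, onset, done = ft.close_trap(trap, e.time)
                events.append({"time": e.time, "source": "flytrap",
                               "kind": "closure",
                               "payload": {"onset_s": onset, "done_s": done,
                                           "closure_count": trap.closure_count}})
                break
        if trap.phase is not ft.Phase.CLOSED:
            outcomes.append({"prey": prey.name, "outcome": trap.phase.value})
            continue
        trap = ft.escape_or_seal(trap, prey, post)
        if trap.phase is ft.Phase.SEALED:
            d = ft.run_digestion(prey, ap_count=trap.ap_count)
            outcomes.append({"prey": prey.name, "outcome": "digested"
                             if d.prey_mass_remaining == 0 else "stalled",
                             "mass_remaining_mg": d.prey_mass_remaining})
            last_t = post[-1].time if post else 0.0
            events.append({"time": last_t, "source": "flytrap",
                           "kind": "sealed", "payload": {"ap_count": trap.ap_count}})
        else:
            outcomes.append({"prey": prey.name, "outcome": trap.phase.value})
        trap = ft.reopen(trap)
    return {"outcomes": outcomes, "events": events,
            "closure_count": trap.closure_count, "phase": trap.phase.value}


def flytrap_truth_table() -> pd.DataFrame:
    """The environment x stimulation-count closure table (three rows)."""
    rows = [
        {"humidity": "humid", "temperature_C": 32.0},
        {"humidity": "humid", "temperature_C": 22.0},
        {"humidity": "dry", "temperature_C": 22.0},
    ]
    for row in rows:
        env = ft.TrapEnvironment(row["temperature_C"], row["humidity"])
        row["band"] = env.band
        row["required_stimulations"] = ft.required_stimulation_count(env)
    return pd.DataFrame(rows)


def _run_rule_check(scenario: Scenario, out_dir: Path) -> dict:
    from .rules import GeneralRule
    rule_doc = scenario.parameters.get("rule")
    if rule_doc is None:
        raise ValueError("rule-check scenario requires a 'rule' parameter block")
    rule = GeneralRule.from_dict(rule_doc)
    verdict = check_well_defined(rule_to_relation(rule), rule.states)
    branching, count = (check_conditional_branching(rule)
                        if verdict.well_defined else (False, 0))
    return {"well_defined": verdict.well_defined, "branching": branching,
            "branch_count": count, "events": []}


def run_scenario(scenario: Scenario, out_dir: str | Path) -> dict:
    """Run a scenario, writing CSV/JSON-lines logs and a run summary.

    Returns the summary dict (also written to ``summary.json``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runner = {"heart": _run_heart, "flytrap": _run_flytrap,
              "rule-check": _run_rule_check}[scenario.model]
    summary = runner(scenario, out)
    events = summary.pop("events", [])
    events.sort(key=lambda r: r["time"])
    validate_event_log(events)
    _write_jsonl(events, out / "events.jsonl")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
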