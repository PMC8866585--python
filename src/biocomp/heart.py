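"""The heart as a biological computing system.

Stroke-indexed discrete-event model of the cardiovascular loop.  The
bloodstream vehicle is a sequence of per-stroke blood portions; each portion
is summarised by a reduced content vector (masses of tracked particle types
plus a volume) rather than per-particle coordinates.  Compartments of the
circulation are delay lines measured in strokes.  Control is layered:

* internal — the SA/AV/Purkinje pacemaker hierarchy, the Frank–Starling
  relation SV = f(EDV), adenosine-mediated coronary dilation, the
  ischemia-activated K_ATP channel, AV conduction delay;
* external — autonomic tone (sympathetic up, parasympathetic down),
  circulating hormones (norepinephrine, epinephrine, thyroxine) and plasma
  electrolyte categories;
* internal state — metastable remodeling (athlete / aging / infarct scars).

Macrostates (HR, SV, EF, CO, HRV) are derived from the stroke sequence:
HR_i = 60/(T_i - T_{i-1}) bpm, EF = SV/EDV, CO = HR*SV.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .rules import (ActionOutput, Branch, GeneralRule, TableGuard)

# --------------------------------------------------------------------------
# Configuration constants (physiologic defaults)
# --------------------------------------------------------------------------

SA_INTRINSIC_BPM = 100.0          # SA node baseline with no external input
AV_BASE_BPM = 50.0                # within the 40-60 bpm latent band
PURKINJE_BASE_BPM = 30.0          # within the 20-40 bpm band
PURKINJE_EXCITED_BPM = 140.0      # fight-or-flight override rate
RATE_CLAMP = (20.0, 220.0)

K_SNS = 0.4                       # sympathetic tone gain on SA rate
K_PNS = 0.3                       # parasympathetic tone gain (resting tone 1 -> 70 bpm)
K_NE = 0.5                        # norepinephrine gain (per unit dose)
K_THYROXINE = 0.1                 # thyroxine direct rate gain and NE/epi enhancer
K_EPI_RATE = 0.7                  # bound-epinephrine gain: saturation -> 140 bpm
K_EPI_CONTRACTILITY = 3.0 / 7.0   # saturation lifts SV 70 -> 100 mL
K_SNS_CONTRACTILITY = 0.2
K_NE_CONTRACTILITY = 0.25

KATP_INTERVAL_FACTOR = 0.85       # open K_ATP shortens the inter-stroke interval
KATP_FORCE_FACTOR = 0.8           # ... and weakens contraction
KATP_CALCIUM_LOAD = 0.4           # relative Ca load with channels open (vs 1.0)

O2_EXTRACTION_CORONARY = 0.65     # fraction of O2 taken by heart muscle
O2_EXTRACTION_SYSTEMIC = 0.25     # fraction taken by other tissues

AV_DELAY_MS = 100.0
ATRIAL_PEAK_OFFSET_MS = 70.0      # depolarisation -> peak atrial force
VENTRICULAR_PEAK_OFFSET_MS = 170.0  # >150 ms; default reproduces the 200 ms gap

#: Compartment transit delays in strokes: hormone released into the venous
#: return reaches the right heart 10 strokes later, the left heart 30, and
#: the coronary receptors 40.
DEFAULT_DELAYS = {"systemic-venous": 10, "pulmonary": 20,
                  "coronary": 10, "systemic-arterial": 10}
CORONARY_FRACTION = 0.05          # share of left output entering coronary flow

EPI_CLEARANCE_PER_STROKE = 0.7    # retained fraction per stroke once binding starts

ADENOSINE_WORKLOAD_THRESHOLD = 1.0
ANP_STRETCH_THRESHOLD = 1.0

ACTION_CATALOG = frozenset({
    "muscle-contraction", "hormone-release", "vessel-dilation",
    "ion-flux", "natriuresis-signal", "paracrine-antihypertrophy",
})


class HeartError(Exception):
    pass


class AsystoleError(HeartError):
    """No functional pacemaker node remains."""


class CurveDomainError(HeartError):
    pass


class UninitializedCirculationError(HeartError):
    pass


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class ReducedVector:
    """Reduced content vector of one blood portion: mass per tracked particle
    type (entries >= 0) and the portion's volume in mL.  Concentrations are
    the normalised entries."""

    volume: float
    counts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.volume < 0 or any(v < 0 for v in self.counts.values()):
            raise ValueError("reduced-vector entries must be nonnegative")

    def concentration(self, particle: str) -> float:
        if self.volume == 0:
            return 0.0
        return self.counts.get(particle, 0.0) / self.volume

    def split(self, fraction: float) -> tuple["ReducedVector", "ReducedVector"]:
        """Disjoint split into (fraction, 1-fraction) portions; mass-exact."""
        a = ReducedVector(self.volume * fraction,
                          {k: v * fraction for k, v in self.counts.items()})
        b = ReducedVector(self.volume - a.volume,
                          {k: v - a.counts[k] for k, v in self.counts.items()})
        return a, b

    @staticmethod
    def combine(*portions: "ReducedVector") -> "ReducedVector":
        counts: dict[str, float] = {}
        vol = 0.0
        for p in portions:
            vol += p.volume
            for k, v in p.counts.items():
                counts[k] = counts.get(k, 0.0) + v
        return ReducedVector(vol, counts)

    def total_mass(self, particle: str) -> float:
        return self.counts.get(particle, 0.0)


@dataclass
class StrokeRecord:
    """One heartbeat of the bloodstream vehicle."""

    index: int
    T_r: float                # s
    T_l: float
    EDV_r: float              # mL
    EDV_l: float
    SV_r: float
    SV_l: float
    contents_r: ReducedVector
    contents_l: ReducedVector

    def __post_init__(self) -> None:
        for sv, edv in ((self.SV_r, self.EDV_r), (self.SV_l, self.EDV_l)):
            if not (0 <= sv <= edv):
                raise ValueError("stroke volume must lie in (0, EDV]")


@dataclass(frozen=True)
class PacemakerNode:
    tier: str                     # "SA" | "AV" | "Purkinje"
    functional: bool = True
    excited: bool = False         # Purkinje overdrive (fear, caffeine)


def default_nodes(sa: bool = True, av: bool = True, purkinje: bool = True,
                  excited: bool = False) -> tuple[PacemakerNode, ...]:
    return (PacemakerNode("SA", sa),
            PacemakerNode("AV", av),
            PacemakerNode("Purkinje", purkinje, excited))


@dataclass
class FrankStarlingCurve:
    """Monotone (healthy) SV = f(EDV) relation, piecewise-linear between
    anchors; a failing curve turns downward at the largest filling volumes.
    ``sympathetic_shift`` >= 0 lifts the curve multiplicatively."""

    anchors: tuple[tuple[float, float], ...] = (
        (0.0, 0.0), (50.0, 30.0), (100.0, 55.0), (140.0, 70.0),
        (180.0, 79.0), (220.0, 84.0),
    )
    sympathetic_shift: float = 0.0
    failing: bool = False

    FAILING_ANCHORS = ((0.0, 0.0), (50.0, 28.0), (100.0, 50.0), (140.0, 62.0),
                       (180.0, 52.0), (220.0, 38.0))

    def __post_init__(self) -> None:
        if self.sympathetic_shift < 0:
            raise ValueError("sympathetic shift must be >= 0")
        xs = [a[0] for a in self.anchors]
        ys = [a[1] for a in self.anchors]
        if xs != sorted(xs):
            raise ValueError("curve anchors must have increasing EDV")
        if not self.failing and ys != sorted(ys):
            raise ValueError("healthy curve must be nondecreasing")

    @property
    def domain(self) -> tuple[float, float]:
        pts = self.FAILING_ANCHORS if self.failing else self.anchors
        return (pts[0][0], pts[-1][0])

    def __call__(self, edv: float) -> float:
        pts = self.FAILING_ANCHORS if self.failing else self.anchors
        lo, hi = pts[0][0], pts[-1][0]
        if not (lo <= edv <= hi):
            raise CurveDomainError(f"EDV {edv} outside curve domain [{lo}, {hi}]")
        base = float(np.interp(edv, [p[0] for p in pts], [p[1] for p in pts]))
        return min(base * (1.0 + self.sympathetic_shift), edv) if edv > 0 else 0.0


@dataclass
class HeartInternalState:
    """Metastable internal state: autonomic tones, hormone levels,
    electrolyte categories, ischemia/K_ATP, remodeling and aging."""

    sns_tone: float = 0.0
    pns_tone: float = 0.0
    norepinephrine: float = 0.0
    epinephrine: float = 0.0          # circulating, pg/mL scale (informational)
    epi_receptor_occupancy: float = 0.0   # bound-receptor fraction in [0, 1]
    thyroxine: float = 0.0
    potassium: str = "normal"         # low | normal | high
    calcium: str = "normal"           # low | normal | high | very-high
    ischemia: bool = False
    anoxia: bool = False
    katp_open: bool = False
    cell_damage: float = 0.0
    remodeling: str = "none"          # none | athlete | diseased
    age_factor: float = 1.0           # surviving calcium-channel fraction
    scar_map: dict[str, float] = field(default_factory=dict)
    purkinje_excited: bool = False
    rhythm: str = "sinus"             # persistence flag: sinus | fibrillation

    def __post_init__(self) -> None:
        if min(self.sns_tone, self.pns_tone, self.norepinephrine,
               self.epinephrine, self.thyroxine) < 0:
            raise ValueError("tones and hormone levels must be >= 0")
        if not (0.0 <= self.age_factor <= 1.0):
            raise ValueError("age_factor must be in [0, 1]")


@dataclass
class MacroSeries:
    """Per-stroke macrostates derived from the stroke sequence."""

    index: np.ndarray
    T: np.ndarray                # s
    HR: np.ndarray               # bpm (NaN for the first stroke)
    SV: np.ndarray               # mL
    EF: np.ndarray               # fraction
    CO: np.ndarray               # L/min
    HRV: float                   # SDNN of inter-stroke intervals, ms

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"index": self.index, "T_s": self.T, "HR_bpm": self.HR,
                             "SV_mL": self.SV, "EF": self.EF, "CO_L_min": self.CO})


@dataclass
class ElectrolyteOverrides:
    rate_factor: float = 1.0
    rate_override: float | None = None   # 0.0 = arrest
    contractility_factor: float = 1.0
    arrhythmia: bool = False


# --------------------------------------------------------------------------
# Macro formulas
# --------------------------------------------------------------------------

def heart_rate_from_times(t_prev: float, t_curr: float) -> float:
    """HR in bpm as the inverse of the inter-stroke interval."""
    if t_curr <= t_prev:
        raise ValueError("invalid stroke ordering")
    return 60.0 / (t_curr - t_prev)


def ejection_fraction(sv: float, edv: float) -> float:
    """EF = SV/EDV, commonly around 0.5-0.6."""
    if not (0 < sv <= edv):
        raise ValueError("impossible ejection")
    return sv / edv


# --------------------------------------------------------------------------
# Electrolytes and K_ATP
# --------------------------------------------------------------------------

def apply_electrolyte_rules(state: HeartInternalState) -> ElectrolyteOverrides:
    """Rate/contractility overrides from plasma electrolyte categories.

    High K+ depolarises the nodal cells beyond the level their sodium drift
    can reach threshold from — cardiac arrest.  Low K+ weakens contraction
    and causes arrhythmias; low Ca++ depresses the heart; high Ca++ raises
    both rate and contractility; very high Ca++ adds dangerous arrhythmias.
    """
    ov = ElectrolyteOverrides()
    if state.potassium == "high":
        ov.rate_override = 0.0
    elif state.potassium == "low":
        ov.contractility_factor *= 0.7
        ov.arrhythmia = True
    elif state.potassium != "normal":
        raise ValueError("invalid electrolyte state")

    if state.calcium == "low":
        ov.rate_factor *= 0.9
        ov.contractility_factor *= 0.8
    elif state.calcium == "high":
        ov.rate_factor *= 1.1
        ov.contractility_factor *= 1.15
    elif state.calcium == "very-high":
        ov.rate_factor *= 1.1
        ov.contractility_factor *= 1.15
        ov.arrhythmia = True
    elif state.calcium != "normal":
        raise ValueError("invalid electrolyte state")
    return ov


def apply_katp_rule(state: HeartInternalState) -> HeartInternalState:
    """Open the ATP-sensitive K+ channels under ischemia or anoxia.

    Open channels admit less calcium: contractions become faster and weaker,
    which protects the tissue from calcium-overload damage during the
    episode.  Without ischemia the state is returned unchanged.
    """
    if state.ischemia or state.anoxia:
        return replace(state, katp_open=True)
    return state


def accumulate_ischemic_damage(state: HeartInternalState, strokes: int
                               ) -> HeartInternalState:
    """Advance the cell-damage accumulator over an ischemic episode; calcium
    load (hence damage per stroke) is lower with K_ATP channels open."""
    if not (state.ischemia or state.anoxia):
        return state
    load = KATP_CALCIUM_LOAD if state.katp_open else 1.0
    return replace(state, cell_damage=state.cell_damage + load * strokes)


# --------------------------------------------------------------------------
# Pacemaker hierarchy and the effective rate
# --------------------------------------------------------------------------

def effective_heart_rate(nodes: Sequence[PacemakerNode],
                         state: HeartInternalState) -> float:
    """Pacing rate of the highest-tier functional node, modulated.

    The SA base rate (100 bpm intrinsic) is pushed up by sympathetic tone,
    norepinephrine, bound epinephrine and thyroxine (sympathetic
    responsiveness scaled by the surviving calcium-channel fraction
    ``age_factor``; thyroxine also enhances the catecholamine effect) and
    down by parasympathetic tone, clamped to physiologic bounds.  Lower-tier
    escape rates are not autonomically modulated.  Electrolyte overrides are
    applied last; open K_ATP channels shorten the inter-stroke interval.
    """
    ov = apply_electrolyte_rules(state)
    if ov.rate_override is not None:
        return ov.rate_override

    by_tier = {n.tier: n for n in nodes}
    sa = by_tier.get("SA")
    av = by_tier.get("AV")
    pk = by_tier.get("Purkinje")

    if sa is not None and sa.functional:
        sympathetic = (K_SNS * state.sns_tone
                       + K_NE * state.norepinephrine
                       + K_EPI_RATE * state.epi_receptor_occupancy)
        sympathetic *= state.age_factor * (1.0 + K_THYROXINE * state.thyroxine)
        modulation = (1.0 + sympathetic + K_THYROXINE * state.thyroxine
                      - K_PNS * state.pns_tone)
        rate = float(np.clip(SA_INTRINSIC_BPM * modulation, *RATE_CLAMP))
    elif av is not None and av.functional:
        rate = AV_BASE_BPM
    elif pk is not None and pk.functional:
        excited = pk.excited or state.purkinje_excited
        rate = PURKINJE_EXCITED_BPM if excited else PURKINJE_BASE_BPM
    else:
        raise AsystoleError("asystole: no functional pacemaker node")

    rate *= ov.rate_factor
    if state.katp_open:
        rate /= KATP_INTERVAL_FACTOR
    return float(np.clip(rate, *RATE_CLAMP)) if rate > 0 else 0.0


def stroke_volume(edv: float, curve: FrankStarlingCurve,
                  state: HeartInternalState) -> float:
    """Frank–Starling output raised by sympathetic/catecholamine
    contractility (scaled by age_factor), reduced by open K_ATP channels and
    electrolyte depression; never exceeds EDV."""
    base = curve(edv)
    ov = apply_electrolyte_rules(state)
    inotropy = 1.0 + state.age_factor * (
        K_EPI_CONTRACTILITY * state.epi_receptor_occupancy
        + K_SNS_CONTRACTILITY * state.sns_tone
        + K_NE_CONTRACTILITY * state.norepinephrine)
    sv = base * inotropy * ov.contractility_factor
    if state.katp_open:
        sv *= KATP_FORCE_FACTOR
    return min(sv, edv)


# --------------------------------------------------------------------------
# Conduction timing and chemical internal controls
# --------------------------------------------------------------------------

def conduction_timing(av_delay_ms: float = AV_DELAY_MS,
                      atrial_peak_offset_ms: float = ATRIAL_PEAK_OFFSET_MS,
                      ventricular_peak_offset_ms: float = VENTRICULAR_PEAK_OFFSET_MS
                      ) -> tuple[float, float, float]:
    """Timing of peak atrial vs ventricular contraction.

    The AV node delays the depolarisation wave by ``av_delay_ms``; peak force
    follows depolarisation by the per-chamber offsets.  Returns
    (atrial_peak, ventricular_peak, gap) in ms; defaults give a 200 ms gap.
    """
    atrial_peak = atrial_peak_offset_ms
    ventricular_peak = av_delay_ms + ventricular_peak_offset_ms
    gap = ventricular_peak - atrial_peak
    if gap < 0:
        raise ValueError("invalid timing config")
    return (atrial_peak, ventricular_peak, gap)


def adenosine_coronary_rule(workload: float, state: HeartInternalState,
                            threshold: float = ADENOSINE_WORKLOAD_THRESHOLD
                            ) -> tuple[float, list[ActionOutput]]:
    """Adenosine release under high myocardial workload dilates the coronary
    arteries.  Returns a coronary-flow factor (>= 1, nondecreasing in
    workload) and the dilation action, if any."""
    if workload < 0:
        raise ValueError("workload must be >= 0")
    if workload <= threshold:
        return (1.0, [])
    excess = workload - threshold
    factor = 1.0 + 0.5 * excess
    return (factor, [ActionOutput("vessel-dilation", factor - 1.0,
                                  "coronary-arteries")])


def anp_rule(atrial_stretch: float, state: HeartInternalState,
             threshold: float = ANP_STRETCH_THRESHOLD) -> list[ActionOutput]:
    """Atrial natriuretic peptide release on atrial stretch: an endocrine
    signal to the kidneys (natriuresis, lower blood pressure) plus a local
    paracrine anti-hypertrophy effect."""
    if atrial_stretch < 0:
        raise ValueError("stretch must be >= 0")
    if atrial_stretch <= threshold:
        return []
    magnitude = atrial_stretch - threshold
    return [ActionOutput("natriuresis-signal", magnitude, "kidneys"),
            ActionOutput("paracrine-antihypertrophy", magnitude, "atrial-myocardium")]


# --------------------------------------------------------------------------
# Remodeling (metastable internal state)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Regimen:
    kind: str                  # "athlete" | "aging" | "infarct"
    duration: float = 1.0      # years (athlete/aging) — must be >= 0
    region: str = "apex"       # infarct only
    severity: float = 0.5      # infarct responsiveness loss in [0, 1]


ATHLETE_SV_EXERCISE_GAIN = 2.0     # trained SV roughly doubles on exercise
UNTRAINED_SV_EXERCISE_GAIN = 1.0
EXERCISE_HR_FACTOR = 2.6           # rest 70 -> ~180 bpm

AGING_CHANNEL_LOSS_PER_YEAR = 0.01


def remodel(state: HeartInternalState, regimen: Regimen) -> HeartInternalState:
    """Apply a long-timescale remodeling regimen; the new internal state
    persists until the next remodel call (metastability)."""
    if regimen.duration < 0:
        raise ValueError("regimen duration must be >= 0")
    if regimen.kind == "athlete":
        return replace(state, remodeling="athlete")
    if regimen.kind == "aging":
        factor = (1.0 - AGING_CHANNEL_LOSS_PER_YEAR) ** regimen.duration
        return replace(state, age_factor=state.age_factor * factor)
    if regimen.kind == "infarct":
        scars = dict(state.scar_map)
        scars[regimen.region] = min(scars.get(regimen.region, 1.0),
                                    1.0 - regimen.severity)
        return replace(state, scar_map=scars, remodeling=state.remodeling)
    raise ValueError(f"unknown regimen {regimen.kind!r}")


def cardiac_output_gain(state: HeartInternalState,
                        hr_factor: float = EXERCISE_HR_FACTOR) -> float:
    """Exercise CO / rest CO.  Rate alone gives a factor of 2-3; athletic
    remodeling adds a stroke-volume gain, lifting the ratio to about 5-6."""
    sv_gain = (ATHLETE_SV_EXERCISE_GAIN if state.remodeling == "athlete"
               else UNTRAINED_SV_EXERCISE_GAIN)
    return hr_factor * sv_gain


# --------------------------------------------------------------------------
# Circulation delay lines and the stroke loop
# --------------------------------------------------------------------------

class Circulation:
    """The closed circulatory loop as stroke-delay lines.

    systemic-venous -> right heart -> pulmonary -> left heart ->
    {coronary | systemic-arterial} -> merge -> systemic-venous.

    Each queue slot is the reduced content vector of one ejected blood
    portion; slots move one position per stroke, so transit times are the
    queue lengths in strokes.  Splitting and merging are mass-exact, so with
    binding and decay disabled every particle's total mass is conserved.
    """

    def __init__(self,
                 delays: Mapping[str, int] = DEFAULT_DELAYS,
                 coronary_fraction: float = CORONARY_FRACTION,
                 baseline_volume: float = 70.0,
                 particles: Iterable[str] = ("epinephrine",)):
        self.delays = dict(delays)
        if any(d < 0 for d in self.delays.values()):
            raise ValueError("delays must be >= 0")
        self.coronary_fraction = coronary_fraction
        self.particles = tuple(particles)
        zero = {p: 0.0 for p in self.particles}
        # the coronary branch carries only its split share of each stroke
        share = {"coronary": coronary_fraction,
                 "systemic-arterial": 1.0 - coronary_fraction}
        self.buffers: dict[str, deque[ReducedVector]] = {
            name: deque(ReducedVector(baseline_volume * share.get(name, 1.0),
                                      dict(zero))
                        for _ in range(d))
            for name, d in self.delays.items()
        }

    def total_mass(self, particle: str) -> float:
        return float(sum(slot.total_mass(particle)
                         for buf in self.buffers.values() for slot in buf))

    def _pop(self, name: str) -> ReducedVector:
        buf = self.buffers[name]
        if not buf:
            raise UninitializedCirculationError(f"uninitialized circulation: {name}")
        return buf.popleft()


def advance_stroke(circ: Circulation, state: HeartInternalState,
                   curve: FrankStarlingCurve,
                   nodes: Sequence[PacemakerNode],
                   *, t_prev: float = 0.0, index: int = 0,
                   edv: float = 140.0,
                   injection: Mapping[str, float] | None = None,
                   split_s2_offset: float = 0.0
                   ) -> tuple[StrokeRecord, float]:
    """Advance the circulation by one stroke.

    Dequeues the venous return into the right heart, moves the pulmonary
    blood into the left heart, splits the left output exactly into coronary
    and systemic portions, and merges the returning portions (plus any
    ``injection`` masses) back into the venous line.  Time advances by
    60/effective_heart_rate seconds.  Returns the stroke record and the new
    clock time.
    """
    rate = effective_heart_rate(nodes, state)
    if rate <= 0:
        raise HeartError("arrested heart cannot stroke")
    dt = 60.0 / rate
    t = t_prev + dt

    sv = stroke_volume(edv, curve, state)

    right_in = circ._pop("systemic-venous")        # right-heart contents
    circ.buffers["pulmonary"].append(right_in)
    left_in = circ._pop("pulmonary")               # left-heart contents
    coronary_portion, systemic_portion = left_in.split(circ.coronary_fraction)
    circ.buffers["coronary"].append(coronary_portion)
    circ.buffers["systemic-arterial"].append(systemic_portion)
    returned = ReducedVector.combine(circ._pop("coronary"),
                                     circ._pop("systemic-arterial"))
    if injection:
        counts = dict(returned.counts)
        for p, mass in injection.items():
            counts[p] = counts.get(p, 0.0) + mass
        returned = ReducedVector(returned.volume, counts)
    circ.buffers["systemic-venous"].append(returned)

    record = StrokeRecord(index=index, T_r=t + split_s2_offset, T_l=t,
                          EDV_r=edv, EDV_l=edv, SV_r=sv, SV_l=sv,
                          contents_r=right_in, contents_l=left_in)
    return record, t


def compute_macroseries(strokes: Sequence[StrokeRecord]) -> MacroSeries:
    """Derive HR/EF/CO/HRV from a stroke sequence.

    HR_i = 60/(T_i - T_{i-1}) bpm (undefined for the first stroke);
    CO = HR*SV/1000 L/min; HRV is the standard deviation of the inter-stroke
    intervals in ms (the SDNN convention) over the full series.
    """
    if len(strokes) < 2:
        raise ValueError("insufficient series")
    t = np.array([s.T_l for s in strokes])
    sv = np.array([s.SV_l for s in strokes])
    edv = np.array([s.EDV_l for s in strokes])
    intervals = np.diff(t)
    hr = np.concatenate([[np.nan], 60.0 / intervals])
    ef = sv / edv
    co = hr * sv / 1000.0
    hrv = float(np.std(intervals * 1000.0))
    return MacroSeries(index=np.array([s.index for s in strokes]),
                       T=t, HR=hr, SV=sv, EF=ef, CO=co, HRV=hrv)


# --------------------------------------------------------------------------
# The epinephrine worked scenario
# --------------------------------------------------------------------------

@dataclass
class EpinephrineConfig:
    """Study conditions for the adrenal-epinephrine transport scenario:
    release into the venous return at stroke 0, arrival at the right heart at
    stroke 10, the left heart at stroke 30, coronary receptor binding from
    stroke 40, saturation at stroke 50."""

    n_strokes: int = 60
    peak_concentration: float = 140.0     # pg/mL in the released portion
    binding_start: int = 40
    saturation: int = 50
    baseline_pns_tone: float = 1.0        # resting: 100 bpm intrinsic -> 70 bpm
    edv: float = 140.0
    clearance: float = EPI_CLEARANCE_PER_STROKE


@dataclass
class EpinephrineResult:
    strokes: list[StrokeRecord]
    macro: MacroSeries
    left_epinephrine: np.ndarray     # pg/mL per stroke, left-chamber contents
    actions: list[dict]


def run_epinephrine_scenario(config: EpinephrineConfig | None = None
                             ) -> EpinephrineResult:
    """Run the epinephrine transport worked example.

    Baseline HR is ~70 bpm and SV ~70 mL.  The released portion carries
    ``peak_concentration`` pg/mL of epinephrine and transits the delay lines
    unchanged, so the left-chamber contents read 0 pg/mL at stroke 0 and the
    peak concentration at stroke 30.  Receptor occupancy ramps linearly from
    stroke 40 to saturation at stroke 50, lifting HR to 140 bpm and SV to
    100 mL; bound/cleared epinephrine then decays toward zero.
    """
    cfg = config or EpinephrineConfig()
    circ = Circulation()
    curve = FrankStarlingCurve()
    nodes = default_nodes()
    state = HeartInternalState(pns_tone=cfg.baseline_pns_tone)

    # mass calibrated so the released venous portion has the peak concentration
    entry_volume = circ.buffers["systemic-venous"][-1].volume if \
        circ.buffers["systemic-venous"] else 70.0
    injection_mass = cfg.peak_concentration * entry_volume

    strokes: list[StrokeRecord] = []
    actions: list[dict] = []
    left_conc = np.zeros(cfg.n_strokes)
    t = 0.0
    ramp = max(cfg.saturation - cfg.binding_start, 1)
    delivered = 0.0   # peak epinephrine concentration seen at the coronary bed
    for i in range(cfg.n_strokes):
        if circ.buffers["coronary"]:
            front = circ.buffers["coronary"][0]
            delivered = max(delivered, front.concentration("epinephrine"))
        # binding ramps linearly once hormone reaches the receptors; with no
        # hormone delivered the receptors stay unoccupied
        drive = min(1.0, delivered / cfg.peak_concentration) \
            if cfg.peak_concentration > 0 else 0.0
        occupancy = drive * float(np.clip((i - cfg.binding_start) / ramp, 0.0, 1.0))
        state = replace(state, epi_receptor_occupancy=occupancy)
        injection = {"epinephrine": injection_mass} if i == 0 else None
        record, t = advance_stroke(circ, state, curve, nodes,
                                   t_prev=t, index=i, edv=cfg.edv,
                                   injection=injection)
        strokes.append(record)
        left_conc[i] = record.contents_l.concentration("epinephrine")
        actions.append({"stroke": i, "kind": "muscle-contraction",
                        "magnitude": record.SV_l, "target": "aorta"})
        if i >= cfg.binding_start:
            # receptor binding and hepatic breakdown clear circulating hormone
            for buf in circ.buffers.values():
                for slot in buf:
                    if "epinephrine" in slot.counts:
                        slot.counts["epinephrine"] *= cfg.clearance

    macro = compute_macroseries(strokes)
    return EpinephrineResult(strokes=strokes, macro=macro,
                             left_epinephrine=left_conc, actions=actions)


# --------------------------------------------------------------------------
# The heart's control function as a general rule
# --------------------------------------------------------------------------

def heart_control_rule() -> GeneralRule:
    """A coarse decision-table view of the heart's pacing control, suitable
    for the rule-engine checks: inputs are the plasma potassium category and
    the autonomic drive, state is the rhythm; outputs set the pacing regime
    and the contraction action."""
    import itertools as it
    axes = ("potassium", "autonomic")
    alphabet = tuple({"potassium": k, "autonomic": a}
                     for k, a in it.product(("normal", "high"),
                                            ("rest", "sympathetic")))
    contract = ActionOutput("muscle-contraction", 70.0, "aorta", "mL")
    contract_hard = ActionOutput("muscle-contraction", 100.0, "aorta", "mL")
    branches = (
        Branch(TableGuard({"potassium": ("high",)}), "arrest", (), "arrested"),
        Branch(TableGuard({"potassium": ("normal",), "autonomic": ("rest",)}),
               "pace-70", (contract,), "sinus"),
        Branch(TableGuard({"potassium": ("normal",), "autonomic": ("sympathetic",)}),
               "pace-140", (contract_hard,), "sinus"),
    )
    return GeneralRule("heart-pacing", axes, frozenset({"sinus", "arrested"}),
                       branches, alphabet)
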