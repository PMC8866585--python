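"""Dionaea muscipula trap closure, prey selection and staged digestion.

The Venus flytrap is modelled as a counting automaton.  Trigger-hair bends
produce receptor potentials that accumulate; the number of stimulations
required for closure depends on the environment (1 when humid and warm,
2 within a ~20-30 s window when humid and moderate, 3 when dry).  Closure is
fast (onset 0.1-0.2 s after threshold, complete within 0.5 s) and each trap
survives only about a dozen closures.  After closure, tiny prey escapes
through the teeth; struggling prey generates further action potentials (APs)
and, with nitrogen sensing, drives hermetic sealing.  Digestion is staged by
AP count — jasmonic acid (JA) signalling after 2 APs, digestive-enzyme gene
expression after 3, nutrient/sodium transporter activation after 5 — with a
positive feedback loop in which prey-derived potassium and chitin sustain JA
signalling until the prey is fully digested.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

from .rules import (ActionOutput, Branch, ContinuousAxis, DiscreteAxis,
                    GeneralRule, TableGuard, Vehicle)

# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

WARM_BAND = (28.0, 36.0)          # degrees C
MODERATE_BAND = (18.0, 28.0)      # lower edge chosen; below it stimuli are ignored
STIMULATION_WINDOW_S = 30.0       # permissive end of the printed 20-30 s band
CLOSURE_ONSET_DELAY_S = 0.15      # within the printed 0.1-0.2 s band
CLOSURE_DURATION_S = 0.30         # onset + duration <= 0.5 s after threshold
CLOSURE_LIFETIME = 12             # "about a dozen closures"
REOPEN_DELAY_DAYS = 1.5           # within the printed 1-2 day band

#: Size-dependent electrical thresholds (charge units): lower for smaller traps.
ELECTRICAL_THRESHOLD = {"small": 1.0, "medium": 1.5, "large": 2.0}

#: AP-count stage thresholds.
AP_JASMONIC = 2
AP_ENZYME_GENES = 3
AP_TRANSPORTERS = 5

#: Sealing: >=1 post-closure AP plus nitrogen sensing, or sustained
#: struggling (>=3 APs) alone.
SEAL_AP_WITH_NITROGEN = 1
SEAL_AP_ALONE = 3

DIGESTION_RATE = 0.05             # fractional mass removed per step at full drive
MASS_EPSILON_MG = 1e-3            # below this the prey counts as fully digested
JA_FLOOR = 0.05                   # JA activity below which enzyme release stops
PHOTOSYNTHESIS_BOOST_WEEKS = 5

DEFAULT_ALLOCATION = {"trap": 0.7, "other-traps-roots": 0.2, "respired-co2": 0.1}


class FlytrapError(Exception):
    pass


class UnclassifiedEnvironmentError(FlytrapError):
    """Temperature outside the documented classification bands."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

class Phase(str, Enum):
    OPEN = "Open"
    CLOSING = "Closing"
    CLOSED = "Closed"
    SEALED = "Sealed"
    DIGESTING = "Digesting"
    REOPENING = "Reopening"
    EXHAUSTED = "Exhausted"


@dataclass(frozen=True)
class TrapEnvironment:
    temperature: float            # degrees C
    humidity: str                 # "humid" | "dry"

    def __post_init__(self) -> None:
        if self.humidity not in ("humid", "dry"):
            raise ValueError("humidity must be 'humid' or 'dry'")

    @property
    def band(self) -> str:
        if WARM_BAND[0] <= self.temperature <= WARM_BAND[1]:
            return "warm"
        if MODERATE_BAND[0] <= self.temperature < MODERATE_BAND[1]:
            return "moderate"
        raise UnclassifiedEnvironmentError(
            f"unclassified environment: {self.temperature} C")


@dataclass(frozen=True)
class StimulusEvent:
    time: float                   # s
    kind: str                     # "hair-bend" | "electrical"
    magnitude: float = 0.0        # charge units, electrical only
    hair_id: int = 1              # 1-6; logging only, all hairs count alike

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event times must be nonnegative")
        if not (1 <= self.hair_id <= 6):
            raise ValueError("hair_id must be 1-6 (three hairs per lobe)")
        if self.kind not in ("hair-bend", "electrical"):
            raise ValueError("unknown stimulus kind")


@dataclass
class TrapState:
    phase: Phase = Phase.OPEN
    charge: float = 0.0
    stim_log: tuple[float, ...] = ()
    closure_count: int = 0
    size_class: str = "medium"
    ap_count: int = 0
    threshold_time: float | None = None   # when closure threshold was reached
    lifetime_limit: int = CLOSURE_LIFETIME
    window_s: float = STIMULATION_WINDOW_S

    def __post_init__(self) -> None:
        if self.charge < 0 or self.closure_count > self.lifetime_limit:
            raise ValueError("invalid trap state")


@dataclass(frozen=True)
class PreyObject:
    name: str
    size: str                     # "tiny" | "fits" | "too-large-to-enter"
    motile: bool
    composition: Mapping[str, float]   # chitin, lipid, protein, nucleic-acid,
                                       # carbohydrate, sodium, potassium, nitrogen
    mass: float                   # mg
    digestible: bool = True

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.composition.values()):
            raise ValueError("composition quantities must be >= 0")
        if not self.digestible and any(v > 0 for v in self.composition.values()):
            raise ValueError("indigestible objects carry no nutrients")

    @property
    def nitrogen_rich(self) -> bool:
        return self.composition.get("nitrogen", 0.0) > 0


@dataclass(frozen=True)
class Enzyme:
    name: str
    substrate: str
    acidic_optimum: bool = True


def default_enzyme_catalog() -> tuple[Enzyme, ...]:
    """The trap's digestive arsenal: 2 chitinases, 1 lipid-transfer protein,
    5 proteases, 4 nucleases (DNase and RNase), 3 carbohydrate-hydrolysing
    enzymes and 2 phosphatases — 17 enzymes in total."""
    catalog = (
        [Enzyme(f"chitinase-{i}", "chitin") for i in (1, 2)]
        + [Enzyme("lipid-transfer-protein", "lipid", acidic_optimum=False)]
        + [Enzyme(f"protease-{i}", "protein") for i in range(1, 6)]
        + [Enzyme("dnase", "nucleic-acid"), Enzyme("rnase", "nucleic-acid"),
           Enzyme("nuclease-3", "nucleic-acid"), Enzyme("nuclease-4", "nucleic-acid")]
        + [Enzyme(f"carbohydrase-{i}", "carbohydrate") for i in (1, 2, 3)]
        + [Enzyme(f"phosphatase-{i}", "nucleic-acid") for i in (1, 2)]
    )
    return tuple(catalog)


#: Breakdown product per substrate class.
PRODUCT_OF = {"chitin": "amino-sugars", "lipid": "lipids", "protein": "amino-acids",
              "nucleic-acid": "nucleobases", "carbohydrate": "sugars",
              "sodium": "sodium", "potassium": "potassium", "nitrogen": "urea-n"}


@dataclass
class DigestionState:
    ap_count: int = 0
    ja_active: bool = False
    ja_activity: float = 0.0              # drive level in [0, 1]
    enzyme_genes_expressed: bool = False
    transporters_active: bool = False
    enzymes_released: tuple[Enzyme, ...] = ()
    prey_mass_remaining: float = 0.0      # mg
    products: dict[str, float] = field(default_factory=dict)
    stalled: bool = False


# --------------------------------------------------------------------------
# Closure algorithm
# --------------------------------------------------------------------------

def required_stimulation_count(env: TrapEnvironment) -> int:
    """Environment-dependent stimulation count for closure: 1 when humid and
    warm (28-36 C), 2 when humid and moderate (~22 C), 3 when dry."""
    band = env.band   # raises UnclassifiedEnvironmentError outside the bands
    if env.humidity == "humid":
        return 1 if band == "warm" else 2
    return 3


def register_stimulus(trap: TrapState, event: StimulusEvent,
                      env: TrapEnvironment) -> TrapState:
    """Record one stimulus on an open trap.

    Hair bends within the sliding window count toward the environment's
    required stimulation number; subthreshold electrical charges accumulate
    additively toward the size-dependent threshold.  Either route reaching
    threshold arms closure (phase -> Closing).  Stimuli on a non-open trap
    are ignored (logged by the caller, no transition)."""
    if trap.phase is not Phase.OPEN:
        return trap
    if event.kind == "hair-bend":
        log = tuple(t for t in trap.stim_log
                    if event.time - t <= trap.window_s) + (event.time,)
        if len(log) >= required_stimulation_count(env):
            return replace(trap, stim_log=log, phase=Phase.CLOSING,
                           threshold_time=event.time)
        return replace(trap, stim_log=log)
    charge = trap.charge + event.magnitude
    if charge >= ELECTRICAL_THRESHOLD[trap.size_class]:
        return replace(trap, charge=charge, phase=Phase.CLOSING,
                       threshold_time=event.time)
    return replace(trap, charge=charge)


def close_trap(trap: TrapState, t_threshold: float,
               onset_delay: float = CLOSURE_ONSET_DELAY_S,
               duration: float = CLOSURE_DURATION_S
               ) -> tuple[TrapState, float, float]:
    """Execute an armed closure.

    Onset follows the threshold stimulation by 0.1-0.2 s and the lobes meet
    within half a second.  The charge accumulator and stimulation window
    reset.  A trap at its lifetime limit becomes Exhausted instead."""
    if trap.phase is not Phase.CLOSING:
        raise FlytrapError("close_trap requires an armed (Closing) trap")
    if trap.closure_count >= trap.lifetime_limit:
        return (replace(trap, phase=Phase.EXHAUSTED, charge=0.0, stim_log=()),
                t_threshold, t_threshold)
    if not (0.1 <= onset_delay <= 0.2):
        raise ValueError("closure onset must fall 0.1-0.2 s after threshold")
    onset = t_threshold + onset_delay
    done = onset + duration
    if done > t_threshold + 0.5:
        raise ValueError("closure must finish within half a second of threshold")
    new = replace(trap, phase=Phase.CLOSED, closure_count=trap.closure_count + 1,
                  charge=0.0, stim_log=(), ap_count=0)
    return (new, onset, done)


def escape_or_seal(trap: TrapState, prey: PreyObject,
                   post_closure_events: Sequence[StimulusEvent]) -> TrapState:
    """Decide between escape, sealing, and abandonment after closure.

    Tiny prey slips out between the interlocking teeth and the trap later
    reopens without digesting.  Prey too large to escape keeps stimulating
    the hairs — each struggle event adds one action potential — and, with
    inner trap cells sensing nitrogen-rich substances such as urea, the trap
    seals hermetically.  A still, nitrogen-free object (a stone) never
    triggers sealing and the trap eventually reopens."""
    if trap.phase is not Phase.CLOSED:
        raise FlytrapError("escape_or_seal requires a Closed trap")
    if prey.size == "tiny":
        return replace(trap, phase=Phase.REOPENING)
    aps = trap.ap_count + (len(post_closure_events) if prey.motile else 0)
    trap = replace(trap, ap_count=aps)
    if (aps >= SEAL_AP_WITH_NITROGEN and prey.nitrogen_rich) or aps >= SEAL_AP_ALONE:
        return replace(trap, phase=Phase.SEALED)
    return replace(trap, phase=Phase.REOPENING)


# --------------------------------------------------------------------------
# Digestion
# --------------------------------------------------------------------------

def digestion_stage(dstate: DigestionState) -> DigestionState:
    """Activate staged pathways from the AP count: JA release at >=2 APs,
    enzyme gene expression at >=3, transporter activation at >=5.  Stages
    never revert within a digestion episode."""
    ja = dstate.ja_active or dstate.ap_count >= AP_JASMONIC
    genes = dstate.enzyme_genes_expressed or dstate.ap_count >= AP_ENZYME_GENES
    transporters = dstate.transporters_active or dstate.ap_count >= AP_TRANSPORTERS
    activity = max(dstate.ja_activity, 0.5 if ja else 0.0)
    return replace(dstate, ja_active=ja, ja_activity=activity,
                   enzyme_genes_expressed=genes, transporters_active=transporters)


def select_enzymes(prey: PreyObject,
                   catalog: Sequence[Enzyme] = default_enzyme_catalog()
                   ) -> tuple[Enzyme, ...]:
    """Release exactly the catalog enzymes whose substrate class is present
    in the prey's composition — a combination suited to the particular prey."""
    return tuple(e for e in catalog
                 if prey.composition.get(e.substrate, 0.0) > 0)


def acidification_actions(enzymes: Sequence[Enzyme]) -> list[ActionOutput]:
    """H+ secretion (hydrochloric acid via proton-pump ATPases) whenever any
    released enzyme works best at acidic pH."""
    if any(e.acidic_optimum for e in enzymes):
        return [ActionOutput("ion-flux", 1.0, "digestive-fluid", "pH-drop")]
    return []


def digestion_feedback_step(dstate: DigestionState, prey: PreyObject,
                            catalog: Sequence[Enzyme] = default_enzyme_catalog(),
                            rate: float = DIGESTION_RATE) -> DigestionState:
    """One step of the digestion positive-feedback loop.

    Prey mass declines in proportion to the released-enzyme fraction and the
    JA drive.  Breakdown liberates potassium (depolarising the gland
    membranes) and chitin (a direct JA stimulant), both of which push the JA
    drive up, releasing more enzymes — the loop ends when the prey is
    entirely digested.  Prey lacking both stimulants (a robotic fly) cannot
    sustain the drive: the JA level decays, enzyme release stops early and
    the remaining mass stalls."""
    if not dstate.enzyme_genes_expressed:
        return dstate
    if dstate.stalled or dstate.prey_mass_remaining <= 0:
        return dstate

    enzymes = dstate.enzymes_released or select_enzymes(prey, catalog)
    e_frac = len(enzymes) / max(len(catalog), 1)
    digested = dstate.prey_mass_remaining * rate * e_frac * dstate.ja_activity
    remaining = dstate.prey_mass_remaining - digested
    if remaining < MASS_EPSILON_MG:
        digested += remaining
        remaining = 0.0

    # distribute the digested mass over the composition classes
    total_comp = sum(prey.composition.values())
    products = dict(dstate.products)
    if total_comp > 0 and digested > 0:
        for substrate, q in prey.composition.items():
            if q > 0:
                products[PRODUCT_OF[substrate]] = (
                    products.get(PRODUCT_OF[substrate], 0.0)
                    + digested * q / total_comp)

    sustains = (prey.composition.get("potassium", 0.0) > 0
                or prey.composition.get("chitin", 0.0) > 0)
    if sustains:
        activity = min(1.0, dstate.ja_activity + 0.25)
        stalled = False
    else:
        activity = dstate.ja_activity * 0.5
        stalled = activity < JA_FLOOR
        if stalled:
            enzymes = ()
    return replace(dstate, enzymes_released=enzymes, ja_activity=activity,
                   prey_mass_remaining=remaining, products=products,
                   stalled=stalled)


def run_digestion(prey: PreyObject, ap_count: int,
                  catalog: Sequence[Enzyme] = default_enzyme_catalog(),
                  max_steps: int = 10_000) -> DigestionState:
    """Drive the staged digestion of a sealed prey to completion or stall."""
    d = DigestionState(ap_count=ap_count, prey_mass_remaining=prey.mass)
    d = digestion_stage(d)
    for _ in range(max_steps):
        if d.prey_mass_remaining <= 0 or d.stalled:
            break
        d = digestion_feedback_step(d, prey, catalog)
    return d


@dataclass(frozen=True)
class ProductAllocation:
    trap: dict[str, float]
    other_traps_roots: dict[str, float]
    respired_co2: dict[str, float]
    photosynthesis_boost_at_weeks: int = PHOTOSYNTHESIS_BOOST_WEEKS

    def total_mass(self) -> float:
        return sum(sum(d.values()) for d in
                   (self.trap, self.other_traps_roots, self.respired_co2))


def allocate_products(dstate: DigestionState,
                      fractions: Mapping[str, float] = DEFAULT_ALLOCATION
                      ) -> ProductAllocation:
    """Split the digestion products among the digesting trap (the majority),
    the plant's other traps and roots, and carbon respired as CO2 within
    about two days; photosynthetic capacity rises about five weeks later."""
    if abs(sum(fractions.values()) - 1.0) > 1e-12:
        raise ValueError("allocation fractions must sum to 1")
    pools = {name: {k: v * f for k, v in dstate.products.items()}
             for name, f in fractions.items()}
    return ProductAllocation(trap=pools["trap"],
                             other_traps_roots=pools["other-traps-roots"],
                             respired_co2=pools["respired-co2"])


def reopen(trap: TrapState, delay_days: float = REOPEN_DELAY_DAYS) -> TrapState:
    """Gradual reopening over one or two days; a trap at its lifetime limit
    is Exhausted instead (Exhausted is absorbing)."""
    if trap.phase is Phase.EXHAUSTED:
        return trap
    if trap.phase not in (Phase.REOPENING, Phase.SEALED, Phase.CLOSED,
                          Phase.DIGESTING):
        raise FlytrapError("reopen requires a closed or reopening trap")
    if not (1.0 <= delay_days <= 2.0):
        raise ValueError("reopening takes one to two days")
    if trap.closure_count >= trap.lifetime_limit:
        return replace(trap, phase=Phase.EXHAUSTED)
    return replace(trap, phase=Phase.OPEN, ap_count=0, charge=0.0, stim_log=())


# --------------------------------------------------------------------------
# The closure algorithm as a general rule; ion distinguishability fixtures
# --------------------------------------------------------------------------

def closure_rule() -> GeneralRule:
    """The environment-dependent closure threshold as a three-branch decision
    table over (humidity, temperature band)."""
    axes = ("humidity", "temperature-band")
    alphabet = tuple({"humidity": h, "temperature-band": b}
                     for h, b in itertools.product(("humid", "dry"),
                                                   ("warm", "moderate")))
    branches = (
        Branch(TableGuard({"humidity": ("humid",), "temperature-band": ("warm",)}),
               1, (), "armed-1"),
        Branch(TableGuard({"humidity": ("humid",), "temperature-band": ("moderate",)}),
               2, (), "armed-2"),
        Branch(TableGuard({"humidity": ("dry",)}), 3, (), "armed-3"),
    )
    return GeneralRule("flytrap-closure", axes,
                       frozenset({"armed-1", "armed-2", "armed-3"}),
                       branches, alphabet)


def ion_selectivity_vehicle() -> Vehicle:
    """Vehicle for the electrical-activity medium: Na+ and K+ are
    biologically distinguishable (channel selectivity), while the three
    common potassium isotopes play the same role and form one class."""
    return Vehicle("trap-electrical-activity", {
        "ion": DiscreteAxis(states=("Na+", "K39+", "K40+", "K41+"),
                            partition=(frozenset({"Na+"}),
                                       frozenset({"K39+", "K40+", "K41+"}))),
    })


def potassium_channel_rule() -> GeneralRule:
    """A K+-selective channel: conducts any potassium isotope, blocks
    sodium — sensitive only to the distinguishable Na/K difference."""
    alphabet = tuple({"ion": i} for i in ("Na+", "K39+", "K40+", "K41+"))
    branches = (
        Branch(TableGuard({"ion": ("K39+", "K40+", "K41+")}), "conduct",
               (ActionOutput("ion-flux", 1.0, "gland-membrane"),), "open"),
        Branch(TableGuard({"ion": ("Na+",)}), "block", (), "open"),
    )
    return GeneralRule("potassium-channel", ("ion",), frozenset({"open"}),
                       branches, alphabet)


def isotope_discriminating_rule() -> GeneralRule:
    """A physically impossible rule that branches on the potassium isotope —
    it reads a biologically indistinguishable difference, so it fails the
    medium-flexibility check."""
    alphabet = tuple({"ion": i} for i in ("Na+", "K39+", "K40+", "K41+"))
    branches = (
        Branch(TableGuard({"ion": ("K40+",)}), "conduct", (), "open"),
        Branch(TableGuard({"ion": ("Na+", "K39+", "K41+")}), "block", (), "open"),
    )
    return GeneralRule("isotope-discriminator", ("ion",), frozenset({"open"}),
                       branches, alphabet)
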