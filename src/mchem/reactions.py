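"""Post-column derivatization reactions: registry, reactivity prediction, validation.

Three orthogonal labeling chemistries are shipped by default:

* **A** — L-cysteine conjugation of electrophiles (Michael acceptors,
  naphthoquinones, epoxyketones, beta-lactones, activated/macrocyclic esters
  via thioester formation, terminal alkenes); net addition C3H7NO2S,
  delta m/z 121.0197 Da.
* **B** — AQC (6-aminoquinolyl-N-hydroxysuccinimidyl carbamate) carbamoylation
  of primary/secondary amines, phenols and N-hydroxy groups; net addition
  C10H6N2O, delta m/z 170.0480 Da.
* **C** — hydroxylamine oximation of aldehydes and ketones; net change
  +NH2OH -H2O (collapsing to +NH), delta m/z 15.0109 Da.

Each reaction carries a curated set of SMARTS patterns for its reactive
groups.  The exact published pattern set is replaceable: registries can be
serialized to and loaded from YAML (see :mod:`mchem.io`), so users may
substitute their own patterns.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction

from .chemcore import (
    ChemError,
    MolecularFormula,
    monoisotopic_mass,
    match_substructure,
    parse_formula,
)

__all__ = [
    "Reaction",
    "ReactivityPrediction",
    "Call",
    "ValidationCall",
    "ReactivitySummary",
    "default_registry",
    "registry_by_id",
    "simulate_reactivity",
    "classify_observation",
    "reactivity_summary",
]

# Ring size >= 8 counts as macrocyclic for the thioester-formation pattern;
# smaller lactones are not labeled by default.  Adjust by editing the SMARTS
# ring-size range (r{8-}) in a custom registry.
MACROCYCLE_MIN_RING = 8


@dataclass(frozen=True)
class Reaction:
    """One derivatization reaction: reagent, net elemental change, patterns."""

    id: str
    reagent: str
    net_change: MolecularFormula
    patterns: tuple[tuple[str, str], ...]  # (label, SMARTS), ordered
    min_yield_pct: float = 0.0

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ChemError(f"reaction {self.id}: patterns must be non-empty")
        labels = [lab for lab, _ in self.patterns]
        if len(set(labels)) != len(labels):
            raise ChemError(f"reaction {self.id}: duplicate pattern labels")

    @property
    def delta_mass(self) -> float:
        """Monoisotopic mass shift of the net change, in Da."""
        return monoisotopic_mass(self.net_change)

    def pattern_labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.patterns)

    def smarts(self) -> tuple[str, ...]:
        return tuple(s for _, s in self.patterns)


@dataclass(frozen=True)
class ReactivityPrediction:
    """Predicted reactivity of one structure toward one reaction."""

    structure_id: str
    reaction_id: str
    matched_labels: tuple[str, ...]
    smarts_hits: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.matched_labels:
            raise ChemError("a prediction must carry at least one matched label")


class Call(str, enum.Enum):
    TRUE_POSITIVE = "true_positive"
    FALSE_POSITIVE = "false_positive"
    FALSE_NEGATIVE = "false_negative"
    TRUE_NEGATIVE = "true_negative"


@dataclass(frozen=True)
class ValidationCall:
    structure_id: str
    reaction_id: str
    call: Call


_REACTION_A_PATTERNS = (
    # alpha,beta-unsaturated carbonyl (classic Michael acceptor)
    ("michael_acceptor_enone", "[CX3]=[CX3][CX3]=[OX1]"),
    # alpha,beta-unsaturated nitrile / ester electrophiles
    ("michael_acceptor_acrylate", "[CX3]=[CX3][CX3](=[OX1])[OX2]"),
    # 1,4-naphthoquinone core
    ("naphthoquinone", "O=C1C=CC(=O)c2ccccc21"),
    # alpha,beta-epoxyketone warhead
    ("epoxyketone", "[OX2r3]1[#6r3][#6r3]1[CX3]=[OX1]"),
    # beta-lactone (4-membered ring ester)
    ("beta_lactone", "[CX3]1(=[OX1])[OX2][CX4][CX4]1"),
    # macrocyclic ester (ring size >= 8), likely thioester formation
    ("macrocyclic_ester", "[C;r{8-}](=[OX1])[O;r{8-}]"),
    # terminal alkene
    ("terminal_alkene", "[CX3H2]=[CX3H1]"),
)

_REACTION_B_PATTERNS = (
    # primary amine, excluding amides/imines (AQC does not label amides)
    ("primary_amine", "[NX3;H2;!$(NC=[O,S,N]);!$(N=*)]"),
    # secondary amine with the same exclusions
    ("secondary_amine", "[NX3;H1;!$(NC=[O,S,N]);!$(N=*);$(N([#6])[#6])]"),
    ("phenol", "[OX2H][c]"),
    ("n_hydroxy", "[NX3][OX2H]"),
)

_REACTION_C_PATTERNS = (
    ("aldehyde", "[CX3H1]=[OX1]"),
    ("ketone", "[#6][CX3](=[OX1])[#6]"),
)


def default_registry() -> list[Reaction]:
    """The three shipped derivatization reactions, in id order.

    Delta masses are computed from the net elemental changes, never stored:
    121.0197 (A), 170.0480 (B), 15.0109 (C) at 4 dp.  Reaction A carries the
    5% minimum conversion-yield cut used to refine electrophile calls; B and
    C apply no yield cut.
    """
    return [
        Reaction(
            id="A",
            reagent="cysteine",
            net_change=parse_formula("C3H7NO2S"),
            patterns=_REACTION_A_PATTERNS,
            min_yield_pct=5.0,
        ),
        Reaction(
            id="B",
            reagent="AQC",
            net_change=parse_formula("C10H6N2O"),
            patterns=_REACTION_B_PATTERNS,
        ),
        Reaction(
            id="C",
            reagent="hydroxylamine",
            net_change=parse_formula("+NH2OH-H2O"),
            patterns=_REACTION_C_PATTERNS,
        ),
    ]


def registry_by_id(registry: list[Reaction]) -> dict[str, Reaction]:
    by_id = {r.id: r for r in registry}
    if len(by_id) != len(registry):
        raise ChemError("duplicate reaction ids in registry")
    return by_id


def simulate_reactivity(
    structure: str, registry: list[Reaction], structure_id: str | None = None
) -> list[ReactivityPrediction]:
    """Predict which reactions label a structure, from its SMARTS hits alone.

    This is the error-free in-silico chemistry used for validation and for
    planted-truth fixtures: a reaction is predicted iff at least one of its
    reactive-group patterns is present.  Unreactive structures yield an
    empty list.
    """
    sid = structure_id if structure_id is not None else structure
    predictions = []
    for reaction in registry:
        labels, hits = [], []
        for label, smarts in reaction.patterns:
            if match_substructure(structure, smarts) > 0:
                labels.append(label)
                hits.append(smarts)
        if labels:
            predictions.append(
                ReactivityPrediction(sid, reaction.id, tuple(labels), tuple(hits))
            )
    return predictions


def classify_observation(
    observed: set[str],
    predictions: list[ReactivityPrediction],
    registry: list[Reaction] | None = None,
    structure_id: str = "",
) -> list[ValidationCall]:
    """Four-cell truth table per reaction: observed vs. predicted reactivity.

    A metabolite that reacted but has no reactive substructure in its known
    structure is a *false positive*; a predicted-but-unobserved reaction is
    a *false negative*.  Output covers every registry reaction exactly once.
    """
    registry = registry if registry is not None else default_registry()
    ids = [r.id for r in registry]
    unknown = observed - set(ids)
    if unknown:
        raise ChemError(f"unknown reaction ids in observed set: {sorted(unknown)}")
    predicted = {p.reaction_id for p in predictions}
    calls = []
    for rid in ids:
        if rid in observed:
            call = Call.TRUE_POSITIVE if rid in predicted else Call.FALSE_POSITIVE
        else:
            call = Call.FALSE_NEGATIVE if rid in predicted else Call.TRUE_NEGATIVE
        calls.append(ValidationCall(structure_id, rid, call))
    return calls


@dataclass(frozen=True)
class ReactivitySummary:
    n_true_positive: int
    n_false_positive: int
    n_false_negative: int
    n_true_negative: int
    fp_rate_pct: float | None  # FP/(TP+FP)*100, None when no events detected

    @property
    def n_detected_events(self) -> int:
        return self.n_true_positive + self.n_false_positive


def reactivity_summary(calls: list[ValidationCall]) -> ReactivitySummary:
    """Counts plus the false-positive rate among detected derivatization events.

    The rate is FP/(TP+FP), computed in exact rational arithmetic before
    conversion to percent; with no detected events it is reported absent.
    """
    if not calls:
        raise ChemError("reactivity_summary requires at least one call")
    n = {c: 0 for c in Call}
    for vc in calls:
        n[vc.call] += 1
    detected = n[Call.TRUE_POSITIVE] + n[Call.FALSE_POSITIVE]
    rate = (
        float(Fraction(n[Call.FALSE_POSITIVE], detected) * 100) if detected else None
    )
    return ReactivitySummary(
        n_true_positive=n[Call.TRUE_POSITIVE],
        n_false_positive=n[Call.FALSE_POSITIVE],
        n_false_negative=n[Call.FALSE_NEGATIVE],
        n_true_negative=n[Call.TRUE_NEGATIVE],
        fp_rate_pct=rate,
    )
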