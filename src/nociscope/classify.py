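"""Functional categories and transcriptomic class decoding.

Functional category: a cell responding only to heat (or only to mechanical
stimuli) is heat- (mechano-) tuned; a cell responding to both is polymodal
if the ratio between its mechanical and thermal response magnitudes lies
strictly inside the (1:5, 5:1) band, otherwise it takes the dominant
modality; a cell responding to neither is a non-responder.

Transcriptomic class: per-cell ternary expression calls (negative / weak /
strong) over an eleven-gene marker panel are decoded to one of ten sensory
neuron classes by an ordered first-match rule table.  The default table
shipped here is a documented, editable stand-in anchored to well-established
markers (Mrgprd -> NP1, Mlc1 -> NP2B, Nppb+Sst -> NP3, Trpm8 -> TRPM8,
Calca/Trpv1 -> PEP, S100b -> myelinated classes) and is flagged provisional
in its metadata; users studying real recordings should load their own table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

#: the ten sensory-neuron classes, in canonical display order
CLASSES = (
    "Abeta-LTMR",
    "Adelta-LTMR",
    "C-LTMR",
    "TRPM8",
    "Adelta-NOC",
    "PEP",
    "NP1",
    "NP2A",
    "NP2B",
    "NP3",
)
UNCLASSIFIED = "unclassified"

#: marker-gene panel probed by multiplexed ISH
PANEL = (
    "Trpm8",
    "S100b",
    "Fxyd2",
    "Scn10a",
    "Calca",
    "Trpv1",
    "Tmem233",
    "Mrgprd",
    "Nppb",
    "Sst",
    "Mlc1",
)
LEVELS = ("negative", "weak", "strong")
#: shorthand accepted in rule files -> set of matching levels
LEVEL_SETS = {
    "negative": frozenset({"negative"}),
    "weak": frozenset({"weak"}),
    "strong": frozenset({"strong"}),
    "positive": frozenset({"weak", "strong"}),
}


class RuleTableError(ValueError):
    """Raised when a rule table is malformed or inconsistent with the panel."""


class CategoryError(ValueError):
    """Raised when functional category cannot be determined from the records."""


# ---------------------------------------------------------------------------
# functional category
# ---------------------------------------------------------------------------

HEAT_TUNED = "heat_tuned"
MECHANO_TUNED = "mechano_tuned"
POLYMODAL = "polymodal"
NON_RESPONDER = "non_responder"

#: polymodality band: mech/heat magnitude ratio strictly inside (1/5, 5)
POLYMODAL_RATIO_BOUND = 5.0


@dataclass(frozen=True)
class FunctionalCategory:
    category: str
    brush_cell: bool
    heat_max: float
    mech_max: float


def categorize(heat_max: float, mech_max: float, ratio_bound: float = POLYMODAL_RATIO_BOUND) -> str:
    """Category from the maximal responsive magnitudes of each modality.

    Equality with the bound (a ratio of exactly 5:1 or 1:5) is *not*
    polymodal; the dominant modality wins.
    """
    if heat_max < 0 or mech_max < 0:
        raise CategoryError("magnitudes must be >= 0")
    if heat_max == 0 and mech_max == 0:
        return NON_RESPONDER
    if heat_max == 0:
        return MECHANO_TUNED
    if mech_max == 0:
        return HEAT_TUNED
    ratio = mech_max / heat_max
    if 1.0 / ratio_bound < ratio < ratio_bound:
        return POLYMODAL
    return MECHANO_TUNED if ratio >= ratio_bound else HEAT_TUNED


def functional_category(
    heat_records: Sequence,
    mech_records: Sequence,
    brush_records: Sequence | None = None,
    magnitude: str = "amplitude",
    ratio_bound: float = POLYMODAL_RATIO_BOUND,
) -> FunctionalCategory:
    """Assign a functional category from scored response records.

    ``magnitude`` selects the quantity entering the ratio rule: the maximal
    responsive peak ``amplitude`` (default) or ``auc``.  Both modalities must
    have been stimulated; raises :class:`CategoryError` otherwise (a missing
    modality is untestable, not a zero).
    """
    if magnitude not in ("amplitude", "auc"):
        raise CategoryError(f"unknown magnitude {magnitude!r}; use 'amplitude' or 'auc'")
    if not heat_records or not mech_records:
        raise CategoryError("both heat and mechanical stimuli must be scored")
    key = (lambda r: r.peak_amplitude) if magnitude == "amplitude" else (lambda r: r.auc)
    heat_max = max((key(r) for r in heat_records if r.responsive), default=0.0)
    mech_max = max((key(r) for r in mech_records if r.responsive), default=0.0)
    brush_cell = False
    if brush_records:
        locked = sum(1 for r in brush_records if r.time_locked)
        brush_cell = locked / len(brush_records) >= 0.5
    return FunctionalCategory(
        category=categorize(heat_max, mech_max, ratio_bound),
        brush_cell=brush_cell,
        heat_max=float(heat_max),
        mech_max=float(mech_max),
    )


# ---------------------------------------------------------------------------
# transcriptomic decoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rule:
    """One decoding rule: all ``require`` levels must match, no ``forbid`` may."""

    label: str
    require: Mapping[str, frozenset]
    forbid: Mapping[str, frozenset] = field(default_factory=dict)

    def genes(self) -> set[str]:
        return set(self.require) | set(self.forbid)


@dataclass
class ClassRuleTable:
    """Ordered first-match decoder from expression calls to class labels."""

    rules: list[Rule]
    panel: tuple[str, ...] = PANEL
    provisional: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for rule in self.rules:
            if rule.label not in CLASSES:
                raise RuleTableError(
                    f"rule label {rule.label!r} not a known class; valid: {CLASSES}"
                )
            for gene in rule.genes():
                if gene not in self.panel:
                    raise RuleTableError(f"rule {rule.label!r} references {gene!r}, not in panel")
            for mapping in (rule.require, rule.forbid):
                for gene, levels in mapping.items():
                    if not levels or not levels <= set(LEVELS):
                        raise RuleTableError(
                            f"rule {rule.label!r}: bad level set {set(levels)} for {gene!r}"
                        )

    def decode(self, calls: Mapping[str, str]) -> str:
        """First matching rule's label; no match -> unclassified.

        A gene absent from ``calls`` is untested.  If a rule cannot be
        decided because a diagnostic gene is untested (and no tested gene
        already rules it out), the cell is conservatively unclassified.
        """
        for gene, level in calls.items():
            if level not in LEVELS:
                raise RuleTableError(f"bad expression call {level!r} for {gene!r}")
        for rule in self.rules:
            failed = False
            undecidable = False
            for gene, levels in rule.require.items():
                if gene not in calls:
                    undecidable = True
                elif calls[gene] not in levels:
                    failed = True
                    break
            if not failed:
                for gene, levels in rule.forbid.items():
                    if gene not in calls:
                        undecidable = True
                    elif calls[gene] in levels:
                        failed = True
                        break
            if failed:
                continue
            if undecidable:
                return UNCLASSIFIED
            return rule.label
        return UNCLASSIFIED

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def levels_repr(levels: frozenset) -> str:
            for name, s in LEVEL_SETS.items():
                if s == levels:
                    return name
            return "|".join(sorted(levels))

        return {
            "panel": list(self.panel),
            "provisional": self.provisional,
            "rules": [
                {
                    "label": r.label,
                    "require": {g: levels_repr(s) for g, s in r.require.items()},
                    **({"forbid": {g: levels_repr(s) for g, s in r.forbid.items()}} if r.forbid else {}),
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassRuleTable":
        def parse_levels(spec: str) -> frozenset:
            if spec in LEVEL_SETS:
                return LEVEL_SETS[spec]
            parts = frozenset(spec.split("|"))
            if not parts <= set(LEVELS):
                raise RuleTableError(f"bad level spec {spec!r}")
            return parts

        rules = [
            Rule(
                label=r["label"],
                require={g: parse_levels(s) for g, s in r.get("require", {}).items()},
                forbid={g: parse_levels(s) for g, s in r.get("forbid", {}).items()},
            )
            for r in d["rules"]
        ]
        return cls(
            rules=rules,
            panel=tuple(d.get("panel", PANEL)),
            provisional=bool(d.get("provisional", True)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ClassRuleTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def decode_class(calls: Mapping[str, str], table: ClassRuleTable) -> str:
    """Decode one cell's expression calls to a class label (first match)."""
    return table.decode(calls)


# canonical full-panel expression pattern of each class; genes not listed are
# negative.  These drive the synthetic expression generator and the default
# rule table's self-consistency.
CANONICAL_PATTERNS: dict[str, dict[str, str]] = {
    "Abeta-LTMR": {"S100b": "strong"},
    "Adelta-LTMR": {"S100b": "strong", "Fxyd2": "strong"},
    "C-LTMR": {"Fxyd2": "strong", "Scn10a": "weak"},
    "TRPM8": {"Trpm8": "strong"},
    "Adelta-NOC": {"S100b": "strong", "Scn10a": "strong", "Calca": "weak"},
    "PEP": {"Calca": "strong", "Trpv1": "strong", "Scn10a": "strong"},
    "NP1": {"Mrgprd": "strong", "Scn10a": "strong", "Tmem233": "weak"},
    "NP2A": {"Tmem233": "strong", "Calca": "weak", "Scn10a": "strong"},
    "NP2B": {"Mlc1": "strong", "Scn10a": "strong"},
    "NP3": {"Nppb": "strong", "Sst": "strong", "Scn10a": "strong", "Trpv1": "weak"},
}


def canonical_pattern(class_label: str, panel: Sequence[str] = PANEL) -> dict[str, str]:
    """Full-panel calls for a class: the canonical pattern padded with negatives."""
    if class_label not in CANONICAL_PATTERNS:
        raise RuleTableError(f"unknown class {class_label!r}; valid: {CLASSES}")
    base = CANONICAL_PATTERNS[class_label]
    return {g: base.get(g, "negative") for g in panel}


def default_rule_table() -> ClassRuleTable:
    """The shipped provisional decoder (ordered, most specific first)."""
    R = LEVEL_SETS
    rules = [
        Rule("NP3", {"Nppb": R["strong"], "Sst": R["strong"]}),
        Rule("NP2B", {"Mlc1": R["strong"]}),
        Rule("NP1", {"Mrgprd": R["strong"]}),
        Rule("TRPM8", {"Trpm8": R["strong"]}),
        Rule("NP2A", {"Tmem233": R["strong"]}, {"Mrgprd": R["strong"]}),
        Rule("PEP", {"Calca": R["strong"], "Trpv1": R["positive"]}),
        Rule("Adelta-NOC", {"S100b": R["positive"], "Scn10a": R["strong"]}),
        Rule("Adelta-LTMR", {"S100b": R["positive"], "Fxyd2": R["positive"]}),
        Rule("Abeta-LTMR", {"S100b": R["positive"]}),
        Rule("C-LTMR", {"Fxyd2": R["strong"]}),
    ]
    return ClassRuleTable(rules=rules, panel=PANEL, provisional=True)
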