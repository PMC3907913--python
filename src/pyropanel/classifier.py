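"""Evidence-combination classification of candidate variants.

Candidates surviving prioritization are graded on a six-step scale —
``Neutral < UV1 < UV2 < UV3 < UV4 < Pathogenic`` — where UV1 is a
variant of unknown clinical significance least likely, and UV4 most
likely, to be disease causing. The evidence lines mirror the usual
contributors of a diagnostic lab's multistep scheme:

a. protein translation predicts a premature termination codon (PTC);
b. allele frequency in public databases or laboratory controls;
c. allele frequency in patients;
d. in silico missense predictions;
e. in silico splice-site predictions;
f. minigene (ex vivo splicing) assay;
g. familial segregation;
h. patient genotype context (e.g. in trans with a pathogenic allele).

Because laboratories weight these lines differently, the combination
logic is an ordered, first-match rule table over an
:class:`EvidenceVector`, shipped with sensible defaults and fully
user-overridable from YAML. In silico scores enter as opaque numbers in
[0, 1] (higher = more damaging); the predictors themselves are outside
this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Any, Sequence

import yaml

log = logging.getLogger(__name__)

#: Severity order, least to most likely disease causing.
CLASS_ORDER = ("Neutral", "UV1", "UV2", "UV3", "UV4", "Pathogenic")
CLASS_RANK = {c: i for i, c in enumerate(CLASS_ORDER)}


class ClassificationError(ValueError):
    pass


class RuleTableError(ValueError):
    pass


@dataclass(frozen=True)
class EvidenceVector:
    """Quantitative evidence for one variant. ``None`` marks unknown."""

    ptc: bool | None = None
    control_af: float | None = None
    patient_af: float | None = None
    missense_score: float | None = None  # in [0,1], higher = more damaging
    splice_delta: float | None = None  # in [0,1], higher = stronger splice impact
    minigene_result: str | None = None  # deleterious | neutral
    segregation_consistent: str | None = None  # yes | no
    genotype_context: str | None = None  # supports | conflicts

    def is_all_unknown(self) -> bool:
        return all(getattr(self, f.name) is None for f in dc_fields(self))


_FIELD_NAMES = {f.name for f in dc_fields(EvidenceVector)}
_OPS = {
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
    "in": lambda a, b: a in b,
}


@dataclass(frozen=True)
class Condition:
    field_name: str
    op: str
    value: Any
    allow_unknown: bool = False

    def matches(self, ev: EvidenceVector) -> bool:
        actual = getattr(ev, self.field_name)
        if actual is None:
            return self.allow_unknown
        return _OPS[self.op](actual, self.value)


@dataclass(frozen=True)
class Rule:
    name: str
    conditions: tuple[Condition, ...]
    klass: str

    def matches(self, ev: EvidenceVector) -> bool:
        return all(c.matches(ev) for c in self.conditions)

    @property
    def is_default(self) -> bool:
        return not self.conditions


@dataclass
class ClassRule:
    """Ordered first-match rule table; must end in a catch-all default."""

    rules: list[Rule] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not any(r.is_default for r in self.rules):
            raise RuleTableError(
                "rule table is not total: no default (empty-when) rule; "
                "an evidence vector matching no rule would be unclassifiable"
            )
        default_idx = next(i for i, r in enumerate(self.rules) if r.is_default)
        unreachable = [r.name for r in self.rules[default_idx + 1 :]]
        if unreachable:
            log.warning("unreachable rules after the default: %s", unreachable)
        seen: dict[tuple, str] = {}
        for r in self.rules:
            sig = tuple(sorted((c.field_name, c.op, repr(c.value)) for c in r.conditions))
            if sig in seen and seen[sig] != r.klass:
                log.warning(
                    "rules with identical predicates and different classes; "
                    "first match (%s) wins over %s",
                    seen[sig],
                    r.name,
                )
            seen.setdefault(sig, r.klass)

    @property
    def default_class(self) -> str:
        return next(r.klass for r in self.rules if r.is_default)


def classify(ev: EvidenceVector, rules: ClassRule) -> str:
    """Deterministic class of one evidence vector under a rule table."""
    if ev.is_all_unknown():
        raise ClassificationError("cannot classify an all-unknown evidence vector")
    for rule in rules.rules:
        if rule.matches(ev):
            return rule.klass
    raise ClassificationError("non-total rule table")  # unreachable post-validation


def _parse_condition(field_name: str, spec: Any) -> Condition:
    if field_name not in _FIELD_NAMES:
        raise RuleTableError(f"unknown evidence field {field_name!r}")
    if not isinstance(spec, dict):
        return Condition(field_name, "eq", spec)
    spec = dict(spec)
    allow_unknown = bool(spec.pop("allow_unknown", False))
    if len(spec) != 1:
        raise RuleTableError(
            f"condition on {field_name!r} must name exactly one operator"
        )
    op, value = next(iter(spec.items()))
    if op not in _OPS:
        raise RuleTableError(f"unknown operator {op!r}")
    return Condition(field_name, op, value, allow_unknown)


def parse_rules(doc: dict) -> ClassRule:
    raw_rules = doc.get("rules")
    if not isinstance(raw_rules, list) or not raw_rules:
        raise RuleTableError("rule file must contain a non-empty 'rules' list")
    rules: list[Rule] = []
    for i, entry in enumerate(raw_rules):
        klass = entry.get("class")
        if klass not in CLASS_ORDER:
            raise RuleTableError(f"rule {i}: class {klass!r} not in {CLASS_ORDER}")
        when = entry.get("when", {}) or {}
        conditions = tuple(_parse_condition(f, s) for f, s in when.items())
        rules.append(Rule(entry.get("name", f"rule_{i}"), conditions, klass))
    return ClassRule(rules)


def load_rules(path: str | Path) -> ClassRule:
    """Load a YAML rule table; aborts on a non-total or malformed table."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return parse_rules(doc)


def default_rules() -> ClassRule:
    """The shipped default table (see ``data/default_rules.yaml``)."""
    text = resources.files("pyropanel").joinpath("data/default_rules.yaml").read_text()
    return parse_rules(yaml.safe_load(text))


def classify_all(
    vectors: Sequence[tuple[Any, EvidenceVector]], rules: ClassRule | None = None
) -> list[tuple[Any, str]]:
    """Classify (key, evidence) pairs, returning (key, class) pairs."""
    table = rules if rules is not None else default_rules()
    return [(key, classify(ev, table)) for key, ev in vectors]
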