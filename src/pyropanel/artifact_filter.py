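"""Automated artifact removal for raw pyrosequencing variant calls.

Three independent, composable predicates remove the bulk of raw-call
noise before any human looks at the data:

i.   **Allele-fraction rule** — calls supported by less than 20% of the
     total reads at the site are removed (low-fraction noise).
ii.  **Strand-disequilibrium rule** — indels with more than 20
     supporting reads whose forward or reverse share of that support
     falls below 10% are removed. One-sided indel evidence next to
     homopolymer tracts is the signature error mode of pyrosequencing.
iii. **Distance rule** — indels more than 20 intronic bases away from
     the nearest exon boundary are removed (deep-intronic indel noise).

All boundaries are strict exactly as worded: a call at exactly 20% VAF
passes rule i, an indel with exactly 20 supporting reads is exempt from
rule ii, an indel with exactly 10% minor-strand fraction passes rule ii,
and an indel exactly 20 bp from an exon passes rule iii. SNVs are never
touched by rules ii and iii (deep-intronic SNVs are handled later, at
prioritization). The rules commute: verdicts do not depend on the order
of application.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

from pyropanel.variant_model import AnnotatedVariant

log = logging.getLogger(__name__)

RuleName = Literal["vaf", "strand", "distance"]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the three artifact rules.

    ``strand_denominator`` selects whether "coverage >20 reads" gates
    rule ii on the variant-supporting reads (default: the sequences
    exhibiting the disequilibrium) or on the total site depth.
    """

    min_vaf: float = 0.20
    strand_min_depth: int = 20
    strand_min_fraction: float = 0.10
    max_exon_distance: float = 20
    strand_denominator: Literal["variant_reads", "total_depth"] = "variant_reads"


DEFAULT_CONFIG = FilterConfig()


@dataclass
class FilterVerdict:
    passed: bool
    failed_rules: frozenset[RuleName] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.failed_rules = frozenset(self.failed_rules)
        assert self.passed == (not self.failed_rules)


def vaf_rule(v: AnnotatedVariant, min_fraction: float = 0.20) -> bool:
    """Allele-fraction rule: True (pass) unless VAF < ``min_fraction``.

    Zero-depth records fail (degenerate, logged).
    """
    if v.call.depth_total == 0:
        log.warning("zero-depth record %s fails the allele-fraction rule", v.key)
        return False
    return v.vaf >= min_fraction


def strand_rule(
    v: AnnotatedVariant,
    min_depth: int = 20,
    min_strand_fraction: float = 0.10,
    denominator: Literal["variant_reads", "total_depth"] = "variant_reads",
) -> bool:
    """Strand-disequilibrium rule for indels.

    Fails only when the depth gate is exceeded (strictly more than
    ``min_depth`` reads) AND the minor strand carries less than
    ``min_strand_fraction`` of the variant-supporting reads. SNVs,
    shallow indels and records without strand counts pass.
    """
    if not v.call.is_indel:
        return True
    if v.call.reads_fwd is None:
        log.debug("strand counts unknown for %s; strand rule passes", v.key)
        return True
    gate = (
        v.call.reads_variant
        if denominator == "variant_reads"
        else v.call.depth_total
    )
    if gate <= min_depth:
        return True
    if v.call.reads_variant == 0:
        return True
    minor = min(v.call.reads_fwd, v.call.reads_rev)
    return minor / v.call.reads_variant >= min_strand_fraction


def distance_rule(v: AnnotatedVariant, max_distance: float = 20) -> bool:
    """Deep-intronic indel rule: indels strictly more than ``max_distance``
    bases from the nearest exon boundary fail. SNVs always pass here."""
    if not v.call.is_indel:
        return True
    return v.exon_distance <= max_distance


def evaluate(v: AnnotatedVariant, config: FilterConfig = DEFAULT_CONFIG) -> FilterVerdict:
    """Apply all three rules to one variant; rules are order-independent."""
    failed: set[RuleName] = set()
    if not vaf_rule(v, config.min_vaf):
        failed.add("vaf")
    if not strand_rule(
        v, config.strand_min_depth, config.strand_min_fraction, config.strand_denominator
    ):
        failed.add("strand")
    if not distance_rule(v, config.max_exon_distance):
        failed.add("distance")
    return FilterVerdict(passed=not failed, failed_rules=frozenset(failed))


def apply_artifact_filters(
    variants: Sequence[AnnotatedVariant],
    config: FilterConfig = DEFAULT_CONFIG,
) -> tuple[list[AnnotatedVariant], list[tuple[AnnotatedVariant, FilterVerdict]]]:
    """Split a call set into retained calls and removed artifacts.

    Returns ``(retained, removed)`` where ``removed`` pairs each
    rejected variant with its verdict (at least one failed rule).
    Retained and removed partition the input.
    """
    retained: list[AnnotatedVariant] = []
    removed: list[tuple[AnnotatedVariant, FilterVerdict]] = []
    for v in variants:
        verdict = evaluate(v, config)
        if verdict.passed:
            retained.append(v)
        else:
            removed.append((v, verdict))
    log.info(
        "artifact filtering: %d raw, %d retained, %d removed",
        len(variants),
        len(retained),
        len(removed),
    )
    return retained, removed


def failure_histogram(
    removed: Sequence[tuple[AnnotatedVariant, FilterVerdict]],
) -> dict[str, int]:
    """Count rule failures across removed variants (a variant failing two
    rules counts once in each bucket)."""
    hist = {"vaf": 0, "strand": 0, "distance": 0}
    for _, verdict in removed:
        for rule in verdict.failed_rules:
            hist[rule] += 1
    return hist
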