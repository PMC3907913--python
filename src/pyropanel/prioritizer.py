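"""Cohort-based prioritization of filtered variants.

After artifact filtering, candidates are selected by two rules applied
to every variant of unknown clinical significance (VUCS):

* keep only variants found in **fewer than five DNAs** of the cohort
  (recurrent variants are almost always polymorphisms or residual
  systematic artifacts), and
* keep only variants located in an exon or within the **20 bp**
  intron–exon boundary window (this time SNVs included).

Known pathogenic variants from the whitelist are always kept,
regardless of cohort frequency or location. One DNA counts once toward
a variant's cohort tally regardless of zygosity or duplicate rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

from pyropanel.variant_model import AnnotatedVariant, VariantCall

log = logging.getLogger(__name__)

MaskReason = Literal["cohort_frequent", "deep_intronic"]

#: "fewer than five DNAs": keep when seen in at most this many cohort DNAs.
DEFAULT_MAX_COHORT_DNA = 4
#: Retention window around exons, in intronic bases.
DEFAULT_MAX_EXON_DISTANCE = 20


@dataclass
class CohortIndex:
    """Per-variant count of distinct cohort DNAs carrying it."""

    counts: dict[tuple[str, int, str, str], int]
    n_patients: int

    def __post_init__(self) -> None:
        bad = {k: c for k, c in self.counts.items() if not 1 <= c <= self.n_patients}
        if bad:
            raise ValueError(f"cohort counts outside [1, n_patients]: {bad}")

    def get(self, key: tuple[str, int, str, str]) -> int:
        return self.counts.get(key, 0)


def build_cohort_index(
    call_tables: Sequence[Sequence[VariantCall]],
) -> CohortIndex:
    """Index a cohort of per-patient call tables.

    Each patient contributes at most one count to any variant key,
    however many times the variant appears in their table (homozygous
    representations, duplicate rows). Duplicate patient ids abort.
    """
    patient_ids = [t[0].patient_id for t in call_tables if t]
    if len(set(patient_ids)) != len(patient_ids):
        raise ValueError("duplicate patient_id across call tables")
    counts: dict[tuple[str, int, str, str], int] = {}
    for table in call_tables:
        seen: set[tuple[str, int, str, str]] = set()
        for call in table:
            if call.key not in seen:
                seen.add(call.key)
                counts[call.key] = counts.get(call.key, 0) + 1
    return CohortIndex(counts=counts, n_patients=len(call_tables))


@dataclass
class MaskedVariant:
    variant: AnnotatedVariant
    reasons: frozenset[MaskReason] = field(default_factory=frozenset)


def prioritize(
    variants: Sequence[AnnotatedVariant],
    index: CohortIndex | None = None,
    max_cohort_dna: int = DEFAULT_MAX_COHORT_DNA,
    max_exon_distance: float = DEFAULT_MAX_EXON_DISTANCE,
) -> tuple[list[AnnotatedVariant], list[MaskedVariant]]:
    """Split filtered variants into candidates and masked variants.

    A variant is a candidate iff it is whitelisted as known pathogenic,
    or it is carried by at most ``max_cohort_dna`` cohort DNAs AND lies
    within ``max_exon_distance`` bases of an exon. The cohort count used
    is the annotated one unless a (fresher) index is supplied.
    """
    candidates: list[AnnotatedVariant] = []
    masked: list[MaskedVariant] = []
    for v in variants:
        if v.known_pathogenic:
            candidates.append(v)
            continue
        count = index.get(v.key) if index is not None else v.cohort_count
        reasons: set[MaskReason] = set()
        if count > max_cohort_dna:
            reasons.add("cohort_frequent")
        if v.exon_distance > max_exon_distance:
            reasons.add("deep_intronic")
        if reasons:
            masked.append(MaskedVariant(v, frozenset(reasons)))
        else:
            candidates.append(v)
    return candidates, masked


@dataclass
class StageCounts:
    """Per-patient accounting of the pipeline funnel."""

    patient_id: str
    n_raw: int
    n_post_filter: int
    n_candidates: int

    def __post_init__(self) -> None:
        if not self.n_raw >= self.n_post_filter >= self.n_candidates >= 0:
            raise ValueError(
                f"stage counts must be non-increasing: "
                f"{self.n_raw} -> {self.n_post_filter} -> {self.n_candidates}"
            )

    def as_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "raw": self.n_raw,
            "post_filter": self.n_post_filter,
            "candidates": self.n_candidates,
        }


def stage_counts(
    patient_id: str,
    raw: Sequence,
    post_filter: Sequence,
    post_prioritize: Sequence,
) -> StageCounts:
    """Build the funnel record for one patient's pipeline run."""
    return StageCounts(
        patient_id=patient_id,
        n_raw=len(raw),
        n_post_filter=len(post_filter),
        n_candidates=len(post_prioritize),
    )


def cohort_means(records: Sequence[StageCounts]) -> dict[str, float]:
    """Cohort-mean stage counts plus the overall retention fraction."""
    if not records:
        return {"raw": 0.0, "post_filter": 0.0, "candidates": 0.0}
    n = len(records)
    raw = sum(r.n_raw for r in records) / n
    post = sum(r.n_post_filter for r in records) / n
    cand = sum(r.n_candidates for r in records) / n
    out = {"raw": raw, "post_filter": post, "candidates": cand}
    if raw:
        out["filter_removal_fraction"] = (raw - post) / raw
        out["candidate_fraction"] = cand / raw
    return out
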