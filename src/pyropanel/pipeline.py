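"""One-shot pipeline orchestration and the machine-readable run report.

``run_pipeline`` chains annotation, artifact filtering and cohort
prioritization over a set of per-patient call tables and assembles a
:class:`RunReport`: per-patient stage counts (raw -> post-filter ->
candidates), cohort means, the filter-failure histogram, optional
per-gene coverage, and a config echo sufficient to reproduce the run.
Timestamps and hostnames are deliberately absent so that two runs with
the same inputs produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from pyropanel import __version__
from pyropanel.artifact_filter import (
    FilterConfig,
    FilterVerdict,
    apply_artifact_filters,
    failure_histogram,
)
from pyropanel.coverage_qc import CoverageProfile, CoverageSummary, summarize_coverage
from pyropanel.panel_model import PanelDesign
from pyropanel.prioritizer import (
    CohortIndex,
    MaskedVariant,
    StageCounts,
    build_cohort_index,
    cohort_means,
    prioritize,
    stage_counts,
)
from pyropanel.variant_model import AnnotatedVariant, VariantCall, annotate_all

log = logging.getLogger(__name__)


@dataclass
class PatientResult:
    patient_id: str
    raw: list[VariantCall]
    annotated: list[AnnotatedVariant]
    retained: list[AnnotatedVariant]
    removed: list[tuple[AnnotatedVariant, FilterVerdict]]
    candidates: list[AnnotatedVariant]
    masked: list[MaskedVariant]
    counts: StageCounts


@dataclass
class RunReport:
    seed: int | None
    config: dict
    version: str
    patients: list[StageCounts]
    means: dict[str, float]
    filter_failures: dict[str, int]
    adoc_by_gene: dict[str, float] = field(default_factory=dict)
    low_coverage_regions: list[dict] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "patients": [p.as_dict() for p in self.patients],
            "cohort_means": self.means,
            "filter_failure_histogram": self.filter_failures,
            "adoc_by_gene": self.adoc_by_gene,
            "low_coverage_regions": self.low_coverage_regions,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2, sort_keys=True)


def run_pipeline(
    design: PanelDesign,
    calls_by_patient: Mapping[str, Sequence[VariantCall]],
    whitelist: Mapping | set | None = None,
    cohort_index: CohortIndex | None = None,
    filter_config: FilterConfig | None = None,
    max_cohort_dna: int = 4,
    coverage_profiles: Sequence[CoverageProfile] | None = None,
    seed: int | None = None,
) -> tuple[RunReport, dict[str, PatientResult]]:
    """Run annotate -> filter -> prioritize for every patient.

    When ``cohort_index`` is None the index is rebuilt from the input
    tables themselves (the run's patients are the masking background);
    passing a frozen index reproduces diagnostic mode, where new
    patients are masked against a reference cohort.
    """
    cfg = filter_config or FilterConfig()
    index = cohort_index or build_cohort_index(list(calls_by_patient.values()))
    results: dict[str, PatientResult] = {}
    all_removed: list[tuple[AnnotatedVariant, FilterVerdict]] = []
    for pid, raw in calls_by_patient.items():
        annotated = annotate_all(list(raw), design, whitelist, index)
        retained, removed = apply_artifact_filters(annotated, cfg)
        candidates, masked = prioritize(retained, index, max_cohort_dna)
        counts = stage_counts(pid, raw, retained, candidates)
        results[pid] = PatientResult(
            pid, list(raw), annotated, retained, removed, candidates, masked, counts
        )
        all_removed.extend(removed)
    summary: CoverageSummary | None = None
    if coverage_profiles is not None:
        summary = summarize_coverage(coverage_profiles)
    report = RunReport(
        seed=seed,
        config={
            **dataclasses.asdict(cfg),
            "max_cohort_dna": max_cohort_dna,
            "cohort_mode": "frozen" if cohort_index is not None else "rebuild",
            "n_patients": len(calls_by_patient),
        },
        version=__version__,
        patients=[r.counts for r in results.values()],
        means=cohort_means([r.counts for r in results.values()]),
        filter_failures=failure_histogram(all_removed),
        adoc_by_gene=(
            {g: round(a, 4) for g, a in summary.adoc_by_gene.items()} if summary else {}
        ),
        low_coverage_regions=(
            [
                {
                    "chrom": f.region.chrom,
                    "start": f.region.start,
                    "end": f.region.end,
                    "gene": f.region.gene,
                    "adoc": round(f.adoc, 4),
                    "gc_flag": f.gc_flag,
                }
                for f in summary.low_coverage_regions
            ]
            if summary
            else []
        ),
    )
    return report, results


ANNOT_COLUMNS = (
    "patient_id\tchrom\tpos\tref\talt\tvtype\tdepth_total\treads_variant\t"
    "reads_fwd\treads_rev\tvaf\tgene\texon_distance\tlocation_class\t"
    "known_pathogenic\tcohort_count"
)


def _annot_row(v: AnnotatedVariant) -> str:
    c = v.call
    dist = "inf" if v.exon_distance == float("inf") else str(int(v.exon_distance))
    return (
        f"{c.patient_id}\t{c.chrom}\t{c.pos}\t{c.ref}\t{c.alt}\t{c.vtype}\t"
        f"{c.depth_total}\t{c.reads_variant}\t"
        f"{c.reads_fwd if c.reads_fwd is not None else '.'}\t"
        f"{c.reads_rev if c.reads_rev is not None else '.'}\t"
        f"{c.vaf:.4f}\t{v.gene or '.'}\t{dist}\t{v.location_class}\t"
        f"{int(v.known_pathogenic)}\t{v.cohort_count}"
    )


def write_outputs(results: Mapping[str, PatientResult], out_dir: str | Path) -> None:
    """Candidates and masked/removed TSVs per patient, with reasons."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pid, res in results.items():
        with open(out / f"{pid}.candidates.tsv", "w") as fh:
            fh.write(ANNOT_COLUMNS + "\n")
            for v in res.candidates:
                fh.write(_annot_row(v) + "\n")
        with open(out / f"{pid}.excluded.tsv", "w") as fh:
            fh.write(ANNOT_COLUMNS + "\tstage\treasons\n")
            for v, verdict in res.removed:
                fh.write(
                    _annot_row(v)
                    + "\tartifact_filter\t"
                    + ",".join(sorted(verdict.failed_rules))
                    + "\n"
                )
            for m in res.masked:
                fh.write(
                    _annot_row(m.variant)
                    + "\tprioritization\t"
                    + ",".join(sorted(m.reasons))
                    + "\n"
                )
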