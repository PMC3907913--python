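"""Coverage quality control for a capture design.

Two statistics drive capture QC here:

* **aDOC** — average depth of coverage of a region: the summed per-base
  depth inside the region divided by the region length in bp. Reported
  per region and per gene (length-weighted).
* **On-target fraction** — aligned bases falling inside the merged
  design footprint divided by all mapped bases. This is a base-level
  ratio; the read-level view (on / overlap / off target categories)
  is exposed separately because the two disagree on reads that
  straddle a region boundary.

Regions whose aDOC falls below a validation threshold (40x by default)
are flagged, carrying a GC annotation (fraction > 0.60 by default)
because GC-rich targets are systematically under-captured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from pyropanel.panel_model import PanelDesign, TargetRegion

log = logging.getLogger(__name__)

ReadCategory = Literal["on_target", "overlap_target", "off_target"]

#: Validation depth: regions below this aDOC are considered unreliable.
DEFAULT_DEPTH_THRESHOLD = 40.0
#: GC fraction above which poor capture is attributed to GC content.
DEFAULT_GC_THRESHOLD = 0.60


class CoverageError(ValueError):
    pass


@dataclass
class CoverageProfile:
    """Per-base depths over one design region."""

    region: TargetRegion
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if self.depths.ndim != 1 or len(self.depths) != len(self.region):
            raise CoverageError(
                f"profile for {self.region.chrom}:{self.region.start}-"
                f"{self.region.end} has {len(self.depths)} depths for "
                f"{len(self.region)} bases"
            )
        if (self.depths < 0).any():
            raise CoverageError("negative depth")


@dataclass
class FlaggedRegion:
    region: TargetRegion
    adoc: float
    gc_flag: bool | None  # None when the region carries no GC annotation


@dataclass
class CoverageSummary:
    adoc_by_region: dict[TargetRegion, float]
    adoc_by_gene: dict[str, float]
    on_target_fraction: float | None = None
    overlap_fraction: float | None = None
    off_target_fraction: float | None = None
    low_coverage_regions: list[FlaggedRegion] = field(default_factory=list)

    @property
    def overall_adoc(self) -> float:
        """Length-weighted aDOC across the whole design."""
        total_bases = sum(
            float(a) * len(r) for r, a in self.adoc_by_region.items()
        )
        total_len = sum(len(r) for r in self.adoc_by_region)
        return total_bases / total_len


def compute_adoc(profile: CoverageProfile) -> float:
    """Average depth of coverage: sum of per-base depth over region length."""
    n = len(profile.depths)
    if n == 0:
        raise CoverageError("zero-length region")
    return float(profile.depths.sum()) / n


def gene_adoc(profiles: Sequence[CoverageProfile], gene: str) -> float:
    """Length-weighted mean aDOC over all regions of a gene.

    Equals the aDOC of the concatenation of the gene's regions: total
    sequenced bases over total targeted length.
    """
    mine = [p for p in profiles if p.region.gene == gene]
    if not mine:
        raise KeyError(f"no coverage profiles for gene {gene!r}")
    total = sum(int(p.depths.sum()) for p in mine)
    length = sum(len(p.depths) for p in mine)
    return total / length


def summarize_coverage(
    profiles: Sequence[CoverageProfile],
    depth_threshold: float = DEFAULT_DEPTH_THRESHOLD,
    gc_threshold: float = DEFAULT_GC_THRESHOLD,
    read_intervals: Sequence[tuple[str, int, int]] | None = None,
    design: PanelDesign | None = None,
) -> CoverageSummary:
    """Assemble the full QC summary from per-region profiles.

    Read-level fractions are filled in only when aligned read intervals
    and the design are supplied.
    """
    adoc_by_region = {p.region: compute_adoc(p) for p in profiles}
    genes = {p.region.gene for p in profiles}
    adoc_by_gene = {g: gene_adoc(profiles, g) for g in sorted(genes)}
    summary = CoverageSummary(adoc_by_region, adoc_by_gene)
    if read_intervals is not None and design is not None:
        cats = [classify_read(iv, design) for iv in read_intervals]
        n = len(cats)
        if n:
            summary.on_target_fraction = cats.count("on_target") / n
            summary.overlap_fraction = cats.count("overlap_target") / n
            summary.off_target_fraction = cats.count("off_target") / n
    summary.low_coverage_regions = flag_low_coverage(
        summary, depth_threshold, gc_threshold
    )
    return summary


def classify_read(
    read_interval: tuple[str, int, int], design: PanelDesign
) -> ReadCategory:
    """Read-level target category of one aligned read.

    ``on_target`` iff every aligned base lies in the merged design,
    ``off_target`` iff none does, ``overlap_target`` otherwise. The read
    interval is 0-based half-open.
    """
    chrom, start, end = read_interval
    if start >= end:
        raise CoverageError(f"empty read interval {chrom}:{start}-{end}")
    inside = design.overlap_bases(chrom, start, end)
    if inside == end - start:
        return "on_target"
    if inside == 0:
        return "off_target"
    return "overlap_target"


def on_target_fraction(
    read_intervals: Iterable[tuple[str, int, int]], design: PanelDesign
) -> float:
    """Base-level on-target ratio: aligned bases inside the design over
    all mapped bases. Bases of boundary-straddling reads contribute only
    their in-target portion."""
    in_target = 0
    total = 0
    for chrom, start, end in read_intervals:
        if start >= end:
            raise CoverageError(f"empty read interval {chrom}:{start}-{end}")
        total += end - start
        in_target += design.overlap_bases(chrom, start, end)
    if total == 0:
        raise CoverageError("no mapped bases")
    return in_target / total


def flag_low_coverage(
    summary: CoverageSummary,
    depth_threshold: float = DEFAULT_DEPTH_THRESHOLD,
    gc_threshold: float = DEFAULT_GC_THRESHOLD,
    mode: Literal["adoc", "min_doc"] = "adoc",
    profiles: Sequence[CoverageProfile] | None = None,
) -> list[FlaggedRegion]:
    """Regions covered less than ``depth_threshold`` (strict), ascending by aDOC.

    ``gc_flag`` is True when the region's GC fraction exceeds
    ``gc_threshold``, False when annotated below it, and None when the
    region carries no GC annotation. ``mode="min_doc"`` flags on the
    minimum per-base depth instead of the mean (requires ``profiles``).
    """
    flagged: list[FlaggedRegion] = []
    if mode == "min_doc":
        if profiles is None:
            raise CoverageError("min_doc mode requires per-base profiles")
        stat = {p.region: float(p.depths.min()) for p in profiles}
    else:
        stat = summary.adoc_by_region
    for region, value in stat.items():
        if value < depth_threshold:
            gc_flag = (
                None
                if region.gc_fraction is None
                else region.gc_fraction > gc_threshold
            )
            flagged.append(
                FlaggedRegion(region, summary.adoc_by_region[region], gc_flag)
            )
    flagged.sort(key=lambda f: f.adoc)
    return flagged


def read_depth_track(path: str | Path, design: PanelDesign) -> list[CoverageProfile]:
    """Load per-base depths from a 3-column TSV (chrom, 1-based pos, depth).

    Positions absent from the track are taken as depth 0. Returns one
    profile per design region.
    """
    depth_at: dict[tuple[str, int], int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise CoverageError(f"{path}:{lineno}: expected 3 columns")
            try:
                depth_at[(cols[0], int(cols[1]))] = int(cols[2])
            except ValueError as exc:
                raise CoverageError(f"{path}:{lineno}: non-integer field") from exc
    profiles = []
    for region in design.regions:
        depths = np.array(
            [
                depth_at.get((region.chrom, pos), 0)
                for pos in range(region.start + 1, region.end + 1)
            ],
            dtype=np.int64,
        )
        profiles.append(CoverageProfile(region, depths))
    return profiles


def write_depth_track(profiles: Sequence[CoverageProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in profiles:
            for offset, depth in enumerate(p.depths):
                fh.write(f"{p.region.chrom}\t{p.region.start + 1 + offset}\t{int(depth)}\n")


def pileup_from_reads(
    read_intervals: Iterable[tuple[str, int, int]], design: PanelDesign
) -> list[CoverageProfile]:
    """Per-base pileup of aligned read intervals over the design regions."""
    arrays = {
        r: np.zeros(len(r), dtype=np.int64) for r in design.regions
    }
    by_chrom: dict[str, list[TargetRegion]] = {}
    for r in design.regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, start, end in read_intervals:
        for region in by_chrom.get(chrom, []):
            lo = max(start, region.start)
            hi = min(end, region.end)
            if lo < hi:
                arrays[region][lo - region.start : hi - region.start] += 1
    return [CoverageProfile(r, arrays[r]) for r in design.regions]
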