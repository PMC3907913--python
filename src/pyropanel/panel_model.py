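"""Capture-design model: target regions, merging, positional queries.

Coordinate conventions
----------------------
Design intervals follow BED: 0-based, half-open ``[start, end)``.
Variant positions are VCF-style 1-based. :func:`to_one_based` owns the
conversion; every distance is computed in 1-based space.

A design is a list of :class:`TargetRegion` (one per targeted exon, UTR
or intronic flank, each labelled with its gene) plus the gene-agnostic
``merged_regions`` footprint obtained by collapsing overlapping and
book-ended intervals — the unit in which capture efficiency and
coverage are reported.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

FEATURES = ("exon", "utr", "intronic_extension")

#: Sentinel distance for positions on chromosomes without any exon.
INF_DISTANCE = math.inf


class DesignError(ValueError):
    """Malformed design input (bad coordinates, unparseable BED line)."""


@dataclass(frozen=True)
class TargetRegion:
    """One labelled interval of the capture design (0-based half-open)."""

    chrom: str
    start: int
    end: int
    gene: str
    feature: str = "exon"
    gc_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise DesignError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.feature not in FEATURES:
            raise DesignError(f"unknown feature {self.feature!r}")
        if self.gc_fraction is not None and not (0.0 <= self.gc_fraction <= 1.0):
            raise DesignError(f"gc_fraction {self.gc_fraction} outside [0, 1]")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether the 1-based position ``pos`` falls inside this region."""
        return chrom == self.chrom and self.start < pos <= self.end


@dataclass(frozen=True)
class Interval:
    """Gene-agnostic interval of the merged design footprint."""

    chrom: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """Map a 0-based half-open interval to 1-based inclusive bounds."""
    return start + 1, end


def merge_regions(regions: Sequence[TargetRegion | Interval]) -> list[Interval]:
    """Collapse intervals into a sorted, disjoint footprint.

    Overlapping and book-ended (touching) intervals merge into one; the
    result counts the "different regions" of the design. Idempotent;
    empty input yields an empty list.
    """
    items = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    merged: list[Interval] = []
    for r in items:
        if merged and merged[-1].chrom == r.chrom and r.start <= merged[-1].end:
            last = merged[-1]
            if r.end > last.end:
                merged[-1] = Interval(last.chrom, last.start, r.end)
        else:
            merged.append(Interval(r.chrom, r.start, r.end))
    return merged


@dataclass
class PanelDesign:
    """The capture design: labelled regions plus their merged footprint."""

    regions: list[TargetRegion]
    merged_regions: list[Interval] = field(init=False)

    def __post_init__(self) -> None:
        self.regions = sorted(self.regions, key=lambda r: (r.chrom, r.start, r.end))
        self.merged_regions = merge_regions(self.regions)
        # per-chromosome merged exon intervals (1-based inclusive) so the
        # distance query can bisect on disjoint intervals
        exon_merged = merge_regions([r for r in self.regions if r.feature == "exon"])
        self._exons: dict[str, list[tuple[int, int]]] = {}
        for iv in exon_merged:
            self._exons.setdefault(iv.chrom, []).append(to_one_based(iv.start, iv.end))
        self._exon_starts = {c: [iv[0] for iv in ivs] for c, ivs in self._exons.items()}
        self._regions_by_chrom: dict[str, list[TargetRegion]] = {}
        for r in self.regions:
            self._regions_by_chrom.setdefault(r.chrom, []).append(r)
        self._region_starts = {
            c: [r.start for r in rs] for c, rs in self._regions_by_chrom.items()
        }
        self._max_region_len = {
            c: max(len(r) for r in rs) for c, rs in self._regions_by_chrom.items()
        }
        self._merged_by_chrom: dict[str, list[Interval]] = {}
        for iv in self.merged_regions:
            self._merged_by_chrom.setdefault(iv.chrom, []).append(iv)
        self._merged_starts = {
            c: [iv.start for iv in ivs] for c, ivs in self._merged_by_chrom.items()
        }

    @property
    def genes(self) -> list[str]:
        return sorted({r.gene for r in self.regions})

    @property
    def target_length(self) -> int:
        """Total bases of the merged (non-redundant) footprint."""
        return sum(len(iv) for iv in self.merged_regions)

    def regions_for_gene(self, gene: str) -> list[TargetRegion]:
        found = [r for r in self.regions if r.gene == gene]
        if not found:
            raise KeyError(f"gene {gene!r} not in design")
        return found

    def region_at(self, chrom: str, pos: int) -> TargetRegion | None:
        """The first design region containing the 1-based position, if any.

        When several regions contain the position (an exon and an
        overlapping flank, say) the one sorting first is returned.
        """
        regs = self._regions_by_chrom.get(chrom)
        if not regs:
            return None
        starts = self._region_starts[chrom]
        j = bisect.bisect_right(starts, pos - 1)  # candidates have start <= pos-1
        lo_bound = pos - 1 - self._max_region_len[chrom]
        best = None
        k = j - 1
        while k >= 0 and regs[k].start > lo_bound:
            if regs[k].contains(chrom, pos):
                best = regs[k]
            k -= 1
        return best

    def overlap_bases(self, chrom: str, start: int, end: int) -> int:
        """Bases of the 0-based half-open query interval inside the footprint."""
        ivs = self._merged_by_chrom.get(chrom)
        if not ivs:
            return 0
        starts = self._merged_starts[chrom]
        i = max(bisect.bisect_right(starts, start) - 1, 0)
        total = 0
        while i < len(ivs) and ivs[i].start < end:
            total += max(0, min(end, ivs[i].end) - max(start, ivs[i].start))
            i += 1
        return total

    def distance_to_exon(self, chrom: str, pos: int) -> float:
        """Base distance from a 1-based position to the nearest exon edge.

        0 when the position lies inside any ``exon`` region; otherwise the
        number of bases between ``pos`` and the closest exon boundary on
        the same chromosome. Chromosomes without exons (or unknown to the
        design) yield :data:`INF_DISTANCE`.
        """
        if pos < 1:
            raise ValueError(f"positions are 1-based; got {pos}")
        exons = self._exons.get(chrom)
        if not exons:
            log.debug("no exons on chromosome %s; distance is infinite", chrom)
            return INF_DISTANCE
        starts = self._exon_starts[chrom]
        i = bisect.bisect_right(starts, pos)
        best = INF_DISTANCE
        if i > 0:
            _, hi = exons[i - 1]
            if pos <= hi:
                return 0
            best = pos - hi
        if i < len(exons):
            lo, _ = exons[i]
            best = min(best, lo - pos)
        return best


def distance_to_exon(design: PanelDesign, chrom: str, pos: int) -> float:
    """Module-level convenience wrapper around :meth:`PanelDesign.distance_to_exon`."""
    return design.distance_to_exon(chrom, pos)


def load_design(path: str | Path, dialect: str = "bed") -> PanelDesign:
    """Read a capture design from a BED-like file.

    Columns: chrom, start, end, name (gene), score (ignored), strand
    (read but ignored), feature, gc_fraction. Columns beyond the third
    are optional; missing gene defaults to the name column or ``"."``.
    """
    if dialect != "bed":
        raise ValueError(f"unsupported design dialect {dialect!r}")
    regions: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise DesignError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise DesignError(f"{path}:{lineno}: non-integer coordinate") from exc
            gene = cols[3] if len(cols) > 3 and cols[3] else "."
            feature = cols[6] if len(cols) > 6 and cols[6] else "exon"
            gc = None
            if len(cols) > 7 and cols[7] not in ("", "."):
                try:
                    gc = float(cols[7])
                except ValueError as exc:
                    raise DesignError(f"{path}:{lineno}: bad gc_fraction") from exc
            try:
                regions.append(
                    TargetRegion(cols[0], start, end, gene, feature, gc)
                )
            except DesignError as exc:
                raise DesignError(f"{path}:{lineno}: {exc}") from exc
    return PanelDesign(regions)


def write_design(design: PanelDesign, path: str | Path) -> None:
    """Write a design back to the 8-column BED dialect read by :func:`load_design`."""
    with open(path, "w") as fh:
        for r in design.regions:
            gc = "" if r.gc_fraction is None else f"{r.gc_fraction:.4f}"
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\t0\t+\t{r.feature}\t{gc}\n"
            )


def union_size(regions: Iterable[TargetRegion | Interval]) -> int:
    """Total number of distinct bases covered by a set of intervals."""
    return sum(len(iv) for iv in merge_regions(list(regions)))
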