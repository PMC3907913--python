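"""Variant calls: parsing, left-normalization and annotation.

Two input dialects are supported:

* ``gsdiff_tsv`` — a flat TSV modelled on the per-patient "all
  differences" tables emitted by amplicon/pyrosequencing mappers:
  chrom, 1-based position, ref, alt, total reads at the site, variant-
  supporting reads, and the forward/reverse split of the variant reads.
* ``vcf`` — standard VCF 4.x; AD-style sample fields map onto the count
  slots, and strand counts are recorded as unknown (they rarely survive
  into VCF).

Indel alleles are VCF-style anchored (the base before the event is
included in both ref and alt), so a deletion of G is e.g. ref ``AG`` /
alt ``A``. :func:`left_normalize` shifts indels to their leftmost
equivalent placement, which matters in homopolymer tracts where
pyrosequencing places most of its errors and where the same deletion
can be written at any position of the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

from pyropanel.panel_model import INF_DISTANCE, PanelDesign

log = logging.getLogger(__name__)

VariantType = Literal["snv", "ins", "del", "delins"]
LocationClass = Literal["exonic", "near_splice", "deep_intronic", "off_gene"]

#: Intronic window (bp from the exon boundary) still considered splice-relevant.
SPLICE_WINDOW = 20


class CallError(ValueError):
    pass


def infer_vtype(ref: str, alt: str) -> VariantType:
    if len(ref) == 1 and len(alt) == 1:
        return "snv"
    if len(ref) < len(alt) and alt.startswith(ref):
        return "ins"
    if len(ref) > len(alt) and ref.startswith(alt):
        return "del"
    return "delins"


@dataclass(frozen=True)
class VariantCall:
    """One called difference with its read support."""

    patient_id: str
    chrom: str
    pos: int  # 1-based anchor
    ref: str
    alt: str
    depth_total: int
    reads_variant: int
    reads_fwd: int | None = None  # None: strand split unknown (e.g. VCF input)
    reads_rev: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CallError(f"position {self.pos} is not 1-based")
        if not self.ref or not self.alt:
            raise CallError("empty allele")
        if self.ref == self.alt:
            raise CallError("ref and alt identical")
        if self.depth_total < 0 or self.reads_variant < 0:
            raise CallError("negative read count")
        if self.reads_variant > self.depth_total:
            raise CallError(
                f"variant reads {self.reads_variant} exceed depth {self.depth_total}"
            )
        if (self.reads_fwd is None) != (self.reads_rev is None):
            raise CallError("forward/reverse counts must both be present or absent")
        if self.reads_fwd is not None:
            if self.reads_fwd < 0 or self.reads_rev < 0:
                raise CallError("negative strand count")
            if self.reads_fwd + self.reads_rev != self.reads_variant:
                raise CallError(
                    f"strand counts {self.reads_fwd}+{self.reads_rev} do not sum "
                    f"to variant reads {self.reads_variant}"
                )

    @property
    def vtype(self) -> VariantType:
        return infer_vtype(self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return self.vtype != "snv"

    @property
    def vaf(self) -> float:
        """Variant allele fraction; 0 for degenerate zero-depth records."""
        return self.reads_variant / self.depth_total if self.depth_total else 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of the variant across patients: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class AnnotatedVariant:
    """A call decorated with everything the filters and prioritizer need."""

    call: VariantCall
    gene: str | None
    exon_distance: float  # 0 = exonic; INF_DISTANCE if no exon on chrom
    location_class: LocationClass
    known_pathogenic: bool
    cohort_count: int
    dbsnp_id: str | None = None

    @property
    def vaf(self) -> float:
        return self.call.vaf

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.call.key


def location_class_for(exon_distance: float, on_panel: bool) -> LocationClass:
    if not on_panel:
        return "off_gene"
    if exon_distance == 0:
        return "exonic"
    if exon_distance <= SPLICE_WINDOW:
        return "near_splice"
    return "deep_intronic"


GSDIFF_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "depth_total",
    "reads_variant",
    "reads_fwd",
    "reads_rev",
)


def read_calls(
    path: str | Path,
    dialect: Literal["vcf", "gsdiff_tsv"] = "gsdiff_tsv",
    patient_id: str | None = None,
) -> list[VariantCall]:
    """Read one patient's call table.

    Records violating the count invariants are rejected individually
    (logged, run continues); unparseable files abort.
    """
    pid = patient_id if patient_id is not None else Path(path).stem
    if dialect == "gsdiff_tsv":
        return _read_gsdiff(path, pid)
    if dialect == "vcf":
        return _read_vcf(path, pid)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_gsdiff(path: str | Path, patient_id: str) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if header is None:
                if cols[0] == "chrom":  # optional header row
                    header = cols
                    continue
                header = list(GSDIFF_COLUMNS)
            if len(cols) < 8:
                raise CallError(f"{path}:{lineno}: expected 8 columns, got {len(cols)}")
            try:
                call = VariantCall(
                    patient_id=patient_id,
                    chrom=cols[0],
                    pos=int(cols[1]),
                    ref=cols[2],
                    alt=cols[3],
                    depth_total=int(cols[4]),
                    reads_variant=int(cols[5]),
                    reads_fwd=int(cols[6]),
                    reads_rev=int(cols[7]),
                )
            except ValueError as exc:
                if isinstance(exc, CallError):
                    log.warning("%s:%d: rejected record: %s", path, lineno, exc)
                    continue
                raise CallError(f"{path}:{lineno}: non-integer count field") from exc
            calls.append(call)
    return calls


def _read_vcf(path: str | Path, patient_id: str) -> list[VariantCall]:
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if not rec.alts:
                continue
            for i, alt in enumerate(rec.alts):
                depth, vreads = _vcf_counts(rec, i)
                if depth is None:
                    log.warning(
                        "%s: %s:%s lacks AD/DP; record skipped", path, rec.chrom, rec.pos
                    )
                    continue
                try:
                    calls.append(
                        VariantCall(
                            patient_id=patient_id,
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            depth_total=depth,
                            reads_variant=vreads,
                        )
                    )
                except CallError as exc:
                    log.warning("%s: rejected %s:%s: %s", path, rec.chrom, rec.pos, exc)
    return calls


def _vcf_counts(rec, alt_index: int) -> tuple[int | None, int]:
    """Extract (depth_total, variant reads) from the first sample's AD/DP."""
    if rec.samples:
        sample = rec.samples[0]
        ad = sample.get("AD")
        if ad is not None and len(ad) > alt_index + 1 and ad[0] is not None:
            vreads = int(ad[alt_index + 1])
            depth = sample.get("DP")
            depth = int(depth) if depth is not None else sum(int(x) for x in ad if x is not None)
            return max(depth, vreads), vreads
        dp = sample.get("DP")
        if dp is not None:
            return int(dp), 0
    dp = rec.info.get("DP")
    if dp is not None:
        return int(dp), 0
    return None, 0


def write_calls(calls: Sequence[VariantCall], path: str | Path) -> None:
    """Write calls in the gsdiff_tsv dialect (with header)."""
    with open(path, "w") as fh:
        fh.write("\t".join(GSDIFF_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.ref}\t{c.alt}\t{c.depth_total}\t"
                f"{c.reads_variant}\t{c.reads_fwd if c.reads_fwd is not None else '.'}\t"
                f"{c.reads_rev if c.reads_rev is not None else '.'}\n"
            )


@dataclass(frozen=True)
class ReferenceContext:
    """A stretch of reference sequence anchored at a 1-based position."""

    chrom: str
    start: int  # 1-based position of seq[0]
    seq: str

    def base(self, pos: int) -> str | None:
        idx = pos - self.start
        if 0 <= idx < len(self.seq):
            return self.seq[idx]
        return None


def left_normalize(call: VariantCall, context: ReferenceContext) -> VariantCall:
    """Shift an indel to its leftmost equivalent placement.

    Uses the standard trim-and-shift procedure: while ref and alt end in
    the same base and the preceding reference base is available, drop the
    shared last base and prepend the reference base before the anchor.
    SNVs (and delins with no shared ends) are returned unchanged; if the
    context does not cover the needed bases the call is returned as-is
    with a warning.
    """
    if call.vtype == "snv":
        return call
    ref, alt, pos = call.ref, call.alt, call.pos
    # trim shared trailing bases without shifting first
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref[-1] == alt[-1]:
        prev = context.base(pos - 1)
        if prev is None:
            log.warning(
                "context too short to left-normalize %s:%d %s>%s; kept as-is",
                call.chrom,
                call.pos,
                call.ref,
                call.alt,
            )
            return call
        ref = prev + ref[:-1]
        alt = prev + alt[:-1]
        pos -= 1
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
    # trim shared leading bases beyond the single anchor
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0] and ref[1] == alt[1]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if (ref, alt, pos) == (call.ref, call.alt, call.pos):
        return call
    return replace(call, pos=pos, ref=ref, alt=alt)


def annotate(
    call: VariantCall,
    design: PanelDesign,
    whitelist: Mapping[tuple[str, int, str, str], str] | set | None = None,
    cohort_index: Mapping[tuple[str, int, str, str], int] | None = None,
    dbsnp: Mapping[tuple[str, int, str, str], str] | None = None,
) -> AnnotatedVariant:
    """Decorate a call with gene, exon distance, whitelist and cohort fields.

    Deterministic and side-effect free. Off-panel calls (not contained in
    any design region) are classed ``off_gene`` but still receive the
    exon distance so downstream rules can reason about them.
    """
    region = design.region_at(call.chrom, call.pos)
    dist = design.distance_to_exon(call.chrom, call.pos)
    on_panel = region is not None
    gene = region.gene if region is not None else None
    known = False
    if whitelist is not None:
        known = call.key in whitelist
    count = 0
    if cohort_index is not None:
        count = _cohort_lookup(cohort_index, call.key)
    rsid = dbsnp.get(call.key) if dbsnp is not None else None
    return AnnotatedVariant(
        call=call,
        gene=gene,
        exon_distance=dist if dist != INF_DISTANCE else INF_DISTANCE,
        location_class=location_class_for(dist, on_panel),
        known_pathogenic=known,
        cohort_count=count,
        dbsnp_id=rsid,
    )


def _cohort_lookup(index, key) -> int:
    # CohortIndex exposes .counts; a bare mapping is accepted too
    counts = getattr(index, "counts", index)
    return counts.get(key, 0)


def annotate_all(
    calls: Sequence[VariantCall],
    design: PanelDesign,
    whitelist=None,
    cohort_index=None,
    dbsnp=None,
) -> list[AnnotatedVariant]:
    return [annotate(c, design, whitelist, cohort_index, dbsnp) for c in calls]


def read_whitelist(path: str | Path) -> dict[tuple[str, int, str, str], str]:
    """Known-pathogenic whitelist TSV: chrom, pos, ref, alt, gene, cdna_label, class.

    Returns a mapping from the normalized genomic key to the stated class
    label (free text, e.g. ``Pathogenic``).
    """
    table: dict[tuple[str, int, str, str], str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise CallError(f"{path}:{lineno}: expected >=4 whitelist columns")
            label = cols[6] if len(cols) > 6 else "Pathogenic"
            table[(cols[0], int(cols[1]), cols[2], cols[3])] = label
    return table


def write_whitelist(
    entries: Mapping[tuple[str, int, str, str], tuple[str, str, str]] | Sequence,
    path: str | Path,
) -> None:
    """Write a whitelist TSV. ``entries`` maps key -> (gene, cdna_label, class)."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\tcdna_label\tclass\n")
        items = entries.items() if hasattr(entries, "items") else entries
        for (chrom, pos, ref, alt), (gene, label, cls) in items:
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{gene}\t{label}\t{cls}\n")
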