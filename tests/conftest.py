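import numpy as np
import pytest

from pyropanel.panel_model import PanelDesign, TargetRegion
from pyropanel.variant_model import AnnotatedVariant, VariantCall, annotate


def make_call(
    chrom="chr1",
    pos=150,
    ref="A",
    alt="G",
    depth=100,
    reads=50,
    fwd=None,
    rev=None,
    patient="P001",
):
    if fwd is None and rev is None:
        fwd = reads // 2
        rev = reads - fwd
    return VariantCall(patient, chrom, pos, ref, alt, depth, reads, fwd, rev)


def make_annotated(design=None, whitelist=None, cohort=None, **kwargs):
    call = make_call(**kwargs)
    if design is None:
        design = PanelDesign([TargetRegion("chr1", 100, 200, "GENE01", "exon")])
    return annotate(call, design, whitelist, cohort)


@pytest.fixture
def small_design():
    """Two genes; GENE01 exon [101,200] 1-based with flanks, GENE02 exon [501,600]."""
    return PanelDesign(
        [
            TargetRegion("chr1", 0, 100, "GENE01", "intronic_extension", 0.45),
            TargetRegion("chr1", 100, 200, "GENE01", "exon", 0.5),
            TargetRegion("chr1", 200, 300, "GENE01", "intronic_extension", 0.55),
            TargetRegion("chr1", 400, 500, "GENE02", "intronic_extension", 0.7),
            TargetRegion("chr1", 500, 600, "GENE02", "exon", 0.72),
            TargetRegion("chr1", 600, 700, "GENE02", "intronic_extension", 0.68),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# independent brute-force oracles


def merge_oracle(regions):
    """Per-base boolean-mask union, re-intervalized."""
    by_chrom = {}
    for r in regions:
        lo, hi = by_chrom.get(r.chrom, (r.start, r.end))
        by_chrom[r.chrom] = (min(lo, r.start), max(hi, r.end))
    out = []
    for chrom in sorted(by_chrom):
        lo, hi = by_chrom[chrom]
        mask = np.zeros(hi - lo, dtype=bool)
        for r in regions:
            if r.chrom == chrom:
                mask[r.start - lo : r.end - lo] = True
        start = None
        for i, bit in enumerate(mask):
            if bit and start is None:
                start = i
            elif not bit and start is not None:
                out.append((chrom, lo + start, lo + i))
                start = None
        if start is not None:
            out.append((chrom, lo + start, lo + len(mask)))
    return out


def distance_oracle(design, chrom, pos):
    """Minimum |pos - base| over every exon base (0 when inside an exon)."""
    best = float("inf")
    for r in design.regions:
        if r.feature != "exon" or r.chrom != chrom:
            continue
        for base in range(r.start + 1, r.end + 1):
            if base == pos:
                return 0
            best = min(best, abs(pos - base))
    return best


def on_target_oracle(reads, design):
    """Per-base membership ratio."""
    member = set()
    for iv in design.merged_regions:
        for b in range(iv.start, iv.end):
            member.add((iv.chrom, b))
    inside = total = 0
    for chrom, start, end in reads:
        for b in range(start, end):
            total += 1
            if (chrom, b) in member:
                inside += 1
    return inside / total


def cohort_oracle(call_tables):
    """Set-membership counting: one DNA contributes once per variant key."""
    counts = {}
    for table in call_tables:
        for key in {c.key for c in table}:
            counts[key] = counts.get(key, 0) + 1
    return counts


__all__ = [
    "make_call",
    "make_annotated",
    "merge_oracle",
    "distance_oracle",
    "on_target_oracle",
    "cohort_oracle",
]
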