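"""Synthetic panels, coverage and cohorts with truth labels.

The generator works at the *call* level, not the read level: it emits
the same design/coverage/call-table/whitelist formats the pipeline
consumes, with every emitted call carrying a hidden truth label. That
is enough to exercise every implemented statistic and filter, because
none of them looks at read sequences — only at interval geometry,
per-base depth and read-support counts.

What it emulates
----------------
* a multi-gene exon panel with 100 bp intronic flanks, where some
  neighbouring exons are close enough that their flanks overlap (so
  footprint merging is exercised), and per-region GC with a heavy right
  tail so some regions exceed the 60% GC mark;
* GC-dependent, overdispersed capture depth (negative-binomial per
  base, regional mean depressed above 50% GC, log-normal region-to-
  region capture efficiency);
* true variants (het/hom, VAF near 0.5/1.0, balanced strands), some
  shared across five or more cohort DNAs to exercise cohort masking,
  and a known-pathogenic whitelist covering a subset;
* the three artifact classes of pyrosequencing call sets: low-fraction
  noise calls (VAF < 20%), strand-biased indels in homopolymer context
  (minor strand < 10% of >20 supporting reads), and deep-intronic
  indels (> 20 bp from any exon).

True variants are emitted with supporting evidence safely inside the
retention regime (VAF >= 0.25, minor-strand share >= 0.2 whenever more
than 20 reads support an indel), emulating calls that a validated
chemistry produces for real variants; artifacts are constructed
strictly inside the corresponding rejection regime. Default rates are
calibrated to the call loads of a diagnostic deafness-panel run on 454
chemistry: a raw mean of ~4674 calls per patient of which ~92.3% are
artifacts, collapsing to ~8 candidate variants per patient after
cohort masking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from pyropanel.panel_model import PanelDesign, TargetRegion
from pyropanel.coverage_qc import CoverageProfile
from pyropanel.variant_model import VariantCall

TruthLabel = Literal[
    "true_variant", "artifact:low_vaf", "artifact:strand", "artifact:deep_intronic"
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulated cohort.

    Defaults describe a 47-patient diagnostic run on a 19-gene deafness
    panel: ~634 targeted exons with 100 bp flanks, 77x mean capture
    depth, and per-patient call loads dominated by pyrosequencing noise.
    """

    seed: int
    n_genes: int = 19
    mean_exons_per_gene: float = 33.4
    exon_length_mean: float = 170.0
    exon_length_sigma: float = 0.45  # log-normal shape of exon lengths
    flank_bp: int = 100
    n_patients: int = 47
    true_rare_per_patient: float = 7.5
    shared_pool_size: int = 600
    shared_carrier_min: int = 5
    deep_intronic_snvs_per_patient: float = 20.0
    low_vaf_noise_per_patient: float = 3894.0
    strand_indels_per_patient: float = 250.0
    deep_intronic_indels_per_patient: float = 170.0
    homopolymer_tracts_per_kb: float = 5.0
    mean_depth: float = 77.0
    depth_dispersion: float = 20.0  # negative-binomial r; var = m + m^2/r
    gc_depth_slope: float = 2.0  # relative depth lost per unit GC above 0.5
    region_efficiency_sigma: float = 0.35  # log-normal capture-efficiency spread
    whitelist_rare_fraction: float = 0.15
    n_whitelisted_shared: int = 1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory; no implicit randomness")
        rates = (
            self.true_rare_per_patient,
            self.deep_intronic_snvs_per_patient,
            self.low_vaf_noise_per_patient,
            self.strand_indels_per_patient,
            self.deep_intronic_indels_per_patient,
            self.homopolymer_tracts_per_kb,
        )
        if any(r < 0 for r in rates):
            raise ValueError("rates must be non-negative")


@dataclass
class TruthRecord:
    """Ground truth for one variant occurrence in one patient."""

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    label: TruthLabel
    emitted: bool = True  # False: present in the DNA but never called
    homopolymer_context: bool = False
    shared: bool = False
    whitelisted: bool = False
    failure_category: str | None = None  # homopolymer | misaligned | low_coverage

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def full_key(self) -> tuple[str, str, int, str, str]:
        return (self.patient_id, self.chrom, self.pos, self.ref, self.alt)


@dataclass
class TruthTable:
    records: list[TruthRecord]
    designed_adoc: dict[TargetRegion, float] = field(default_factory=dict)

    def by_label(self, label: TruthLabel) -> list[TruthRecord]:
        return [r for r in self.records if r.label == label]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "patient_id\tchrom\tpos\tref\talt\tlabel\temitted\t"
                "homopolymer\tshared\twhitelisted\tfailure_category\n"
            )
            for r in self.records:
                fh.write(
                    f"{r.patient_id}\t{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t"
                    f"{r.label}\t{int(r.emitted)}\t{int(r.homopolymer_context)}\t"
                    f"{int(r.shared)}\t{int(r.whitelisted)}\t"
                    f"{r.failure_category or '.'}\n"
                )


# ---------------------------------------------------------------------------
# panel


def simulate_panel(cfg: SimulationConfig) -> PanelDesign:
    """Draw a multi-gene exon+flank design; deterministic for a fixed seed.

    Each gene sits on its own chromosome. Inter-exon gaps are drawn so
    that a fraction of neighbouring flanks overlap (short introns),
    which makes the merged footprint strictly smaller than the region
    list. Exon GC is a two-component mixture with a heavy right tail.
    """
    rng = np.random.default_rng(cfg.seed)
    regions: list[TargetRegion] = []
    for g in range(cfg.n_genes):
        gene = f"GENE{g + 1:02d}"
        chrom = f"chr{g + 1}"
        n_exons = max(1, rng.poisson(cfg.mean_exons_per_gene))
        pos = int(rng.integers(10_000, 50_000))
        for _ in range(n_exons):
            length = max(
                30,
                int(rng.lognormal(math.log(cfg.exon_length_mean), cfg.exon_length_sigma)),
            )
            gc = _draw_gc(rng)
            start = pos
            end = pos + length
            regions.append(TargetRegion(chrom, start, end, gene, "exon", gc))
            fl = cfg.flank_bp
            if fl > 0:
                left = max(0, start - fl)
                if left < start:
                    regions.append(
                        TargetRegion(
                            chrom, left, start, gene, "intronic_extension",
                            _jitter_gc(rng, gc),
                        )
                    )
                regions.append(
                    TargetRegion(
                        chrom, end, end + fl, gene, "intronic_extension",
                        _jitter_gc(rng, gc),
                    )
                )
            # ~25% short introns so successive exon+flank targets overlap
            if rng.random() < 0.25:
                gap = int(rng.integers(20, 2 * cfg.flank_bp))
            else:
                gap = int(rng.integers(2 * cfg.flank_bp + 50, 6000))
            pos = end + gap
    return PanelDesign(regions)


def _draw_gc(rng: np.random.Generator) -> float:
    if rng.random() < 0.85:
        return float(np.clip(rng.beta(20, 20), 0.0, 1.0))
    return float(np.clip(rng.beta(24, 12), 0.0, 1.0))  # GC-rich tail


def _jitter_gc(rng: np.random.Generator, gc: float) -> float:
    return float(np.clip(gc + rng.normal(0, 0.03), 0.0, 1.0))


def panel_with_merge_structure(
    n_regions: int, n_components: int, seed: int = 0, gene: str = "GENE01"
) -> PanelDesign:
    """A design with exactly ``n_regions`` regions whose per-base union
    has exactly ``n_components`` disjoint components.

    Components are well-separated intervals; the surplus
    ``n_regions - n_components`` regions are overlapping duplicates
    placed inside randomly chosen components.
    """
    if not 1 <= n_components <= n_regions:
        raise ValueError("need 1 <= n_components <= n_regions")
    rng = np.random.default_rng(seed)
    regions: list[TargetRegion] = []
    comp_spans: list[tuple[str, int, int]] = []
    pos = 100
    chrom = "chr1"
    for _ in range(n_components):
        length = int(rng.integers(120, 400))
        regions.append(TargetRegion(chrom, pos, pos + length, gene, "exon"))
        comp_spans.append((chrom, pos, pos + length))
        pos += length + int(rng.integers(50, 500))  # gap > 0: never merges
    extras = n_regions - n_components
    idx = rng.integers(0, n_components, size=extras)
    for i in idx:
        c, lo, hi = comp_spans[int(i)]
        a = int(rng.integers(lo, hi - 1))
        b = int(rng.integers(a + 1, hi + 1))
        regions.append(TargetRegion(c, a, b, gene, "exon"))
    return PanelDesign(regions)


# ---------------------------------------------------------------------------
# coverage


def designed_region_depth(
    region: TargetRegion, cfg: SimulationConfig, rng: np.random.Generator
) -> float:
    """Designed mean depth of a region: GC-depressed, efficiency-scaled."""
    gc = region.gc_fraction if region.gc_fraction is not None else 0.5
    gc_factor = max(0.02, 1.0 - cfg.gc_depth_slope * max(0.0, gc - 0.5))
    efficiency = rng.lognormal(0.0, cfg.region_efficiency_sigma)
    return cfg.mean_depth * gc_factor * efficiency


def simulate_coverage(
    design: PanelDesign, cfg: SimulationConfig
) -> tuple[list[CoverageProfile], TruthTable]:
    """Per-base depth profiles for every design region.

    Depth is negative-binomial around the region's designed mean
    (variance = m + m^2/r with r = ``depth_dispersion``). The truth
    table records the designed mean of every region.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    profiles: list[CoverageProfile] = []
    designed: dict[TargetRegion, float] = {}
    r = cfg.depth_dispersion
    for region in design.regions:
        mean = designed_region_depth(region, cfg, rng)
        designed[region] = mean
        p = r / (r + mean)
        depths = rng.negative_binomial(r, p, size=len(region))
        profiles.append(CoverageProfile(region, depths))
    return profiles, TruthTable(records=[], designed_adoc=designed)


# ---------------------------------------------------------------------------
# cohort


class _PositionSampler:
    """Uniform sampling of 1-based positions from a set of intervals."""

    def __init__(self, intervals: Sequence[tuple[str, int, int, TargetRegion]]):
        # intervals: (chrom, lo, hi) 1-based inclusive + owning region
        self.intervals = list(intervals)
        lengths = np.array([hi - lo + 1 for _, lo, hi, _ in self.intervals])
        self.cum = np.concatenate([[0], np.cumsum(lengths)])
        self.total = int(self.cum[-1])

    def at(self, flat: int) -> tuple[str, int, TargetRegion]:
        i = int(np.searchsorted(self.cum, flat, side="right") - 1)
        chrom, lo, _, region = self.intervals[i]
        return chrom, lo + (flat - int(self.cum[i])), region

    def sample(self, rng: np.random.Generator, size: int, replace: bool = True):
        flats = (
            rng.integers(0, self.total, size=size)
            if replace
            else rng.choice(self.total, size=size, replace=False)
        )
        return [self.at(int(f)) for f in np.atleast_1d(flats)]


def _exon_sampler(design: PanelDesign) -> _PositionSampler:
    return _PositionSampler(
        [
            (r.chrom, r.start + 1, r.end, r)
            for r in design.regions
            if r.feature == "exon"
        ]
    )


def _deep_flank_sampler(design: PanelDesign, min_dist: int = 21) -> _PositionSampler:
    """Flank positions strictly more than 20 bp from *any* exon.

    Checked against the design's own distance query, base by base, so
    overlapping flanks in short introns cannot smuggle a near-splice
    position into the deep-intronic pool. Runs of qualifying bases are
    re-intervalized for uniform sampling.
    """
    ivs = []
    for r in design.regions:
        if r.feature != "intronic_extension":
            continue
        run_start = None
        for pos in range(r.start + 1, r.end + 1):
            deep = design.distance_to_exon(r.chrom, pos) >= min_dist
            if deep and run_start is None:
                run_start = pos
            elif not deep and run_start is not None:
                ivs.append((r.chrom, run_start, pos - 1, r))
                run_start = None
        if run_start is not None:
            ivs.append((r.chrom, run_start, r.end, r))
    return _PositionSampler(ivs)


def _snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return str(_BASES[ref]), str(_BASES[alt])


def _indel_alleles(rng: np.random.Generator, homopolymer_base: str | None = None):
    anchor = homopolymer_base or str(_BASES[rng.integers(0, 4)])
    run_base = homopolymer_base or str(_BASES[rng.integers(0, 4)])
    if rng.random() < 0.5:  # single-base deletion
        return anchor + run_base, anchor
    return anchor, anchor + run_base  # single-base insertion


def _depth_at(
    region: TargetRegion,
    designed: dict[TargetRegion, float],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    minimum: int = 1,
) -> int:
    mean = designed.get(region, cfg.mean_depth)
    r = cfg.depth_dispersion
    d = int(rng.negative_binomial(r, r / (r + mean)))
    return max(d, minimum)


def _true_support(
    depth: int, rng: np.random.Generator
) -> tuple[int, int, int]:
    """Read support of a true variant: het/hom VAF, balanced strands.

    Clamped inside the retention regime (VAF >= 0.25; minor strand
    share >= 0.2 when more than 20 reads support the call).
    """
    hom = rng.random() < 0.2
    vaf_center = 0.98 if hom else 0.5
    rv = int(rng.binomial(depth, vaf_center))
    rv = max(rv, max(1, math.ceil(0.25 * depth)))
    rv = min(rv, depth)
    if rv > 20:
        fwd = int(rng.integers(math.ceil(0.2 * rv), math.floor(0.8 * rv) + 1))
    else:
        fwd = int(rng.binomial(rv, 0.5))
    return rv, fwd, rv - fwd


def simulate_cohort(
    design: PanelDesign,
    cfg: SimulationConfig,
    coverage_truth: TruthTable | None = None,
) -> tuple[dict[str, list[VariantCall]], TruthTable, dict]:
    """Emit per-patient call tables, the truth table, and a whitelist.

    Returns ``(calls_by_patient, truth, whitelist)`` where ``whitelist``
    maps the variant key to ``(gene, cdna_label, class)``. The emitted
    call tables contain no truth columns.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    designed = coverage_truth.designed_adoc if coverage_truth else {}
    exon_s = _exon_sampler(design)
    deep_s = _deep_flank_sampler(design)
    patients = [f"P{i + 1:03d}" for i in range(cfg.n_patients)]
    calls: dict[str, list[VariantCall]] = {p: [] for p in patients}
    records: list[TruthRecord] = []
    whitelist: dict[tuple[str, int, str, str], tuple[str, str, str]] = {}
    used: set[tuple] = set()  # (patient, chrom, pos, ref, alt): one truth label per call

    def _claim(pid: str, chrom: str, pos: int, ref: str, alt: str, redraw) -> tuple | None:
        """Reserve a per-patient variant key, redrawing alleles on collision."""
        for _ in range(12):
            key = (pid, chrom, pos, ref, alt)
            if key not in used:
                used.add(key)
                return ref, alt
            ref, alt = redraw()
        return None

    # homopolymer tracts: positions inside exons where strand artifacts recur
    n_tracts = max(
        1,
        int(
            cfg.homopolymer_tracts_per_kb
            * sum(len(r) for r in design.regions if r.feature == "exon")
            / 1000
        ),
    )
    tracts = exon_s.sample(rng, min(n_tracts, exon_s.total), replace=False)
    tract_bases = [str(_BASES[rng.integers(0, 4)]) for _ in tracts]

    # unique positions for rare true, shared true and deep-intronic SNVs
    n_rare = rng.poisson(cfg.true_rare_per_patient, size=cfg.n_patients)
    n_deep_snv = rng.poisson(cfg.deep_intronic_snvs_per_patient, size=cfg.n_patients)
    n_shared = min(cfg.shared_pool_size, max(exon_s.total // 4, 1))
    need_exonic = int(n_rare.sum()) + n_shared
    exonic_sites = exon_s.sample(rng, min(need_exonic, exon_s.total), replace=False)
    shared_sites = exonic_sites[:n_shared]
    rare_sites = exonic_sites[n_shared:]
    deep_sites = deep_s.sample(
        rng, min(int(n_deep_snv.sum()), deep_s.total), replace=False
    )

    # shared pool: carriage >= shared_carrier_min DNAs each
    shared_pool = []
    for chrom, pos, region in shared_sites:
        ref, alt = _snv_alleles(rng)
        lo = min(cfg.shared_carrier_min, cfg.n_patients)  # tiny cohorts: carry everyone
        carriage = int(rng.integers(lo, cfg.n_patients + 1))
        carriers = rng.choice(cfg.n_patients, size=carriage, replace=False)
        shared_pool.append((chrom, pos, ref, alt, region, carriers))
    for j in range(min(cfg.n_whitelisted_shared, len(shared_pool))):
        chrom, pos, ref, alt, region, _ = shared_pool[j]
        whitelist[(chrom, pos, ref, alt)] = (region.gene, f"c.{pos}{ref}>{alt}", "Pathogenic")

    # emit shared variants
    for chrom, pos, ref, alt, region, carriers in shared_pool:
        wl = (chrom, pos, ref, alt) in whitelist
        for ci in carriers:
            pid = patients[int(ci)]
            used.add((pid, chrom, pos, ref, alt))
            depth = _depth_at(region, designed, cfg, rng, minimum=8)
            rv, fwd, rev = _true_support(depth, rng)
            calls[pid].append(
                VariantCall(pid, chrom, pos, ref, alt, depth, rv, fwd, rev)
            )
            records.append(
                TruthRecord(pid, chrom, pos, ref, alt, "true_variant",
                            shared=True, whitelisted=wl)
            )

    # rare true variants (unique site each; ~15% indels) + whitelist subset
    site_iter = iter(rare_sites)
    for pi, pid in enumerate(patients):
        for _ in range(int(n_rare[pi])):
            try:
                chrom, pos, region = next(site_iter)
            except StopIteration:  # exonic space exhausted (tiny designs)
                break
            if rng.random() < 0.15:
                ref, alt = _indel_alleles(rng)
            else:
                ref, alt = _snv_alleles(rng)
            used.add((pid, chrom, pos, ref, alt))
            depth = _depth_at(region, designed, cfg, rng, minimum=8)
            rv, fwd, rev = _true_support(depth, rng)
            calls[pid].append(
                VariantCall(pid, chrom, pos, ref, alt, depth, rv, fwd, rev)
            )
            wl = rng.random() < cfg.whitelist_rare_fraction
            if wl:
                whitelist[(chrom, pos, ref, alt)] = (
                    region.gene, f"c.{pos}{ref}>{alt}", "Pathogenic",
                )
            records.append(
                TruthRecord(pid, chrom, pos, ref, alt, "true_variant", whitelisted=wl)
            )

    # deep-intronic SNVs: real but masked at prioritization
    deep_iter = iter(deep_sites)
    for pi, pid in enumerate(patients):
        for _ in range(int(n_deep_snv[pi])):
            try:
                chrom, pos, region = next(deep_iter)
            except StopIteration:
                break
            ref, alt = _snv_alleles(rng)
            used.add((pid, chrom, pos, ref, alt))
            depth = _depth_at(region, designed, cfg, rng, minimum=8)
            rv, fwd, rev = _true_support(depth, rng)
            calls[pid].append(
                VariantCall(pid, chrom, pos, ref, alt, depth, rv, fwd, rev)
            )
            records.append(
                TruthRecord(pid, chrom, pos, ref, alt, "true_variant")
            )

    # artifacts
    all_s = _PositionSampler(
        [(r.chrom, r.start + 1, r.end, r) for r in design.regions]
    )
    n_low = rng.poisson(cfg.low_vaf_noise_per_patient, size=cfg.n_patients)
    n_strand = rng.poisson(cfg.strand_indels_per_patient, size=cfg.n_patients)
    n_deepi = rng.poisson(cfg.deep_intronic_indels_per_patient, size=cfg.n_patients)
    for pi, pid in enumerate(patients):
        # (1) low-fraction noise calls anywhere on the footprint
        for chrom, pos, region in all_s.sample(rng, int(n_low[pi])):
            claimed = _claim(pid, chrom, pos, *_snv_alleles(rng), lambda: _snv_alleles(rng))
            if claimed is None:
                continue
            ref, alt = claimed
            depth = _depth_at(region, designed, cfg, rng, minimum=25)
            vaf = rng.uniform(0.02, 0.18)
            rv = max(1, int(depth * vaf))
            fwd = int(rng.binomial(rv, 0.5))
            calls[pid].append(
                VariantCall(pid, chrom, pos, ref, alt, depth, rv, fwd, rv - fwd)
            )
            records.append(
                TruthRecord(pid, chrom, pos, ref, alt, "artifact:low_vaf")
            )
        # (2) strand-biased indels at recurrent homopolymer tracts
        if tracts:
            which = rng.integers(0, len(tracts), size=int(n_strand[pi]))
            for ti in which:
                chrom, pos, region = tracts[int(ti)]
                base = tract_bases[int(ti)]
                claimed = _claim(
                    pid, chrom, pos, *_indel_alleles(rng, homopolymer_base=base),
                    lambda: _indel_alleles(rng),
                )
                if claimed is None:
                    continue
                ref, alt = claimed
                rv = int(rng.integers(21, 81))
                vaf = rng.uniform(0.25, 0.6)
                depth = max(int(math.ceil(rv / vaf)), rv)
                minor = int(rv * rng.uniform(0.0, 0.1))
                fwd, rev = (minor, rv - minor) if rng.random() < 0.5 else (rv - minor, minor)
                calls[pid].append(
                    VariantCall(pid, chrom, pos, ref, alt, depth, rv, fwd, rev)
                )
                records.append(
                    TruthRecord(pid, chrom, pos, ref, alt, "artifact:strand",
                                homopolymer_context=True)
                )
        # (3) deep-intronic indels
        for chrom, pos, region in deep_s.sample(rng, int(n_deepi[pi])):
            claimed = _claim(pid, chrom, pos, *_indel_alleles(rng), lambda: _indel_alleles(rng))
            if claimed is None:
                continue
            ref, alt = claimed
            depth = _depth_at(region, designed, cfg, rng, minimum=8)
            rv, fwd, rev = _true_support(depth, rng)
            calls[pid].append(
                VariantCall(pid, chrom, pos, ref, alt, depth, rv, fwd, rev)
            )
            records.append(
                TruthRecord(pid, chrom, pos, ref, alt, "artifact:deep_intronic")
            )

    truth = TruthTable(records=records, designed_adoc=designed)
    return calls, truth, whitelist


# ---------------------------------------------------------------------------
# sensitivity study


def simulate_sensitivity_study(
    cfg: SimulationConfig,
    n_true: int = 687,
    n_homopolymer_fn: int = 6,
    n_misaligned_fn: int = 4,
    n_low_coverage_fn: int = 3,
    n_patients: int = 24,
) -> tuple[PanelDesign, dict[str, list[VariantCall]], TruthTable]:
    """A concordance study: ``n_true`` previously confirmed variants, of
    which a fixed number are constructed to escape detection.

    The false negatives mirror the failure modes of pyrosequencing
    panels: variants in homopolymer tracts are emitted with the
    one-sided strand signature that the artifact filter rightly removes;
    misaligned variants are never emitted by the caller; variants in
    poorly covered regions (< 40x) are never emitted either. All
    remaining variants are emitted cleanly inside the retention regime.
    """
    n_fn = n_homopolymer_fn + n_misaligned_fn + n_low_coverage_fn
    if n_fn > n_true:
        raise ValueError("more designed false negatives than true variants")
    design = simulate_panel(replace(cfg, n_patients=n_patients))
    rng = np.random.default_rng(cfg.seed + 3)
    exon_s = _exon_sampler(design)
    sites = exon_s.sample(rng, min(n_true, exon_s.total), replace=False)
    if len(sites) < n_true:
        raise ValueError("design too small for the requested number of variants")
    patients = [f"S{i + 1:03d}" for i in range(n_patients)]
    assignment = rng.integers(0, n_patients, size=n_true)
    categories = (
        ["homopolymer"] * n_homopolymer_fn
        + ["misaligned"] * n_misaligned_fn
        + ["low_coverage"] * n_low_coverage_fn
        + [None] * (n_true - n_fn)
    )
    order = rng.permutation(n_true)
    calls: dict[str, list[VariantCall]] = {p: [] for p in patients}
    records: list[TruthRecord] = []
    for k in range(n_true):
        chrom, pos, region = sites[k]
        pid = patients[int(assignment[k])]
        category = categories[int(order[k])]
        is_indel = rng.random() < 0.15 or category == "homopolymer"
        if is_indel:
            ref, alt = _indel_alleles(rng)
        else:
            ref, alt = _snv_alleles(rng)
        if category == "misaligned" or category == "low_coverage":
            records.append(
                TruthRecord(pid, chrom, pos, ref, alt, "true_variant",
                            emitted=False, failure_category=category)
            )
            continue
        if category == "homopolymer":
            rv = int(rng.integers(21, 81))
            depth = max(int(math.ceil(rv / rng.uniform(0.25, 0.6))), rv)
            minor = int(rv * rng.uniform(0.0, 0.1))
            fwd, rev = (minor, rv - minor) if rng.random() < 0.5 else (rv - minor, minor)
            calls[pid].append(
                VariantCall(pid, chrom, pos, ref, alt, depth, rv, fwd, rev)
            )
            records.append(
                TruthRecord(pid, chrom, pos, ref, alt, "true_variant",
                            homopolymer_context=True, failure_category="homopolymer")
            )
            continue
        depth = max(int(rng.normal(cfg.mean_depth, cfg.mean_depth / 5)), 45)
        rv, fwd, rev = _true_support(depth, rng)
        calls[pid].append(VariantCall(pid, chrom, pos, ref, alt, depth, rv, fwd, rev))
        records.append(TruthRecord(pid, chrom, pos, ref, alt, "true_variant"))
    return design, calls, TruthTable(records=records)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class SensitivityReport:
    n_true: int
    n_true_detected: int
    n_artifacts: int
    n_artifacts_removed: int
    false_negative_categories: dict[str, int]
    confusion: dict[str, dict[str, int]]

    @property
    def sensitivity(self) -> float:
        return self.n_true_detected / self.n_true if self.n_true else float("nan")

    @property
    def specificity(self) -> float:
        """Fraction of injected artifacts removed by the pipeline."""
        return (
            self.n_artifacts_removed / self.n_artifacts
            if self.n_artifacts
            else float("nan")
        )

    def as_dict(self) -> dict:
        return {
            "n_true": self.n_true,
            "n_true_detected": self.n_true_detected,
            "sensitivity": self.sensitivity,
            "n_artifacts": self.n_artifacts,
            "n_artifacts_removed": self.n_artifacts_removed,
            "specificity": self.specificity,
            "false_negative_categories": self.false_negative_categories,
            "confusion": self.confusion,
        }


def evaluate_filters(
    truth: TruthTable,
    retained: dict[str, Sequence],
) -> SensitivityReport:
    """Score a pipeline run against the truth table.

    ``retained`` maps patient id to the variants the pipeline kept
    (anything exposing ``.key`` or 4-tuples). Sensitivity counts every
    true variant in the truth table, emitted or not, as the denominator
    — exactly as a concordance study against a prior gold standard
    would. Retained keys that the truth table does not know abort.
    """
    retained_keys: set[tuple] = set()
    for pid, items in retained.items():
        for v in items:
            key = v.key if hasattr(v, "key") else tuple(v)
            retained_keys.add((pid, *key))
    known_emitted = {r.full_key for r in truth.records if r.emitted}
    unknown = retained_keys - known_emitted
    if unknown:
        raise ValueError(
            f"{len(unknown)} retained variants are absent from the truth table, "
            f"e.g. {sorted(unknown)[:3]}"
        )
    confusion: dict[str, dict[str, int]] = {}
    fn_categories: dict[str, int] = {}
    n_true = n_true_det = n_art = n_art_rm = 0
    for r in truth.records:
        kept = r.full_key in retained_keys
        bucket = confusion.setdefault(r.label, {"retained": 0, "removed": 0})
        bucket["retained" if kept else "removed"] += 1
        if r.label == "true_variant":
            n_true += 1
            if kept:
                n_true_det += 1
            else:
                cat = r.failure_category or (
                    "homopolymer" if r.homopolymer_context else "other"
                )
                fn_categories[cat] = fn_categories.get(cat, 0) + 1
        else:
            n_art += 1
            if not kept:
                n_art_rm += 1
    return SensitivityReport(
        n_true=n_true,
        n_true_detected=n_true_det,
        n_artifacts=n_art,
        n_artifacts_removed=n_art_rm,
        false_negative_categories=fn_categories,
        confusion=confusion,
    )
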