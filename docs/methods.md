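# Methods note

This note records the models implemented in `pyropanel`, the parameter
defaults, the scope of the synthetic-data generator, numerical
conventions, and known limitations. Nothing here asserts empirical
performance beyond what the code computes.

## Coordinate and interval conventions

* Design files are a BED dialect: 0-based, half-open intervals with
  columns `chrom, start, end, gene, score, strand, feature, gc`.
  `feature` is one of `exon`, `utr`, `intronic_extension`; intronic
  flanks are explicit regions, never implicit padding.
* Variant calls are 1-based, VCF-style (`pos` is the first reference
  base of `ref`). The conversion between the two conventions lives in
  one place (`panel_model`); distances never re-derive it.
* `merge_regions` merges overlapping *and* book-ended intervals
  (`[a,b) + [b,c) -> [a,c)`), matching how capture probes tile.
* `distance_to_exon` returns 0 inside an exon and the base-count gap to
  the nearest exon edge otherwise, computed against the merged exon
  union per chromosome, so nested or overlapping exon annotations
  cannot distort it. A chromosome without exons yields `inf`.
* Indel representation: `left_normalize` shifts an indel to its
  leftmost equivalent placement against the supplied reference context
  (trim-and-shift; idempotent). Cohort counting and whitelist lookups
  key on `(chrom, pos, ref, alt)` after normalization.

## Coverage QC

* aDOC of a region = sum of per-base depth / region length; gene-level
  aDOC is the length-weighted mean over the gene's regions
  (equivalently, a concatenated-profile mean).
* On-target fraction is **base-level**: aligned bases falling inside
  the merged design divided by all aligned bases. Read-level
  classification (`on_target` / `overlap_target` / `off_target`) is a
  separate report.
* Low-coverage flagging is strict: `aDOC < 40.0` flags a region
  (exactly 40 does not), annotated with `gc_flag = gc > 0.60`, `None`
  when the design carries no GC value. An alternative `min_doc` mode
  flags on the minimum per-base depth instead.

## Artifact filter

Three independent predicates; a call is removed iff at least one fails.
All boundaries are strict by design:

1. **VAF rule** — fail iff `reads_variant / depth_total < 0.20`.
   Exactly 20% passes. A zero-depth site fails degenerately.
2. **Strand rule** (indels only) — fail iff `reads_variant > 20` and
   `min(fwd, rev) / reads_variant < 0.10`. Exactly 20 supporting reads
   is exempt; exactly 10% passes; unknown strand counts pass. The
   denominator is variant reads; a config switch (`strand_denominator =
   "total_depth"`) gates the depth test on site depth instead, since
   source descriptions of such filters are ambiguous on this point.
3. **Distance rule** (indels only) — fail iff the call lies more than
   20 bp from the nearest exon. Exactly 20 bp passes. SNVs always pass
   rules 2 and 3.

## Cohort masking (prioritization)

A variant is a candidate iff it is whitelisted (known pathogenic) or
(`cohort_count <= 4` and `exon_distance <= 20`). The cohort count is
per-DNA: a homozygous call still counts its patient once. Unlike
artifact rule 3, the distance criterion here applies to SNVs too.
Masking reasons (`cohort_frequent`, `deep_intronic`) are recorded per
variant. The cohort index may be rebuilt from the run itself or frozen
from a reference cohort (diagnostic mode).

## Classification

An ordered, first-match rule table over an evidence vector
(`ptc, control_af, patient_af, missense_score, splice_delta,
minigene_result, segregation_consistent, genotype_context`; `None` =
unknown) maps to `Neutral < UV1 < UV2 < UV3 < UV4 < Pathogenic`.
Totality is enforced: a table without a catch-all default rule is
rejected at load time; rules after the default, or duplicate predicates
with conflicting classes, warn. Default thresholds: `control_af > 0.01`
is "common"; scores `>= 0.8` are damaging, `[0.5, 0.8)` moderately
suggestive. Conditions may declare `allow_unknown` so that a missing
value does not block a rule. An all-unknown vector is an error, not a
class. In-silico scores are opaque numbers in [0, 1]; the predictors
themselves are out of scope.

## Synthetic data generator

Scope: the generator produces *calibration-shaped* data for exercising
and validating the pipeline — it is not a sequencing simulator. No
reads, alignments, or base qualities are produced; depth and call
tables are drawn directly.

* **Panel**: one chromosome per gene; log-normal exon lengths (mean
  170 bp, σ=0.45 on the log scale); ~634 exons at default scale; every
  exon gets explicit 100 bp intronic flanks, and ~25% of introns are
  drawn short so flanks overlap and the merged design has fewer
  components than regions. GC per region is a Beta mixture with a
  GC-rich minority.
* **Depth**: per-base negative binomial (variance = m + m²/r, r = 20)
  around a designed regional mean = 77× × GC penalty (slope 2.0 above
  50% GC) × log-normal capture efficiency (σ=0.35).
* **Calls per patient** (defaults): ~7.5 rare true variants, ~332
  expected carriages from a shared pool of 600 (carrier counts uniform
  on {5..47}), 20 deep-intronic SNVs, 3894 low-VAF noise calls, 250
  strand-biased homopolymer indels, 170 deep-intronic indels — ≈4674
  raw calls, of which the three artifact classes (≈92%) sit strictly
  inside the filter's rejection regimes, and true variants sit strictly
  inside the retention regime (VAF ≥ 0.25; minor strand ≥ 20% whenever
  the strand rule applies). Truth labels are returned separately; the
  emitted tables carry no truth columns. One shared variant is
  whitelisted, as are ~15% of rare true variants.
* **Concordance study**: 687 true variants over 24 patients, of which
  exactly 13 are constructed to escape detection — 6 emitted with a
  homopolymer strand-bias signature (correctly removed by the filter),
  4 "misaligned" and 3 "low coverage" never emitted. The resulting
  sensitivity, 674/687, is exact by construction, not an empirical
  estimate.
* **Determinism**: `SimulationConfig.seed` is mandatory; panel,
  coverage, cohort and study use `seed`, `seed+1`, `seed+2`, `seed+3`
  respectively, so stages are independently reproducible. Per-patient
  key collisions are prevented at generation time so that every emitted
  call has exactly one truth label.

## Numerical choices

* Depth arrays are int64 numpy; aDOC and fractions are double
  precision; no accumulation tricks are needed at panel scale.
* Reports are JSON with sorted keys and no timestamps/hostnames, so
  identical inputs give byte-identical output.
* `evaluate_filters` counts every true variant (emitted or not) in the
  sensitivity denominator, as a concordance study against a prior gold
  standard would; retained keys unknown to the truth table abort.

## Limitations

* The generator draws calls, not reads: alignment, base-calling and
  caller behavior are modeled only through their end effects (the
  artifact regimes and the constructed failure categories).
* Cohort-level sensitivity of *candidates* (post-masking) on a
  simulated cohort undercounts by design: true variants shared by ≥5
  DNAs are masked unless whitelisted, exactly as the pipeline intends —
  use the filter-stage evaluation for detection sensitivity.
* The classifier's default thresholds are conventional round numbers,
  not fitted values; laboratories are expected to ship their own table.
* VCF ingestion maps `AD`/`DP` only; per-strand counts from VCF are
  unknown (`None`), which the strand rule treats as passing.
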