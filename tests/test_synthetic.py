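import dataclasses

import numpy as np
import pytest

from pyropanel.artifact_filter import evaluate as filter_evaluate
from pyropanel.coverage_qc import compute_adoc
from pyropanel.panel_model import merge_regions
from pyropanel.synthetic import (
    SimulationConfig,
    TruthRecord,
    TruthTable,
    evaluate_filters,
    panel_with_merge_structure,
    simulate_cohort,
    simulate_coverage,
    simulate_panel,
    simulate_sensitivity_study,
)
from pyropanel.variant_model import annotate


def small_cfg(seed=7, **kw):
    """A scaled-down cohort so module tests stay fast; rate structure is
    the same as the defaults, only the magnitudes shrink."""
    defaults = dict(
        seed=seed,
        n_genes=4,
        mean_exons_per_gene=8.0,
        n_patients=6,
        true_rare_per_patient=4.0,
        shared_pool_size=40,
        deep_intronic_snvs_per_patient=5.0,
        low_vaf_noise_per_patient=60.0,
        strand_indels_per_patient=15.0,
        deep_intronic_indels_per_patient=10.0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestPanel:
    def test_deterministic_under_seed(self):
        a = simulate_panel(small_cfg(seed=11))
        b = simulate_panel(small_cfg(seed=11))
        assert a.regions == b.regions

    def test_seed_changes_panel(self):
        a = simulate_panel(small_cfg(seed=11))
        b = simulate_panel(small_cfg(seed=12))
        assert a.regions != b.regions

    def test_flanks_present_for_every_exon(self):
        design = simulate_panel(small_cfg())
        exons = [r for r in design.regions if r.feature == "exon"]
        flanks = [r for r in design.regions if r.feature == "intronic_extension"]
        assert exons and flanks
        # every exon has an abutting flank on each side
        flank_edges = {(f.chrom, f.end) for f in flanks} | {
            (f.chrom, f.start) for f in flanks
        }
        for e in exons:
            assert (e.chrom, e.start) in flank_edges
            assert (e.chrom, e.end) in flank_edges

    def test_merge_structure_builder(self):
        design = panel_with_merge_structure(634, 535, seed=3)
        assert len(design.regions) == 634
        merged = merge_regions(design.regions)
        assert len(merged) == 535

    def test_gc_fractions_in_range(self):
        design = simulate_panel(small_cfg())
        assert all(0.0 <= r.gc_fraction <= 1.0 for r in design.regions)


class TestCoverage:
    def test_deterministic_under_seed(self):
        cfg = small_cfg(seed=21)
        design = simulate_panel(cfg)
        p1, _ = simulate_coverage(design, cfg)
        p2, _ = simulate_coverage(design, cfg)
        for a, b in zip(p1, p2):
            assert np.array_equal(a.depths, b.depths)

    def test_unbiased_when_gc_and_efficiency_disabled(self):
        cfg = small_cfg(seed=5, gc_depth_slope=0.0, region_efficiency_sigma=0.0)
        design = simulate_panel(cfg)
        profiles, _ = simulate_coverage(design, cfg)
        depths = np.concatenate([p.depths for p in profiles])
        n = len(depths)
        m, r = cfg.mean_depth, cfg.depth_dispersion
        se = np.sqrt((m + m * m / r) / n)
        assert abs(depths.mean() - m) < 3 * se

    def test_gc_rich_regions_run_shallower(self):
        cfg = small_cfg(seed=5, region_efficiency_sigma=0.0)
        design = simulate_panel(cfg)
        profiles, _ = simulate_coverage(design, cfg)
        rich = [compute_adoc(p) for p in profiles if p.region.gc_fraction > 0.62]
        normal = [compute_adoc(p) for p in profiles if p.region.gc_fraction <= 0.55]
        if not rich:
            pytest.skip("no GC-rich region drawn in this panel")
        assert np.mean(rich) < np.mean(normal)

    def test_designed_adoc_recorded_for_every_region(self):
        cfg = small_cfg()
        design = simulate_panel(cfg)
        _, truth = simulate_coverage(design, cfg)
        assert set(truth.designed_adoc) == set(design.regions)


class TestCohort:
    def test_deterministic_under_seed(self):
        cfg = small_cfg(seed=31)
        design = simulate_panel(cfg)
        c1, t1, w1 = simulate_cohort(design, cfg)
        c2, t2, w2 = simulate_cohort(design, cfg)
        assert c1 == c2
        assert t1.records == t2.records
        assert w1 == w2

    def test_one_truth_label_per_emitted_call(self):
        cfg = small_cfg(seed=31)
        design = simulate_panel(cfg)
        calls, truth, _ = simulate_cohort(design, cfg)
        emitted_truth = {}
        for r in truth.records:
            if r.emitted:
                assert r.full_key not in emitted_truth, "duplicate truth key"
                emitted_truth[r.full_key] = r.label
        for pid, table in calls.items():
            keys = [(pid, *c.key) for c in table]
            assert len(keys) == len(set(keys)), "duplicate call within a patient"
            for k in keys:
                assert k in emitted_truth, "call without a truth record"

    def test_emitted_tables_carry_no_truth_columns(self):
        cfg = small_cfg()
        design = simulate_panel(cfg)
        calls, _, _ = simulate_cohort(design, cfg)
        sample = next(iter(calls.values()))[0]
        field_names = {f.name for f in dataclasses.fields(sample)}
        assert "label" not in field_names and "emitted" not in field_names

    def test_artifact_regimes_match_their_filter_rules(self):
        cfg = small_cfg(seed=31)
        design = simulate_panel(cfg)
        calls, truth, _ = simulate_cohort(design, cfg)
        by_key = {
            (c.patient_id, *c.key): c for table in calls.values() for c in table
        }
        checked = {"artifact:low_vaf": 0, "artifact:strand": 0, "artifact:deep_intronic": 0}
        for r in truth.records:
            if not r.emitted or r.label == "true_variant":
                continue
            verdict = filter_evaluate(annotate(by_key[r.full_key], design))
            rule = {
                "artifact:low_vaf": "vaf",
                "artifact:strand": "strand",
                "artifact:deep_intronic": "distance",
            }[r.label]
            assert rule in verdict.failed_rules, (r.label, r.full_key)
            checked[r.label] += 1
        assert all(n > 0 for n in checked.values())

    def test_true_variants_survive_the_filter(self):
        cfg = small_cfg(seed=31)
        design = simulate_panel(cfg)
        calls, truth, _ = simulate_cohort(design, cfg)
        by_key = {
            (c.patient_id, *c.key): c for table in calls.values() for c in table
        }
        n = 0
        for r in truth.records:
            if r.emitted and r.label == "true_variant":
                assert filter_evaluate(annotate(by_key[r.full_key], design)).passed
                n += 1
        assert n > 0

    def test_zero_artifact_rates_emit_only_true_variants(self):
        cfg = small_cfg(
            seed=31,
            low_vaf_noise_per_patient=0.0,
            strand_indels_per_patient=0.0,
            deep_intronic_indels_per_patient=0.0,
            deep_intronic_snvs_per_patient=0.0,
        )
        design = simulate_panel(cfg)
        calls, truth, _ = simulate_cohort(design, cfg)
        assert all(r.label == "true_variant" for r in truth.records)
        assert sum(len(t) for t in calls.values()) == sum(
            1 for r in truth.records if r.emitted
        )

    def test_whitelist_entries_are_true_variants(self):
        cfg = small_cfg()
        design = simulate_panel(cfg)
        _, truth, whitelist = simulate_cohort(design, cfg)
        true_keys = {r.key for r in truth.records if r.label == "true_variant"}
        assert whitelist
        assert set(whitelist) <= true_keys
        whitelisted_records = [r for r in truth.records if r.whitelisted]
        assert {r.key for r in whitelisted_records} == set(whitelist)

    def test_shared_variants_recur_across_patients(self):
        cfg = small_cfg(seed=31)
        design = simulate_panel(cfg)
        _, truth, _ = simulate_cohort(design, cfg)
        shared = [r for r in truth.records if r.shared]
        assert shared
        carriers = {}
        for r in shared:
            carriers.setdefault(r.key, set()).add(r.patient_id)
        assert max(len(c) for c in carriers.values()) >= 2


class TestSensitivityStudy:
    def test_constructed_false_negative_counts(self):
        design, calls, truth = simulate_sensitivity_study(
            small_cfg(seed=41),
            n_true=100,
            n_homopolymer_fn=3,
            n_misaligned_fn=2,
            n_low_coverage_fn=1,
            n_patients=5,
        )
        assert len(truth.records) == 100
        not_emitted = [r for r in truth.records if not r.emitted]
        assert len(not_emitted) == 3  # misaligned + low-coverage never called
        homopoly = [r for r in truth.records if r.failure_category == "homopolymer"]
        assert len(homopoly) == 3
        # homopolymer false negatives are emitted but fail the strand rule
        by_key = {(c.patient_id, *c.key) for t in calls.values() for c in t}
        for r in homopoly:
            assert r.full_key in by_key

    def test_recovered_sensitivity_is_by_construction(self):
        cfg = small_cfg(seed=41)
        design, calls, truth = simulate_sensitivity_study(
            cfg, n_true=100, n_homopolymer_fn=3, n_misaligned_fn=2,
            n_low_coverage_fn=1, n_patients=5,
        )
        retained = {}
        for pid, table in calls.items():
            annotated = [annotate(c, design) for c in table]
            retained[pid] = [v.call for v in annotated if filter_evaluate(v).passed]
        report = evaluate_filters(truth, retained)
        assert report.n_true == 100
        assert report.n_true_detected == 94
        assert report.sensitivity == pytest.approx(0.94)
        assert report.false_negative_categories == {
            "homopolymer": 3,
            "misaligned": 2,
            "low_coverage": 1,
        }

    def test_too_many_false_negatives_rejected(self):
        with pytest.raises(ValueError):
            simulate_sensitivity_study(
                small_cfg(), n_true=5, n_homopolymer_fn=4, n_misaligned_fn=2,
                n_low_coverage_fn=0, n_patients=2,
            )


class TestEvaluateFilters:
    def _truth(self):
        return TruthTable(
            records=[
                TruthRecord("P1", "chr1", 10, "A", "G", "true_variant"),
                TruthRecord("P1", "chr1", 20, "A", "G", "artifact:low_vaf"),
                TruthRecord("P2", "chr1", 10, "A", "G", "true_variant", emitted=False,
                            failure_category="misaligned"),
            ]
        )

    def test_counts(self):
        report = evaluate_filters(self._truth(), {"P1": [("chr1", 10, "A", "G")]})
        assert report.n_true == 2
        assert report.n_true_detected == 1
        assert report.n_artifacts == 1
        assert report.n_artifacts_removed == 1
        assert report.false_negative_categories == {"misaligned": 1}
        assert report.confusion["true_variant"] == {"retained": 1, "removed": 1}

    def test_unknown_retained_key_aborts(self):
        with pytest.raises(ValueError, match="absent from the truth table"):
            evaluate_filters(self._truth(), {"P1": [("chr1", 99, "A", "G")]})

    def test_retained_key_of_unemitted_record_aborts(self):
        # P2's variant exists in the DNA but was never called; a pipeline
        # cannot legitimately "retain" it.
        with pytest.raises(ValueError):
            evaluate_filters(self._truth(), {"P2": [("chr1", 10, "A", "G")]})


def test_seed_is_mandatory():
    with pytest.raises(TypeError):
        SimulationConfig()  # no seed


def test_negative_rate_rejected():
    with pytest.raises(ValueError):
        small_cfg(low_vaf_noise_per_patient=-1.0)
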