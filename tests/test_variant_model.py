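import math

import pytest

from pyropanel.panel_model import PanelDesign, TargetRegion
from pyropanel.prioritizer import build_cohort_index
from pyropanel.variant_model import (
    CallError,
    ReferenceContext,
    VariantCall,
    annotate,
    infer_vtype,
    left_normalize,
    read_calls,
    read_whitelist,
    write_calls,
    write_whitelist,
)

from conftest import make_call


class TestVariantCall:
    def test_strand_counts_must_sum(self):
        with pytest.raises(CallError):
            VariantCall("P", "chr1", 10, "A", "G", 100, 50, 20, 20)

    def test_variant_reads_cannot_exceed_depth(self):
        with pytest.raises(CallError):
            VariantCall("P", "chr1", 10, "A", "G", 40, 50, 25, 25)

    def test_vaf_and_key(self):
        call = make_call(depth=80, reads=20)
        assert call.vaf == pytest.approx(0.25)
        assert call.key == ("chr1", 150, "A", "G")

    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("A", "G", "snv"),
            ("A", "AT", "ins"),
            ("AG", "A", "del"),
            ("AG", "TC", "delins"),
            ("A", "TG", "delins"),
        ],
    )
    def test_vtype_inference(self, ref, alt, expected):
        assert infer_vtype(ref, alt) == expected


class TestReadCalls:
    def test_well_formed_tsv(self, tmp_path):
        rows = [
            f"chr1\t{100 + i}\tA\tG\t100\t50\t25\t25" for i in range(5)
        ]
        path = tmp_path / "P001.tsv"
        path.write_text("\n".join(rows) + "\n")
        calls = read_calls(path, "gsdiff_tsv")
        assert len(calls) == 5
        assert calls[0].patient_id == "P001"

    def test_invariant_violating_record_rejected_individually(self, tmp_path):
        rows = [
            "chrom\tpos\tref\talt\tdepth_total\treads_variant\treads_fwd\treads_rev",
            "chr1\t100\tA\tG\t100\t50\t25\t25",
            "chr1\t101\tA\tG\t40\t50\t25\t25",  # variant reads > depth
            "chr1\t102\tA\tG\t100\t50\t25\t25",
            "chr1\t103\tA\tG\t100\t50\t10\t25",  # strands do not sum
            "chr1\t104\tA\tG\t100\t50\t25\t25",
        ]
        path = tmp_path / "P002.tsv"
        path.write_text("\n".join(rows) + "\n")
        calls = read_calls(path, "gsdiff_tsv")
        assert [c.pos for c in calls] == [100, 102, 104]

    def test_file_level_syntax_error_aborts(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chr1\t100\tA\tG\t100\n")
        with pytest.raises(CallError):
            read_calls(path, "gsdiff_tsv")

    def test_round_trip(self, tmp_path):
        calls = [make_call(pos=100 + i) for i in range(4)]
        path = tmp_path / "P001.tsv"
        write_calls(calls, path)
        assert read_calls(path) == calls

    def test_vcf_ad_mapping_strands_unknown(self, tmp_path):
        vcf = tmp_path / "P003.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t150\t.\tA\tG\t.\t.\t.\tGT:AD:DP\t0/1:80,20:100\n"
        )
        calls = read_calls(vcf, "vcf")
        assert len(calls) == 1
        assert calls[0].vaf == pytest.approx(0.20)
        assert calls[0].reads_fwd is None and calls[0].reads_rev is None


class TestLeftNormalize:
    def test_deletion_in_homopolymer_anchored_at_run_start(self):
        # reference: positions 8..15 = T A G G G G C T ; delete one G
        ctx = ReferenceContext("chr1", 8, "TAGGGGCT")
        call = make_call(pos=12, ref="GG", alt="G", reads=30)
        norm = left_normalize(call, ctx)
        assert (norm.pos, norm.ref, norm.alt) == (9, "AG", "A")

    def test_snv_unchanged(self):
        ctx = ReferenceContext("chr1", 140, "ACGTACGTACGTACGTACGT")
        call = make_call(pos=150, ref="A", alt="G")
        assert left_normalize(call, ctx) is call

    def test_idempotent(self):
        ctx = ReferenceContext("chr1", 8, "TAGGGGCT")
        call = make_call(pos=12, ref="GG", alt="G", reads=30)
        once = left_normalize(call, ctx)
        assert left_normalize(once, ctx) == once

    def test_context_too_short_keeps_call(self):
        ctx = ReferenceContext("chr1", 12, "GGGG")
        call = make_call(pos=12, ref="GG", alt="G", reads=30)
        assert left_normalize(call, ctx) == call

    def test_haplotype_preserved_against_enumeration_oracle(self, rng):
        """Applying the edit before and after normalization must give the
        same sequence, and the normalized anchor must be the leftmost of
        all equivalent placements found by exhaustive shifting."""
        bases = "ACGT"
        for _ in range(50):
            seq = "".join(rng.choice(list(bases), size=30))
            start = 5
            anchor = int(rng.integers(start + 5, start + 25))
            if rng.random() < 0.5:  # deletion of 1-2 bases
                k = int(rng.integers(1, 3))
                ref = seq[anchor - start : anchor - start + 1 + k]
                alt = ref[0]
                if len(ref) < 1 + k:
                    continue
            else:  # insertion of 1-2 bases
                ref = seq[anchor - start]
                ins = "".join(rng.choice(list(bases), size=int(rng.integers(1, 3))))
                alt = ref + ins
            ctx = ReferenceContext("chr1", start, seq)
            call = VariantCall("P", "chr1", anchor, ref, alt, 100, 30, 15, 15)
            norm = left_normalize(call, ctx)

            def apply_edit(pos, r, a):
                off = pos - start
                assert seq[off : off + len(r)] == r
                return seq[:off] + a + seq[off + len(r) :]

            assert apply_edit(norm.pos, norm.ref, norm.alt) == apply_edit(
                anchor, ref, alt
            )
            # leftmost equivalence: no equivalent placement exists further left
            edited = apply_edit(anchor, ref, alt)
            for pos in range(start + 1, norm.pos):
                r2 = seq[pos - start : pos - start + len(norm.ref)]
                if len(r2) == len(norm.ref):
                    candidate = apply_edit(pos, r2, r2[: len(norm.alt)])
                    # only deletions enumerate cleanly; equality check suffices
                    if candidate == edited and len(norm.ref) > len(norm.alt):
                        pytest.fail(f"placement at {pos} also matches: {call}")


class TestAnnotate:
    def test_whitelisted_exonic_snv(self, small_design):
        call = make_call(pos=150)
        ann = annotate(call, small_design, whitelist={call.key})
        assert ann.known_pathogenic
        assert ann.exon_distance == 0
        assert ann.location_class == "exonic"
        assert ann.gene == "GENE01"

    def test_deep_intronic_boundary(self, small_design):
        near = annotate(make_call(pos=220), small_design)  # 20 bp into the intron
        deep = annotate(make_call(pos=225), small_design)  # 25 bp
        assert near.location_class == "near_splice"
        assert deep.location_class == "deep_intronic"
        assert deep.exon_distance == 25

    def test_off_panel_variant(self, small_design):
        ann = annotate(make_call(pos=350), small_design)
        assert ann.location_class == "off_gene"
        assert ann.gene is None

    def test_cohort_count_from_index(self, small_design):
        shared = [make_call(patient=f"P{i}") for i in range(6)]
        unique = make_call(patient="P9", pos=155)
        index = build_cohort_index([[c] for c in shared[:5]] + [[shared[5], unique]])
        ann = annotate(shared[0], small_design, cohort_index=index)
        assert ann.cohort_count == 6
        assert annotate(unique, small_design, cohort_index=index).cohort_count == 1

    def test_deterministic(self, small_design):
        call = make_call()
        assert annotate(call, small_design) == annotate(call, small_design)


def test_whitelist_round_trip(tmp_path):
    entries = {
        ("chr1", 150, "A", "G"): ("GENE01", "c.150A>G", "Pathogenic"),
        ("chr2", 99, "AG", "A"): ("GENE02", "c.99delG", "Pathogenic"),
    }
    path = tmp_path / "whitelist.tsv"
    write_whitelist(entries, path)
    table = read_whitelist(path)
    assert set(table) == set(entries)
    assert table[("chr1", 150, "A", "G")] == "Pathogenic"
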