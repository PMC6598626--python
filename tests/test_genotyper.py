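"""Read classification, diploid calling, phasing and the phantom-variant scan."""

from collections import Counter

import numpy as np
import pytest

from msh3rep.align import DEFAULT_SCORING, SUBSTITUTION_FAVORING
from msh3rep.errors import AlignmentError, NoCallError
from msh3rep.genotyper import (
    artefact_scan,
    call_genotype,
    classify_read,
    classify_reads,
    genotype_reads,
    merge_pairs,
    write_sam,
)
from msh3rep.locus import render_allele_sequence
from msh3rep.simulate import SimulationConfig, simulate_reads

from .conftest import make_hap


def truth_key(*haps):
    return frozenset(Counter(h.key() for h in haps).items())


class TestClassify:
    def test_full_span_read_identifies_its_allele(self, locus, bank):
        for allele in ("3a", "6a", "7a", "8b"):
            c = classify_read(bank[allele], bank)
            assert c.best_allele == allele and c.margin > 0 and not c.ambiguous

    def test_flank_only_read_is_ambiguous(self, locus, bank):
        read = bank["6a"][:200]  # left flank only: identical across alleles
        c = classify_read(read, bank)
        assert c.ambiguous and c.margin == 0
        assert set(c.co_optimal) == set(bank)

    def test_prefix_consistent_partial_read_is_ambiguous(self, locus, bank):
        # left flank + 4 reference units: consistent with 7a, 8a, 9a, ...
        read = bank["7a"][: len(locus.left_flank) + 36]
        c = classify_read(read, bank, band=None)
        assert c.ambiguous
        assert {"7a", "8a", "9a"} <= set(c.co_optimal)

    def test_bank_of_one_rejected(self, bank):
        with pytest.raises(AlignmentError):
            classify_read(bank["6a"], {"6a": bank["6a"]})


class TestCallGenotype:
    def test_homozygote_all_reference(self, locus, bank):
        reads = [bank["6a"]] * 100
        call = genotype_reads(reads, locus)
        assert call.repeat_genotype == ("6a", "6a")
        assert all(n == 0 for n in call.variant_genotypes.values())
        assert call.n_unambiguous == 100

    def test_het_with_phased_snp(self, locus):
        h3 = make_hap(locus, "3a", ["rs10168"])
        h6 = make_hap(locus, "6a")
        reads = [render_allele_sequence(locus, h3)] * 50 + [
            render_allele_sequence(locus, h6)
        ] * 50
        call = genotype_reads(reads, locus)
        assert call.haplotype_keys() == truth_key(h3, h6)
        by_allele = {h.repeat_allele: h for h in call.haplotypes}
        assert by_allele["3a"].variant_alleles["rs10168"] == "alt"
        assert by_allele["6a"].variant_alleles["rs10168"] == "ref"

    def test_indel_variant_called_and_phased(self, locus):
        h7 = make_hap(locus, "7a", ["msh3_1bp_del"])
        h6 = make_hap(locus, "6a")
        reads = [render_allele_sequence(locus, h7)] * 40 + [
            render_allele_sequence(locus, h6)
        ] * 40
        call = genotype_reads(reads, locus)
        assert call.haplotype_keys() == truth_key(h7, h6)

    def test_minor_reads_below_threshold_flagged_hom_call(self, locus, bank):
        reads = [bank["6a"]] * 95 + [bank["3a"]] * 5
        call = genotype_reads(reads, locus, min_hap_frac=0.2)
        assert call.repeat_genotype == ("6a", "6a")
        assert any(f.startswith("minor_allele_reads") for f in call.flags)

    def test_repeat_homozygote_variant_partitioning(self, locus):
        # same repeat allele, different variant vectors: read-backed phasing
        ha = make_hap(locus, "6a", ["rs1105524", "rs1650697"])
        hb = make_hap(locus, "6a")
        reads = [render_allele_sequence(locus, ha)] * 55 + [
            render_allele_sequence(locus, hb)
        ] * 45
        call = genotype_reads(reads, locus)
        assert call.haplotype_keys() == truth_key(ha, hb)

    def test_low_depth_is_a_no_call(self, locus, bank):
        with pytest.raises(NoCallError):
            genotype_reads([bank["6a"]] * 10, locus, min_depth=30)

    def test_three_way_mixture_flags_contamination(self, locus, bank):
        reads = [bank["3a"]] * 40 + [bank["6a"]] * 35 + [bank["8a"]] * 25
        call = genotype_reads(reads, locus)
        assert any(f.startswith("contamination") for f in call.flags)
        assert call.repeat_genotype == ("3a", "6a")


class TestArtefact:
    def test_matching_reference_scan_is_clean(self, locus, bank):
        assert artefact_scan([bank["6a"]] * 20, locus, "6a") == []

    def test_three_vs_six_creates_in_repeat_substitution(self, locus, bank):
        found = artefact_scan(
            [bank["3a"]] * 20, locus, "6a", scoring=SUBSTITUTION_FAVORING
        )
        subs = [v for v in found if v.classification == "substitution" and v.in_repeat]
        assert subs and all(v.fraction == 1.0 for v in subs)

    def test_default_scoring_shows_unit_multiple_deletion(self, locus, bank):
        found = artefact_scan([bank["3a"]] * 20, locus, "6a", scoring=DEFAULT_SCORING)
        dels = [v for v in found if v.classification == "deletion" and v.in_repeat]
        assert len(dels) == 27  # a full 27-bp (three-unit) phantom deletion

    def test_bank_resolution_ends_the_artefact(self, locus, bank):
        reads = [bank["3a"]] * 20
        cls = classify_reads(reads, bank)
        assert all(c.best_allele == "3a" and not c.ambiguous for c in cls)
        assert artefact_scan(reads, locus, "3a") == []

    def test_artefact_dichotomy_across_allele_pairs(self, locus, bank):
        # full-span reads from A forced on B != A always leave a trace
        for a in ("3a", "6a", "7a"):
            for b in ("3a", "6b", "8a"):
                if a == b:
                    continue
                found = artefact_scan([bank[a]] * 5, locus, b)
                assert found, f"{a} vs {b} left no apparent variants"

    def test_scan_without_repeat_coverage_raises(self, locus, bank):
        flank_read = bank["6a"][:100]
        with pytest.raises(AlignmentError):
            artefact_scan([flank_read] * 5, locus, "6a", band=None)


class TestEndToEnd:
    def test_simulated_diploids_recover_exactly(self, locus):
        table = [
            (make_hap(locus, "3a", ["rs151182735", "rs10168", "rs2250063"]), None),
            (make_hap(locus, "6a"), None),
            (make_hap(locus, "7a", ["msh3_1bp_del"]), None),
            (make_hap(locus, "8a"), None),
        ]
        cfg = SimulationConfig(seed=42, coverage=60, error_rate=0.005)
        rng = np.random.default_rng(99)
        ok = 0
        pairs = [(0, 1), (1, 1), (0, 2), (2, 3), (3, 3), (0, 0)]
        for i, j in pairs:
            pair = (table[i][0], table[j][0])
            fwd, rev = simulate_reads(locus, pair, cfg, rng=rng)
            merged = [m.sequence for m in merge_pairs(fwd, rev) if m.merged]
            call = genotype_reads(merged, locus)
            ok += call.haplotype_keys() == truth_key(*pair)
        assert ok == len(pairs)

    def test_sam_output_is_readable(self, locus, bank, tmp_path):
        import pysam

        from msh3rep.align import align_to_reference
        from msh3rep.genotyper import MergedRead

        reads = [
            MergedRead(f"r{i}", bank["3a"], tuple([38] * len(bank["3a"])), True, 50)
            for i in range(3)
        ]
        recs = [
            (m, align_to_reference(m.sequence, bank["3a"], reference_id="3a", band=25))
            for m in reads
        ]
        path = tmp_path / "subject.sam"
        write_sam(path, recs, locus, comment="test")
        with pysam.AlignmentFile(str(path)) as sam:
            rows = list(sam)
        assert len(rows) == 3
        assert all(r.reference_name == "3a" and r.cigarstring for r in rows)
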