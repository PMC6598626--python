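"""Synthetic-data generators: determinism, error model, cohort structure."""

import numpy as np
import pytest

from msh3rep.association import hwe_test, ld_stats
from msh3rep.errors import ConfigError
from msh3rep.simulate import (
    EffectSizes,
    SimulationConfig,
    build_haplotype_table,
    default_haplotype_table,
    simulate_cohort,
    simulate_reads,
    simulate_repeat_distribution,
    write_fastq,
)

from .conftest import make_hap


class TestReads:
    def test_error_free_reads_are_exact_substrings(self, locus):
        cfg = SimulationConfig(seed=0, coverage=50, error_rate=0.0)
        hap = make_hap(locus, "6a")
        amp = None
        fwd, rev = simulate_reads(locus, (hap, hap), cfg)
        from msh3rep.locus import render_allele_sequence, revcomp

        amp = render_allele_sequence(locus, hap)
        assert all(seq in amp for _, seq, _ in fwd)
        assert all(revcomp(seq) in amp for _, seq, _ in rev)

    def test_pooled_mismatch_fraction_matches_error_rate(self, locus):
        rate = 0.01
        cfg = SimulationConfig(seed=1, coverage=2000, error_rate=rate)
        hap = make_hap(locus, "6a")
        from msh3rep.locus import render_allele_sequence

        amp = render_allele_sequence(locus, hap)
        fwd, _ = simulate_reads(locus, (hap, hap), cfg)
        truth = np.frombuffer(amp[:400].encode(), dtype=np.uint8)
        mism = total = 0
        for _, seq, _ in fwd:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            mism += int((arr != truth).sum())
            total += arr.size
        se = np.sqrt(rate * (1 - rate) / total)
        assert abs(mism / total - rate) < 3 * se

    def test_same_seed_gives_byte_identical_fastq(self, locus, tmp_path):
        cfg = SimulationConfig(seed=7, coverage=20, error_rate=0.01)
        hap = make_hap(locus, "3a")
        paths = []
        for tag in ("a", "b"):
            fwd, _ = simulate_reads(locus, (hap, hap), cfg)
            p = tmp_path / f"{tag}.fastq"
            write_fastq(p, fwd)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_amplicon_shorter_than_read_rejected(self, locus):
        cfg = SimulationConfig(seed=0, read_len_fwd=600)
        with pytest.raises(ConfigError):
            simulate_reads(locus, (make_hap(locus, "3a"), make_hap(locus, "3a")), cfg)


class TestRepeatDistribution:
    def test_zero_rate_keeps_all_reads_at_progenitor(self):
        cfg = SimulationConfig(seed=0)
        d = simulate_repeat_distribution(100, 50.0, 0.0, cfg)
        assert d.counts == {100: cfg.instability_reads}

    def test_gain_increases_with_age_rate_and_length(self):
        cfg = SimulationConfig(seed=0, instability_reads=10_000)

        def mean_gain(progenitor, age, rate, seed):
            d = simulate_repeat_distribution(
                progenitor, age, rate, cfg, rng=np.random.default_rng(seed)
            )
            return sum((k - progenitor) * v for k, v in d.counts.items()) / d.total

        assert mean_gain(100, 60, 0.05, 5) > mean_gain(100, 20, 0.05, 5)
        assert mean_gain(100, 40, 0.10, 5) > mean_gain(100, 40, 0.02, 5)
        assert mean_gain(300, 40, 0.05, 5) > mean_gain(80, 40, 0.05, 5)

    def test_distribution_is_seed_deterministic(self):
        cfg = SimulationConfig(seed=3)
        a = simulate_repeat_distribution(42, 55.0, 0.08, cfg)
        b = simulate_repeat_distribution(42, 55.0, 0.08, cfg)
        assert a.counts == b.counts

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigError):
            simulate_repeat_distribution(100, 50.0, -0.1, SimulationConfig(seed=0))


class TestCohort:
    def test_null_effects_give_null_onset_association(self, locus):
        from msh3rep.association import fit_marker

        cfg = SimulationConfig(
            seed=11, cohort_size=2000, effects=EffectSizes().null()
        )
        df = simulate_cohort(locus, cfg, include_expansion=False)
        r = fit_marker(df, "3a", "onset", "HD")
        assert abs(r.beta) < 3 * r.se

    def test_onset_effect_recovered_within_two_se(self, locus):
        from msh3rep.association import fit_marker

        cfg = SimulationConfig(seed=13, cohort_size=2000)
        df = simulate_cohort(locus, cfg, include_expansion=False)
        r = fit_marker(df, "3a", "onset", "HD")
        assert abs(r.beta - 1.05) < 2 * r.se

    def test_constructed_snps_in_complete_ld_with_3a(self, locus):
        cfg = SimulationConfig(seed=17, cohort_size=500)
        df = simulate_cohort(locus, cfg, include_expansion=False)
        haps = [h for pair in df.attrs["haplotypes"] for h in pair]
        for vid in ("rs151182735", "rs10168", "rs2250063"):
            pairs = [
                (int(h.repeat_allele == "3a"), int(h.variant_alleles[vid] == "alt"))
                for h in haps
            ]
            assert ld_stats(pairs).r2 == 1.0

    def test_allele_frequencies_converge_to_targets(self, locus):
        cfg = SimulationConfig(seed=19, cohort_size=4000)
        df = simulate_cohort(locus, cfg, include_expansion=False)
        target = sum(f for h, f in default_haplotype_table(locus) if h.repeat_allele == "3a")
        n_chr = 2 * len(df)
        observed = df["dos_3a"].sum() / n_chr
        se = np.sqrt(target * (1 - target) / n_chr)
        assert abs(observed - target) < 3 * se

    def test_random_mating_cohorts_are_in_hwe(self, locus):
        ps = []
        for seed in range(8):
            cfg = SimulationConfig(seed=seed, cohort_size=400)
            df = simulate_cohort(locus, cfg, include_expansion=False)
            dos = df["dos_rs1105524"].astype(int)
            counts = ((dos == 0).sum(), (dos == 1).sum(), (dos == 2).sum())
            ps.append(hwe_test(counts, "exact").p)
        assert min(ps) > 1e-3  # no systematic HWE violation across replicates

    def test_expansion_index_is_computed_not_injected(self, locus):
        cfg = SimulationConfig(seed=23, cohort_size=40)
        df, dists = simulate_cohort(locus, cfg, return_distributions=True)
        from msh3rep.instability import expansion_index_hd

        for _, row in df.head(10).iterrows():
            recomputed = expansion_index_hd(dists[row["subject"]]).value
            assert row["expansion_index"] == pytest.approx(recomputed, abs=1e-5)

    def test_cohort_is_seed_deterministic(self, locus):
        cfg = SimulationConfig(seed=29, cohort_size=60)
        a = simulate_cohort(locus, cfg)
        b = simulate_cohort(locus, cfg)
        assert a.drop(columns=["hap1", "hap2"]).equals(b.drop(columns=["hap1", "hap2"]))

    def test_dm1_cohort_has_interruptions_and_modal_shift(self, locus):
        cfg = SimulationConfig(seed=31, cohort_size=300, disease="DM1")
        df = simulate_cohort(locus, cfg)
        assert 0 < df["interrupted"].sum() < len(df)
        assert df["progression"].isna().all()
        assert (df["expansion_index"] == df["expansion_index"].round()).all()


class TestHaplotypeConstruction:
    def test_infeasible_ld_target_names_the_bound(self, locus):
        with pytest.raises(ConfigError, match="D'max"):
            build_haplotype_table(
                locus,
                {"3a": 0.05, "6a": 0.95},
                {"rs10168": 0.5},
                {"rs10168": 0.9},
            )

    def test_feasible_targets_are_approximately_hit(self, locus):
        table = build_haplotype_table(
            locus,
            {"3a": 0.2, "6a": 0.8},
            {"rs10168": 0.2, "rs1105524": 0.3},
            {"rs10168": 1.0, "rs1105524": 0.25},
        )
        cfg = SimulationConfig(seed=37, cohort_size=3000, haplotype_freqs=table)
        df = simulate_cohort(locus, cfg, include_expansion=False)
        haps = [h for pair in df.attrs["haplotypes"] for h in pair]
        pairs = [
            (int(h.repeat_allele == "3a"), int(h.variant_alleles["rs10168"] == "alt"))
            for h in haps
        ]
        assert ld_stats(pairs).r2 > 0.95
        pairs = [
            (int(h.repeat_allele == "3a"), int(h.variant_alleles["rs1105524"] == "alt"))
            for h in haps
        ]
        assert abs(ld_stats(pairs).r2 - 0.25) < 0.08
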