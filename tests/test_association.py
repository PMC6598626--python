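"""Regression engine, HWE, LD, haplotype summaries, meta-analysis, network."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from msh3rep.association import (
    AssociationResult,
    additive_dosage,
    conditional_fit,
    fit_additive,
    haplotype_frequencies,
    haplotype_network,
    hwe_test,
    ld_from_counts,
    ld_stats,
    meta_analysis,
    meta_z,
)
from msh3rep.errors import NotEstimableError
from msh3rep.locus import Haplotype

from .oracles import oracle_hwe_exact, oracle_ols, random_spanning_tree_weight


def _result(beta, se, p, n):
    t = beta / se
    return AssociationResult("m", "y", beta, se, t, p, n, n - 2, ())


class TestFitAdditive:
    def test_matches_normal_equations_on_hand_table(self):
        y = [61.2, 55.0, 58.3, 49.9, 63.1, 52.4, 60.0, 47.2, 66.5, 51.8, 57.7, 54.1]
        dos = [1, 0, 1, 0, 2, 0, 1, 0, 2, 0, 1, 1]
        cag = [42, 45, 43, 47, 41, 46, 44, 49, 40, 46, 43, 44]
        r = fit_additive(y, dos, {"cag": cag})
        X = np.column_stack([np.ones(12), dos, cag])
        beta, se, t, p = oracle_ols(y, X)
        assert r.beta == pytest.approx(beta[1], abs=1e-10)
        assert r.se == pytest.approx(se[1], abs=1e-10)
        assert r.t == pytest.approx(t[1], abs=1e-10)
        assert r.p == pytest.approx(p[1], abs=1e-10)

    def test_matches_oracle_on_random_small_designs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(8, 21))
            k = int(rng.integers(0, 3))  # extra covariates beyond dosage
            dos = rng.integers(0, 3, n).astype(float)
            if np.var(dos) == 0:
                dos[0] += 1
            cov = rng.normal(size=(n, k))
            y = rng.normal(size=n)
            covs = {f"c{i}": cov[:, i] for i in range(k)}
            r = fit_additive(y, dos, covs if k else None)
            X = np.column_stack([np.ones(n), dos, cov])
            beta, se, t, p = oracle_ols(y, X)
            assert r.beta == pytest.approx(beta[1], rel=1e-8, abs=1e-10)
            assert r.se == pytest.approx(se[1], rel=1e-8, abs=1e-10)
            assert r.p == pytest.approx(p[1], rel=1e-8, abs=1e-12)

    def test_constant_dosage_not_estimable(self):
        r = fit_additive([1.0, 2.0, 3.0, 4.0, 2.5], [1, 1, 1, 1, 1])
        assert not r.estimable and "zero variance" in r.note

    def test_nan_phenotypes_are_dropped(self):
        y = [1.0, np.nan, 2.0, 3.0, 2.5, 1.5]
        r = fit_additive(y, [0, 1, 2, 1, 0, 1])
        assert r.n == 5


class TestConditionalFit:
    def test_complete_ld_snp_flagged_with_dependency(self):
        rng = np.random.default_rng(1)
        dos3a = rng.integers(0, 3, 200).astype(float)
        y = 50 + 1.0 * dos3a + rng.normal(0, 2, 200)
        r = conditional_fit(y, dos3a.copy(), {"dos_3a": dos3a})
        assert not r.estimable
        assert "dos_3a" in r.note

    def test_independent_snp_effect_recovered(self):
        rng = np.random.default_rng(2)
        n = 1000
        dos3a = rng.integers(0, 3, n).astype(float)
        snp = rng.integers(0, 3, n).astype(float)
        y = 50 + 1.0 * dos3a + 0.8 * snp + rng.normal(0, 2, n)
        r = conditional_fit(y, snp, {"dos_3a": dos3a})
        assert r.estimable and abs(r.beta - 0.8) < 3 * r.se

    def test_empty_repeat_set_reduces_to_marginal_fit(self):
        rng = np.random.default_rng(3)
        snp = rng.integers(0, 3, 50).astype(float)
        y = rng.normal(size=50)
        marginal = fit_additive(y, snp)
        conditional = conditional_fit(y, snp, pd.DataFrame(index=range(50)))
        assert conditional.beta == pytest.approx(marginal.beta, abs=1e-12)


class TestHWE:
    def test_balanced_table_has_zero_chi2(self):
        r = hwe_test((25, 50, 25), "chi2")
        assert r.statistic == 0.0 and r.p == 1.0

    def test_monomorphic_p_is_one(self):
        assert hwe_test((40, 0, 0), "exact").p == 1.0
        assert hwe_test((0, 0, 17), "chi2").p == 1.0

    @pytest.mark.parametrize("counts", [(10, 10, 10), (3, 14, 5), (0, 10, 0), (7, 1, 9)])
    def test_exact_p_matches_enumeration_oracle(self, counts):
        assert hwe_test(counts, "exact").p == pytest.approx(oracle_hwe_exact(*counts), abs=1e-12)

    def test_exact_sweep_small_tables(self):
        for n in range(1, 13):
            for n_aa in range(n + 1):
                for n_ab in range(n - n_aa + 1):
                    counts = (n_aa, n_ab, n - n_aa - n_ab)
                    assert hwe_test(counts, "exact").p == pytest.approx(
                        oracle_hwe_exact(*counts), abs=1e-12
                    )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_test((-1, 2, 3))


class TestLD:
    def test_textbook_counts(self):
        s = ld_from_counts(40, 10, 10, 40)
        assert s.d == pytest.approx(0.15)
        assert s.d_prime == pytest.approx(0.6)
        assert s.r2 == pytest.approx(0.36)

    def test_duplicated_locus_is_complete_ld(self):
        pairs = [(1, 1)] * 30 + [(0, 0)] * 70
        s = ld_stats(pairs)
        assert s.d_prime == 1.0 and s.r2 == 1.0

    def test_independent_equal_frequency_loci_have_zero_d(self):
        s = ld_from_counts(25, 25, 25, 25)
        assert s.d == pytest.approx(0.0, abs=1e-15)

    def test_monomorphic_locus_undefined(self):
        with pytest.raises(NotEstimableError):
            ld_stats([(1, 0), (1, 1), (1, 1)])

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.tuples(*[st.integers(0, 30)] * 4))
    def test_bounds_always_hold(self, counts):
        ab, aB, Ab, bb = counts
        try:
            s = ld_from_counts(ab, aB, Ab, bb)
        except (NotEstimableError, ValueError):
            return
        assert -1.0 <= s.d_prime <= 1.0
        assert 0.0 <= s.r2 <= 1.0
        assert s.r2 <= abs(s.d_prime) + 1e-12


class TestHaplotypeFrequencies:
    def _hap(self, allele, alt=()):
        return Haplotype(allele, {"v1": "alt" if "v1" in alt else "ref",
                                  "v2": "alt" if "v2" in alt else "ref"})

    def test_single_haplotype(self):
        t = haplotype_frequencies([self._hap("6a")] * 8)
        assert len(t) == 1
        assert t.iloc[0]["haplotype"] == "Hap1" and t.iloc[0]["frequency"] == 1.0

    def test_descending_frequency_naming(self):
        haps = [self._hap("6a")] * 6 + [self._hap("3a", ("v1",))] * 4
        t = haplotype_frequencies(haps)
        assert list(t["haplotype"]) == ["Hap1", "Hap2"]
        assert list(t["repeat_allele"]) == ["6a", "3a"]
        assert list(t["frequency"]) == [0.6, 0.4]

    def test_subject_order_invariance(self):
        haps = [self._hap("6a")] * 5 + [self._hap("3a", ("v1",))] * 3 + [self._hap("7a")] * 2
        a = haplotype_frequencies(haps)
        b = haplotype_frequencies(list(reversed(haps)))
        assert a.equals(b)


class TestMeta:
    def test_single_study_passes_through(self):
        assert meta_z([1.7], [300]) == pytest.approx(1.7, abs=1e-12)

    def test_two_identical_studies(self):
        assert meta_z([2.0, 2.0], [100, 100]) == pytest.approx(2 * np.sqrt(2), abs=1e-12)

    def test_equal_size_opposite_effects_cancel(self):
        assert meta_z([2.0, -2.0], [150, 150]) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3, 5, 8])
    def test_k_identical_studies_scale_by_sqrt_k(self, k):
        z = meta_z([2.0] * k, [100] * k)
        assert z == pytest.approx(2.0 * np.sqrt(k), abs=1e-12)

    def test_meta_analysis_of_results_orients_and_weights(self):
        a = _result(-1.0, 0.4, 0.012, 218)
        b = _result(-0.8, 0.5, 0.11, 247)
        m = meta_analysis([a, b])
        assert m.z < 0 and m.p < 0.012
        assert m.direction_concordance == 1.0
        flipped = meta_analysis([a, b], orientations=[-1, -1])
        assert flipped.z == pytest.approx(-m.z, abs=1e-12)

    def test_zero_studies_rejected(self):
        with pytest.raises(ValueError):
            meta_analysis([])

    def test_inverse_variance_scheme(self):
        a = _result(1.0, 0.5, 0.0455, 100)
        b = _result(1.0, 0.5, 0.0455, 100)
        m = meta_analysis([a, b], scheme="inverse_variance")
        assert m.z == pytest.approx(1.0 / 0.5 * np.sqrt(2), rel=1e-6)


def _table(rows):
    # rows: (name, vector, count); columns v0..vk
    k = len(rows[0][1])
    return pd.DataFrame(
        [
            {"haplotype": name, **{f"c{i}": v for i, v in enumerate(vec)}, "count": c,
             "frequency": 0.0}
            for name, vec, c in rows
        ]
    )


class TestNetwork:
    def test_two_haplotypes_one_difference(self):
        t = _table([("Hap1", ("6a", "ref"), 10), ("Hap2", ("6a", "alt"), 5)])
        net = haplotype_network(t)
        assert net.edges == (("Hap1", "Hap2", 1),)

    def test_star_topology_excludes_long_edge(self):
        t = _table(
            [
                ("Hap1", ("6a", "ref", "ref"), 10),  # center
                ("Hap2", ("6a", "alt", "ref"), 4),
                ("Hap3", ("6a", "ref", "alt"), 3),
            ]
        )
        net = haplotype_network(t)
        weights = {frozenset((u, v)): w for u, v, w in net.edges}
        assert weights == {
            frozenset(("Hap1", "Hap2")): 1,
            frozenset(("Hap1", "Hap3")): 1,
        }

    def test_co_minimal_ties_are_all_kept(self):
        t = _table(
            [
                ("Hap1", ("a", "x"), 5),
                ("Hap2", ("b", "x"), 4),
                ("Hap3", ("a", "y"), 3),
                ("Hap4", ("b", "y"), 2),
            ]
        )
        net = haplotype_network(t)
        assert len(net.edges) == 4  # the 4-cycle of distance-1 edges, no diagonals
        assert all(w == 1 for _, _, w in net.edges)

    def test_median_vector_reduces_total_weight(self):
        t = _table(
            [
                ("Hap1", ("a", "x", "p"), 3),
                ("Hap2", ("b", "x", "q"), 3),
                ("Hap3", ("b", "y", "p"), 3),
            ]
        )
        plain = haplotype_network(t, add_medians=False)
        withm = haplotype_network(t, add_medians=True)
        assert withm.medians == (("b", "x", "p"),)
        assert withm.total_weight() < plain.total_weight()

    def test_network_weight_not_beaten_by_random_spanning_trees(self):
        rng = np.random.default_rng(5)
        states = ["a", "b", "c"]
        vectors = {
            f"H{i}": tuple(rng.choice(states, 5)) for i in range(8)
        }
        t = _table([(name, vec, 1) for name, vec in sorted(vectors.items())])
        net = haplotype_network(t)
        # MST weight = MSN weight restricted to one tree per tie class; compare
        # against sampled spanning trees of the complete Hamming graph
        import networkx as nx

        g = nx.Graph()
        for (u, uv), (v, vv) in itertools.combinations(vectors.items(), 2):
            g.add_edge(u, v, weight=sum(a != b for a, b in zip(uv, vv)))
        mst_weight = sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True))
        for _ in range(300):
            assert mst_weight <= random_spanning_tree_weight(vectors, rng)

    def test_duplicate_rows_collapse_upstream(self):
        haps = [Haplotype("6a", {"v": "ref"})] * 4 + [Haplotype("3a", {"v": "alt"})] * 2
        table = haplotype_frequencies(haps)
        assert len(table) == 2 and table["count"].tolist() == [4, 2]


class TestDosage:
    def test_additive_dosage_counts_target_copies(self, locus):
        from msh3rep.genotyper import genotype_reads
        from msh3rep.locus import reference_bank, render_allele_sequence

        from .conftest import make_hap

        bank = reference_bank(locus)
        reads = [bank["3a"]] * 50 + [bank["6a"]] * 50
        call = genotype_reads(reads, locus)
        assert additive_dosage(call, "3a") == 1
        assert additive_dosage(call, "6a") == 1
        assert additive_dosage(call, "8a") == 0
        assert additive_dosage(call, "rs10168") == 0
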