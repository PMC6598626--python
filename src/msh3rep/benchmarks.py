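"""Study-condition computations exercised end to end on synthetic data.

Each function sets up one of the package's standard evaluation scenarios —
the phantom-SNP artefact reproduction, diploid genotype recovery from reads,
regression calibration under the null, recovery of the +1.05-year onset
effect — runs the relevant pipeline stages from scratch, and returns summary
numbers. They are deterministic given the seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import replace

import numpy as np

from .align import SUBSTITUTION_FAVORING
from .association import conditional_fit, fit_marker
from .errors import NoCallError
from .genotyper import artefact_scan, classify_reads, genotype_reads, merge_pairs
from .instability import relative_rate
from .locus import LocusModel, default_locus, reference_bank, render_allele_sequence
from .simulate import (
    SimulationConfig,
    default_haplotype_table,
    simulate_cohort,
    simulate_reads,
)


def _truth_key(pair) -> frozenset:
    return frozenset(Counter(h.key() for h in pair).items())


def genotype_recovery(
    seed: int,
    n_subjects: int = 200,
    coverage: int = 100,
    error_rate: float = 0.005,
    locus: LocusModel | None = None,
) -> dict:
    """Exact diploid repeat + phased-variant recovery rate over simulated subjects.

    Haplotype pairs are drawn from the default frequency table, reads are
    simulated, merged and genotyped; a subject counts as recovered only if the
    called pair of phased haplotypes matches the simulated truth exactly.
    """
    locus = locus or default_locus()
    table = default_haplotype_table(locus)
    haps = [h for h, _ in table]
    probs = np.array([p for _, p in table])
    cfg = SimulationConfig(seed=seed, coverage=coverage, error_rate=error_rate)
    root = np.random.SeedSequence(seed)
    draw_rng = np.random.default_rng(root.spawn(1)[0])
    pair_idx = draw_rng.choice(len(haps), size=(n_subjects, 2), p=probs)
    read_seeds = root.spawn(n_subjects + 1)[1:]
    matched = 0
    no_calls = 0
    for k in range(n_subjects):
        pair = (haps[pair_idx[k, 0]], haps[pair_idx[k, 1]])
        fwd, rev = simulate_reads(
            locus, pair, cfg, rng=np.random.default_rng(read_seeds[k]), subject=f"S{k:04d}"
        )
        merged = [m.sequence for m in merge_pairs(fwd, rev) if m.merged]
        try:
            call = genotype_reads(merged, locus)
        except NoCallError:
            no_calls += 1
            continue
        if call.haplotype_keys() == _truth_key(pair):
            matched += 1
    return {
        "fraction": matched / n_subjects,
        "n": n_subjects,
        "no_calls": no_calls,
        "coverage": coverage,
        "error_rate": error_rate,
    }


def artefact_reproduction(seed: int, n_replicates: int = 50, coverage: int = 30) -> dict:
    """Reproduce the phantom-SNP mechanism over seeded replicates.

    Per replicate: error-free reads from the three-unit allele are merged and
    (a) forced onto the six-unit reference alone under gap-hostile scoring —
    expected to yield at least one apparent substitution inside the repeat;
    (b) classified against the full reference bank — expected to hit the true
    allele for every full-span read, after which the artefact scan against the
    true allele reports nothing.
    """
    locus = default_locus()
    bank = reference_bank(locus)
    hap3a = locus.all_ref_haplotype("3a")
    cfg = SimulationConfig(seed=seed, coverage=coverage, error_rate=0.0)
    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    n_artefact = n_resolved = 0
    reads_total = reads_3a = 0
    for ss in seeds:
        fwd, rev = simulate_reads(
            locus, (hap3a, hap3a), cfg, rng=np.random.default_rng(ss)
        )
        merged = [m.sequence for m in merge_pairs(fwd, rev) if m.merged]
        found = artefact_scan(merged, locus, "6a", scoring=SUBSTITUTION_FAVORING, min_frac=0.5)
        if any(v.classification == "substitution" and v.in_repeat for v in found):
            n_artefact += 1
        cls = classify_reads(merged, bank)
        reads_total += len(cls)
        reads_3a += sum(1 for c in cls if not c.ambiguous and c.best_allele == "3a")
        if not artefact_scan(merged, locus, "3a", min_frac=0.5):
            n_resolved += 1
    return {
        "replicates": n_replicates,
        "fraction_with_in_repeat_substitution": n_artefact / n_replicates,
        "fraction_reads_classified_3a": reads_3a / reads_total,
        "fraction_resolved_with_bank": n_resolved / n_replicates,
    }


def null_type1_rate(seed: int, n_cohorts: int = 1000, n: int = 200) -> dict:
    """Fraction of null cohorts where the 3a-onset test gives p < 0.05."""
    base = SimulationConfig(seed=0, cohort_size=n, disease="HD")
    null_effects = base.effects.null()
    hits = 0
    tested = 0
    for k in range(n_cohorts):
        cfg = replace(base, seed=seed * 100_003 + k, effects=null_effects)
        df = simulate_cohort(default_locus(), cfg, include_expansion=False)
        r = fit_marker(df, "3a", "onset", "HD")
        if r.estimable:
            tested += 1
            hits += r.p < 0.05
    return {"rate": hits / tested, "n_cohorts": tested, "n_per_cohort": n}


def onset_beta_recovery(seed: int, n: int = 2000) -> dict:
    """Recover the simulated +1.05-year-per-3a-copy onset effect by OLS."""
    cfg = SimulationConfig(seed=seed, cohort_size=n, disease="HD")
    df = simulate_cohort(default_locus(), cfg, include_expansion=False)
    r = fit_marker(df, "3a", "onset", "HD")
    return {
        "beta": r.beta,
        "se": r.se,
        "p": r.p,
        "n": n,
        "true_beta": cfg.effects.onset_per_3a,
    }


def conditional_ld_flag_rate(seed: int, n_runs: int = 20, n: int = 500) -> dict:
    """How often a SNP in complete LD with 3a is flagged non-estimable."""
    flagged = 0
    for k in range(n_runs):
        cfg = SimulationConfig(seed=seed * 7919 + k, cohort_size=n, disease="HD")
        df = simulate_cohort(default_locus(), cfg, include_expansion=False)
        r = conditional_fit(
            df["onset"], df["dos_rs151182735"], df[["dos_3a"]], df[["inherited_length"]],
            marker="rs151182735", phenotype_name="onset",
        )
        flagged += int(not r.estimable)
    return {"fraction_flagged": flagged / n_runs, "n_runs": n_runs}


def relative_rate_noise_recovery(seed: int, n: int = 500) -> dict:
    """Residualisation sanity: residuals recover injected noise, orthogonally.

    index = 1 + 0.02*age + 0.05*length + eps; the relative-rate residuals
    should correlate with eps near 1 and be numerically orthogonal to the
    covariates.
    """
    rng = np.random.default_rng(seed)
    age = rng.uniform(30, 70, n)
    length = rng.uniform(40, 55, n)
    eps = rng.normal(0, 0.3, n)
    index = 1.0 + 0.02 * age + 0.05 * length + eps
    resid = relative_rate(index, age, length)
    corr = float(np.corrcoef(resid, eps)[0, 1])

    def northo(x):
        return float(abs(resid @ (x - x.mean())) / (np.linalg.norm(resid) * np.linalg.norm(x - x.mean())))

    return {
        "corr_resid_noise": corr,
        "orthogonality_age": northo(age),
        "orthogonality_length": northo(length),
        "n": n,
    }
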