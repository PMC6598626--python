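"""Synthetic data with the statistical structure the analysis assumes.

Generates every input the pipeline consumes: MiSeq-like paired amplicon reads
(400 nt forward / 200 nt reverse, substitution errors only), expansion-biased
age- and length-dependent repeat-size distributions, and cohort tables with
diploid haplotypes drawn in Hardy-Weinberg proportions from a haplotype
frequency table that places three 5' SNPs in complete LD with the three-unit
repeat allele — mirroring the observed structure of the locus. Phenotypes are
linear additive in allele dosage with Gaussian noise; the three-unit allele is
protective by default (delays onset, slows expansion and progression).

All generators are pure functions of (config, seed): identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .instability import (
    RepeatSizeDistribution,
    expansion_index_dm1,
    expansion_index_hd,
)
from .locus import Haplotype, LocusModel, render_allele_sequence

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: The three 5'-of-repeat variants generated in complete LD with the 3a allele.
COMPLETE_LD_VARIANTS = ("rs151182735", "rs10168", "rs2250063")


@dataclass(frozen=True)
class EffectSizes:
    """Additive effects per copy of the three-unit (3a) repeat allele.

    Units: years for onset, phenotype units for progression, expansions/year
    scale for the instability rate, rpkm-like units for expression. The onset
    default is the +1.05-year delay used as the simulation scenario.
    """

    onset_per_3a: float = 1.05
    progression_per_3a: float = -0.52
    expansion_rate_per_3a: float = -0.02
    msh3_expr_per_3a: float = -0.5
    dhfr_expr_per_3a: float = -0.8
    msh3_expr_per_long: float = 0.4  # per copy of a 7- or 8-unit allele
    onset_per_interruption: float = 8.0
    expansion_rate_per_interruption: float = -0.03

    def null(self) -> "EffectSizes":
        return EffectSizes(0, 0, 0, 0, 0, 0, 0, 0)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    # read simulation
    coverage: int = 100
    read_len_fwd: int = 400
    read_len_rev: int = 200
    error_rate: float = 0.005
    qual_plateau: float = 38.0
    qual_floor_fwd: float = 28.0
    qual_floor_rev: float = 30.0
    qual_sd: float = 3.0
    qual_plateau_frac: float = 0.75
    # cohort
    cohort_size: int = 200
    disease: str = "HD"
    effects: EffectSizes = field(default_factory=EffectSizes)
    onset_sd: float = 5.0
    progression_sd: float = 0.5
    expr_sd: float = 1.0
    interruption_prevalence: float = 0.08  # DM1 only
    inbreeding: float = 0.0
    # instability process
    expansion_rate_base: float = 0.05  # expansions/year scale at progenitor length 100
    progenitor_scale: float = 0.01  # f(L) = progenitor_scale * L, increasing in L
    instability_reads: int = 300
    # optional custom haplotype structure
    haplotype_freqs: tuple | None = None  # ((Haplotype, freq), ...)
    ld_targets: tuple | None = None  # ((variant_id, r2 vs 3a), ...)

    def __post_init__(self):
        if not (0.0 <= self.error_rate < 0.5):
            raise ConfigError(f"error rate {self.error_rate} outside [0, 0.5)")
        if self.coverage < 1:
            raise ConfigError("coverage must be >= 1")
        if self.disease not in ("HD", "DM1"):
            raise ConfigError(f"unknown disease {self.disease!r}")
        if self.haplotype_freqs is not None:
            total = sum(f for _, f in self.haplotype_freqs)
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"haplotype frequencies sum to {total}, not 1")
        if self.ld_targets is not None:
            for vid, r2 in self.ld_targets:
                if not (0.0 <= r2 <= 1.0):
                    raise ConfigError(f"r2 target for {vid} outside [0, 1]")


# -- haplotype structure ---------------------------------------------------


def default_haplotype_table(locus: LocusModel) -> tuple[tuple[Haplotype, float], ...]:
    """Twelve haplotypes echoing the observed locus structure.

    The six-unit reference allele is the most common and the three-unit allele
    second; the three 5' SNPs are alt on all and only 3a haplotypes (complete
    LD by construction); the 3a background splits into two haplotypes that
    differ only at rs1677658, as the observed Hap1/Hap2 pair does.
    """
    vids = [v.id for v in locus.variants]

    def hap(allele: str, alts: Sequence[str] = ()) -> Haplotype:
        return Haplotype(allele, {vid: ("alt" if vid in alts else "ref") for vid in vids})

    three = list(COMPLETE_LD_VARIANTS)
    return (
        (hap("3a", three), 0.06),
        (hap("3a", three + ["rs1677658"]), 0.09),
        (hap("6a"), 0.40),
        (hap("6a", ["rs1105524"]), 0.08),
        (hap("6a", ["rs1650697"]), 0.06),
        (hap("7a"), 0.12),
        (hap("7a", ["msh3_1bp_del"]), 0.04),
        (hap("8a"), 0.09),
        (hap("8b", ["rs1650697"]), 0.03),
        (hap("4a"), 0.01),
        (hap("5a"), 0.01),
        (hap("9a"), 0.01),
    )


def build_haplotype_table(
    locus: LocusModel,
    allele_freqs: Mapping[str, float],
    variant_alt_freqs: Mapping[str, float],
    ld_targets: Mapping[str, float],
    target_allele: str = "3a",
) -> tuple[tuple[Haplotype, float], ...]:
    """Construct a haplotype table hitting allele/variant frequencies and r2 targets.

    Variants are conditionally independent given carrier status of the target
    repeat allele; each requested r2 (vs the target allele) is converted to a
    positive D and checked against the attainable Dmax, raising a ConfigError
    that names the bound when the target is infeasible for the given margins.
    """
    if abs(sum(allele_freqs.values()) - 1.0) > 1e-9:
        raise ConfigError("allele frequencies must sum to 1")
    p_a = allele_freqs.get(target_allele, 0.0)
    if not (0.0 < p_a < 1.0):
        raise ConfigError(f"target allele {target_allele!r} needs frequency in (0,1)")
    cond: dict[str, tuple[float, float]] = {}
    for v in locus.variants:
        p_b = variant_alt_freqs.get(v.id, 0.0)
        r2 = ld_targets.get(v.id, 0.0)
        if r2 > 0 and not (0.0 < p_b < 1.0):
            raise ConfigError(f"variant {v.id}: r2 target needs alt frequency in (0,1)")
        d = np.sqrt(r2 * p_a * (1 - p_a) * p_b * (1 - p_b))
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
        if d > d_max + 1e-12:
            raise ConfigError(
                f"variant {v.id}: requested r2={r2} needs D={d:.4g} > D'max bound {d_max:.4g} "
                f"for frequencies p({target_allele})={p_a}, p(alt)={p_b}"
            )
        p_alt_given_a = p_b + d * (1 - p_a) / (p_a * (1 - p_a)) * p_a if p_a else p_b
        # simplifies to p_b + d / p_a; keep the direct form
        p_alt_given_a = min(1.0, p_b + d / p_a)
        p_alt_given_not = max(0.0, p_b - d / (1 - p_a))
        cond[v.id] = (p_alt_given_a, p_alt_given_not)
    table: list[tuple[Haplotype, float]] = []
    vids = [v.id for v in locus.variants]
    for allele, freq in allele_freqs.items():
        if freq <= 0:
            continue
        combos: list[tuple[dict[str, str], float]] = [({}, freq)]
        is_target = allele == target_allele
        for vid in vids:
            p_alt = cond[vid][0 if is_target else 1]
            nxt = []
            for assign, p in combos:
                if p_alt > 0:
                    nxt.append(({**assign, vid: "alt"}, p * p_alt))
                if p_alt < 1:
                    nxt.append(({**assign, vid: "ref"}, p * (1 - p_alt)))
            combos = nxt
        for assign, p in combos:
            if p > 1e-12:
                table.append((Haplotype(allele, assign), p))
    total = sum(p for _, p in table)
    return tuple((h, p / total) for h, p in table)


def haplotype_table(locus: LocusModel, config: SimulationConfig):
    if config.haplotype_freqs is not None:
        return config.haplotype_freqs
    return default_haplotype_table(locus)


# -- read simulation -------------------------------------------------------


def _quality_profile(length: int, plateau: float, floor: float, frac: float) -> np.ndarray:
    knee = int(length * frac)
    means = np.full(length, plateau)
    if knee < length:
        means[knee:] = np.linspace(plateau, floor, length - knee)
    return means


def _apply_errors(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return seq
    hits = rng.random(seq.shape[0]) < rate
    n = int(hits.sum())
    if n:
        seq = seq.copy()
        # replace with one of the three other bases, uniformly
        cur = seq[hits]
        shift = rng.integers(1, 4, size=n)
        idx = (np.searchsorted(_BASES, cur) + shift) % 4
        seq[hits] = _BASES[idx]
    return seq


def simulate_reads(
    locus: LocusModel,
    genotype: tuple[Haplotype, Haplotype],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    subject: str = "S",
) -> tuple[list[tuple[str, str, tuple[int, ...]]], list[tuple[str, str, tuple[int, ...]]]]:
    """Simulate paired amplicon reads for one diploid subject.

    Each of ~``coverage`` pairs draws a haplotype by fair coin, takes the
    forward read from the amplicon start and the reverse read (reverse-
    complemented) from the amplicon end, applies i.i.d. substitution errors at
    the configured rate, and assigns Phred+33 qualities from a two-piece
    (plateau then 3' decay) model. Returns (forward, reverse) lists of
    (name, sequence, qualities).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    amps = [
        np.frombuffer(render_allele_sequence(locus, h).encode(), dtype=np.uint8)
        for h in genotype
    ]
    for a in amps:
        if len(a) < max(config.read_len_fwd, config.read_len_rev):
            raise ConfigError(
                f"amplicon length {len(a)} shorter than read length "
                f"{max(config.read_len_fwd, config.read_len_rev)}"
            )
    prof_f = _quality_profile(
        config.read_len_fwd, config.qual_plateau, config.qual_floor_fwd, config.qual_plateau_frac
    )
    prof_r = _quality_profile(
        config.read_len_rev, config.qual_plateau, config.qual_floor_rev, config.qual_plateau_frac
    )
    comp = np.zeros(256, dtype=np.uint8)
    for x, y in zip(b"ACGT", b"TGCA"):
        comp[x] = y
    fwd, rev = [], []
    for i in range(config.coverage):
        amp = amps[int(rng.integers(2))]
        f = _apply_errors(amp[: config.read_len_fwd], config.error_rate, rng)
        r_src = _apply_errors(amp[len(amp) - config.read_len_rev :], config.error_rate, rng)
        r = comp[r_src][::-1]
        qf = np.clip(np.rint(rng.normal(prof_f, config.qual_sd)), 2, 40).astype(int)
        qr = np.clip(np.rint(rng.normal(prof_r, config.qual_sd)), 2, 40).astype(int)
        name = f"{subject}_read{i:05d}"
        fwd.append((name + "/1", f.tobytes().decode(), tuple(qf)))
        rev.append((name + "/2", r.tobytes().decode(), tuple(qr)))
    return fwd, rev


def write_fastq(path: str | Path, reads: Sequence[tuple[str, str, Sequence[int]]]) -> None:
    """Phred+33 FASTQ writer (format forbids comment lines, so no header)."""
    with open(path, "w") as fh:
        for name, seq, quals in reads:
            fh.write(f"@{name}\n{seq}\n+\n{''.join(chr(q + 33) for q in quals)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, tuple[int, ...]]]:
    from Bio import SeqIO

    from .errors import QCError

    out = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            out.append(
                (rec.id, str(rec.seq), tuple(rec.letter_annotations["phred_quality"]))
            )
    except ValueError as e:
        raise QCError(f"{path}: malformed FASTQ near record {len(out)}: {e}") from e
    return out


# -- instability process ---------------------------------------------------


def simulate_repeat_distribution(
    progenitor: int,
    age: float,
    rate: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    subject: str = "",
) -> RepeatSizeDistribution:
    """Expansion-biased repeat-size distribution for one subject.

    Per-read gain ~ Poisson(rate * age * f(progenitor)) with f increasing in
    the progenitor length, so expected expansion grows with age, rate and
    inherited length. Gains are non-negative: the process is expansion-biased
    by construction.
    """
    if rate < 0:
        raise ConfigError("expansion rate must be >= 0")
    if progenitor <= 0:
        raise ConfigError("progenitor length must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mean = rate * age * config.progenitor_scale * progenitor
    gains = rng.poisson(mean, size=config.instability_reads)
    lengths, counts = np.unique(progenitor + gains, return_counts=True)
    return RepeatSizeDistribution(dict(zip(lengths, counts)), progenitor, subject=subject)


# -- cohort simulation -----------------------------------------------------


def _dosage_columns(locus, haps1, haps2):
    alleles = sorted({h.repeat_allele for h in haps1} | {h.repeat_allele for h in haps2})
    cols = {}
    for a in alleles:
        cols[f"dos_{a}"] = [
            (h1.repeat_allele == a) + (h2.repeat_allele == a) for h1, h2 in zip(haps1, haps2)
        ]
    for v in locus.variants:
        cols[f"dos_{v.id}"] = [
            (h1.variant_alleles[v.id] == "alt") + (h2.variant_alleles[v.id] == "alt")
            for h1, h2 in zip(haps1, haps2)
        ]
    return cols


def simulate_cohort(
    locus: LocusModel,
    config: SimulationConfig,
    include_expansion: bool = True,
    return_distributions: bool = False,
):
    """Simulate a disease cohort table (and optionally the raw distributions).

    Haplotype pairs are drawn i.i.d. from the frequency table (Hardy-Weinberg
    under the default zero inbreeding). Phenotypes are additive in the 3a
    dosage plus covariates plus Gaussian noise. The expansion index is never
    injected directly: a repeat-size distribution is simulated per subject and
    scored by the instability module.
    """
    rng = np.random.default_rng(config.seed)
    table = haplotype_table(locus, config)
    haps = [h for h, _ in table]
    probs = np.array([p for _, p in table])
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ConfigError("haplotype frequencies must sum to 1")
    n = config.cohort_size
    i1 = rng.choice(len(haps), size=n, p=probs)
    i2 = rng.choice(len(haps), size=n, p=probs)
    if config.inbreeding > 0:
        same = rng.random(n) < config.inbreeding
        i2[same] = i1[same]
    haps1 = [haps[i] for i in i1]
    haps2 = [haps[i] for i in i2]
    dos = _dosage_columns(locus, haps1, haps2)
    dos3a = np.array(dos.get("dos_3a", [0] * n), dtype=float)
    eff = config.effects

    if config.disease == "HD":
        age = np.round(rng.uniform(30, 70, n), 1)
        inherited = np.clip(np.rint(rng.normal(44, 3, n)), 40, 55).astype(int)
        interrupted = np.zeros(n, dtype=int)
        onset = (
            70.0
            - 0.8 * (inherited - 40)
            + eff.onset_per_3a * dos3a
            + rng.normal(0, config.onset_sd, n)
        )
        progression = (
            1.0
            + 0.05 * (inherited - 44)
            + eff.progression_per_3a * dos3a
            + rng.normal(0, config.progression_sd, n)
        )
    else:  # DM1
        age = np.round(rng.uniform(20, 60, n), 1)
        inherited = np.clip(np.rint(rng.normal(300, 80, n)), 80, 600).astype(int)
        interrupted = (rng.random(n) < config.interruption_prevalence).astype(int)
        onset = (
            45.0
            - 0.05 * (inherited - 300)
            + eff.onset_per_interruption * interrupted
            + eff.onset_per_3a * dos3a
            + rng.normal(0, config.onset_sd, n)
        )
        progression = np.full(n, np.nan)

    dos_long = np.array(dos.get("dos_7a", [0] * n)) + np.array(dos.get("dos_8a", [0] * n))
    msh3 = (
        10.0
        + eff.msh3_expr_per_3a * dos3a
        + eff.msh3_expr_per_long * dos_long
        + rng.normal(0, config.expr_sd, n)
    )
    dhfr = 8.0 + eff.dhfr_expr_per_3a * dos3a + rng.normal(0, config.expr_sd, n)

    subjects = [f"{config.disease}{k:04d}" for k in range(n)]
    expansion = np.full(n, np.nan)
    dists: dict[str, RepeatSizeDistribution] = {}
    if include_expansion:
        rates = np.maximum(
            config.expansion_rate_base
            + eff.expansion_rate_per_3a * dos3a
            + eff.expansion_rate_per_interruption * interrupted,
            0.0,
        )
        for k in range(n):
            d = simulate_repeat_distribution(
                int(inherited[k]), float(age[k]), float(rates[k]), config, rng, subjects[k]
            )
            dists[subjects[k]] = d
            idx = expansion_index_hd(d) if config.disease == "HD" else expansion_index_dm1(d)
            expansion[k] = idx.value

    df = pd.DataFrame(
        {
            "subject": subjects,
            "disease": config.disease,
            "hap1": [h.key().__repr__() for h in haps1],
            "hap2": [h.key().__repr__() for h in haps2],
            "repeat_genotype": [
                "/".join(sorted((h1.repeat_allele, h2.repeat_allele)))
                for h1, h2 in zip(haps1, haps2)
            ],
            **dos,
            "age": age,
            "inherited_length": inherited,
            "interrupted": interrupted,
            "onset": np.round(onset, 3),
            "progression": np.round(progression, 4),
            "expansion_index": np.round(expansion, 5),
            "msh3_rpkm": np.round(msh3, 4),
            "dhfr_rpkm": np.round(dhfr, 4),
        }
    )
    df.attrs["haplotypes"] = list(zip(haps1, haps2))
    if return_distributions:
        return df, dists
    return df


def write_cohort_tsv(path: str | Path, df: pd.DataFrame, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)
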