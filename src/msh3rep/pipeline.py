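"""End-to-end pipeline: simulate -> QC -> genotype -> instability -> associate
-> meta -> network, with a config snapshot, a log and deterministic outputs.

Every run directory contains the serialized configuration, a version stamp and
a log with the seed, config hash and per-stage record counts; re-running with
the same configuration and seed reproduces every table byte for byte. Stages
are resumable: a completed stage (marked done under the same config hash) is
skipped on re-entry, and a failing stage halts the run with a stage-named
error while partial outputs are retained.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .align import DEFAULT_SCORING, SUBSTITUTION_FAVORING
from .association import (
    bonferroni,
    fit_marker,
    haplotype_frequencies,
    haplotype_network,
    hwe_test,
    ld_stats,
    meta_analysis,
    write_network,
)
from .errors import ConfigError, NoCallError, QCError, StageError
from .genotyper import artefact_scan, genotype_reads, merge_pairs, write_sam, write_variant_tsv
from .instability import relative_rate, write_indices_tsv
from .locus import (
    default_locus,
    export_reference_bank,
    read_locus_json,
    render_allele_sequence,
    write_locus_json,
)
from .simulate import (
    SimulationConfig,
    read_fastq,
    simulate_cohort,
    simulate_reads,
    write_cohort_tsv,
    write_fastq,
)

COMMON_MARKERS = ("3a", "6a", "7a", "8a")


@dataclass(frozen=True)
class QCReport:
    per_file: dict
    pooled_fraction: float
    q_threshold: int
    pass_frac: float

    @property
    def passed(self) -> bool:
        return self.pooled_fraction > self.pass_frac


def fastq_qc(paths, q_threshold: int = 30, pass_frac: float = 0.8) -> QCReport:
    """Fraction of bases at or above the Phred threshold, per file and pooled.

    The run passes if the pooled fraction exceeds ``pass_frac`` (the >80% of
    bases above Q30 acceptance rule for this assay).
    """
    per_file = {}
    pooled_hi = pooled_n = 0
    for path in paths:
        reads = read_fastq(path)
        if not reads:
            raise QCError(f"{path}: empty FASTQ file")
        hi = n = 0
        for _, _, quals in reads:
            q = np.asarray(quals)
            hi += int(np.count_nonzero(q >= q_threshold))
            n += q.size
        per_file[str(path)] = hi / n
        pooled_hi += hi
        pooled_n += n
    return QCReport(per_file, pooled_hi / pooled_n, q_threshold, pass_frac)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/demo"
    n_subjects: int = 200
    coverage: int = 50
    error_rate: float = 0.005
    locus_path: str | None = None
    min_depth: int = 30
    min_hap_frac: float = 0.2
    q_threshold: int = 30
    pass_frac: float = 0.8
    artefact_reads: int = 30

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output path excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:16]


def _stage_done(run_dir: Path, stage: str, cfg_hash: str) -> bool:
    marker = run_dir / f".{stage}.done"
    return marker.exists() and marker.read_text().strip() == cfg_hash


def _mark_done(run_dir: Path, stage: str, cfg_hash: str) -> None:
    (run_dir / f".{stage}.done").write_text(cfg_hash + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage into ``config.out_dir`` and return the run directory."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    (run_dir / "config.yaml").write_text(config.to_yaml())
    (run_dir / "VERSION").write_text(f"msh3rep {__version__}\n")
    log: list[str] = [f"seed={config.seed}", f"config_hash={cfg_hash}"]

    def log_write():
        (run_dir / "log.txt").write_text("\n".join(log) + "\n")

    try:
        result = _run_stages(config, run_dir, cfg_hash, log)
    except Exception as e:
        log.append(f"FAILED: {e}")
        log_write()
        raise
    log_write()
    return result


def _run_stages(config: RunConfig, run_dir: Path, cfg_hash: str, log: list[str]) -> Path:
    prov = f"seed={config.seed} config={cfg_hash} msh3rep={__version__}"

    # -- locus ------------------------------------------------------------
    if config.locus_path is not None:
        locus_path = Path(config.locus_path)
        if not locus_path.exists():
            raise ConfigError(f"locus file not found: {locus_path}")
        locus = read_locus_json(locus_path)
    else:
        locus = default_locus()
    if not _stage_done(run_dir, "locus", cfg_hash):
        (run_dir / "locus").mkdir(exist_ok=True)
        write_locus_json(locus, run_dir / "locus" / "locus.json")
        export_reference_bank(locus, run_dir / "locus" / "bank.fasta")
        _mark_done(run_dir, "locus", cfg_hash)
    log.append(f"locus: {len(locus.catalogue)} alleles, {len(locus.variants)} variants")

    sim = SimulationConfig(
        seed=config.seed,
        coverage=config.coverage,
        error_rate=config.error_rate,
        cohort_size=config.n_subjects,
    )

    # -- simulate ---------------------------------------------------------
    stage = "simulate"
    cohorts: dict[str, pd.DataFrame] = {}
    dists = {}
    try:
        for disease, sub_seed in (("HD", 1), ("DM1", 2)):
            dcfg = dataclasses.replace(sim, disease=disease, seed=config.seed * 1000 + sub_seed)
            cohorts[disease], dists[disease] = simulate_cohort(
                locus, dcfg, return_distributions=True
            )
        (run_dir / "cohorts").mkdir(exist_ok=True)
        for disease, df in cohorts.items():
            write_cohort_tsv(run_dir / "cohorts" / f"{disease}.tsv", df, comment=prov)
            _write_distributions(run_dir / "cohorts", disease, dists[disease], prov)
        reads_dir = run_dir / "reads"
        if not _stage_done(run_dir, stage, cfg_hash):
            reads_dir.mkdir(exist_ok=True)
            hd = cohorts["HD"]
            seeds = np.random.SeedSequence(config.seed * 1000 + 3).spawn(len(hd))
            for (idx, row), ss in zip(hd.iterrows(), seeds):
                hap1, hap2 = hd.attrs["haplotypes"][idx]
                fwd, rev = simulate_reads(
                    locus, (hap1, hap2), sim, rng=np.random.default_rng(ss),
                    subject=row["subject"],
                )
                write_fastq(reads_dir / f"{row['subject']}_R1.fastq", fwd)
                write_fastq(reads_dir / f"{row['subject']}_R2.fastq", rev)
            _mark_done(run_dir, stage, cfg_hash)
        log.append(
            "simulate: "
            + ", ".join(f"{d}={len(df)} subjects" for d, df in cohorts.items())
            + f", reads for {len(cohorts['HD'])} HD subjects at {config.coverage}x"
        )
    except (ConfigError, StageError):
        raise
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # -- qc ---------------------------------------------------------------
    stage = "qc"
    try:
        fastqs = sorted((run_dir / "reads").glob("*_R1.fastq"))[:20]
        report = fastq_qc(fastqs, config.q_threshold, config.pass_frac)
        lines = [f"# {prov}", "file\tfraction_ge_q30"]
        for f, frac in sorted(report.per_file.items()):
            lines.append(f"{Path(f).name}\t{frac:.5f}")
        lines.append(f"POOLED\t{report.pooled_fraction:.5f}")
        lines.append(f"PASS\t{report.passed}")
        (run_dir / "qc.tsv").write_text("\n".join(lines) + "\n")
        log.append(f"qc: pooled {report.pooled_fraction:.4f} pass={report.passed}")
    except QCError:
        raise
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # -- genotype ---------------------------------------------------------
    stage = "genotype"
    try:
        hd = cohorts["HD"]
        if _stage_done(run_dir, stage, cfg_hash) and (run_dir / "genotype_calls.json").exists():
            calls = read_calls_json(run_dir / "genotype_calls.json")
            log.append(f"genotype: {len(calls)} calls (resumed)")
        else:
            calls = {}
            no_calls = []
            sam_dir = run_dir / "sam"
            sam_dir.mkdir(exist_ok=True)
            for _, row in hd.iterrows():
                subject = row["subject"]
                fwd = read_fastq(run_dir / "reads" / f"{subject}_R1.fastq")
                rev = read_fastq(run_dir / "reads" / f"{subject}_R2.fastq")
                merged = [m for m in merge_pairs(fwd, rev) if m.merged]
                try:
                    calls[subject] = genotype_reads(
                        [m.sequence for m in merged],
                        locus,
                        min_depth=config.min_depth,
                        min_hap_frac=config.min_hap_frac,
                    )
                except NoCallError:
                    no_calls.append(subject)
            _write_calls_json(run_dir / "genotype_calls.json", calls, prov)
            write_variant_tsv(run_dir / "variants.tsv", calls, locus)
            # one confirmatory SAM for the first genotyped subject
            first = sorted(calls)[0]
            fwd = read_fastq(run_dir / "reads" / f"{first}_R1.fastq")
            rev = read_fastq(run_dir / "reads" / f"{first}_R2.fastq")
            merged = [m for m in merge_pairs(fwd, rev) if m.merged]
            from .align import align_to_reference
            from .genotyper import DEFAULT_BAND, classify_reads
            from .locus import reference_bank

            bank = reference_bank(locus)
            cls = classify_reads([m.sequence for m in merged], bank)
            recs = []
            for m, c in zip(merged, cls):
                if c.ambiguous:
                    recs.append((m, None))
                else:
                    recs.append(
                        (m, align_to_reference(m.sequence, bank[c.best_allele],
                                               reference_id=c.best_allele, band=DEFAULT_BAND))
                    )
            write_sam(sam_dir / f"{first}.sam", recs, locus, comment=prov)
            _mark_done(run_dir, stage, cfg_hash)
            log.append(f"genotype: {len(calls)} calls, {len(no_calls)} no-calls")
    except StageError:
        raise
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # -- artefact ---------------------------------------------------------
    stage = "artefact"
    try:
        hap3a = locus.all_ref_haplotype("3a")
        amp = render_allele_sequence(locus, hap3a)
        reads = [amp] * config.artefact_reads  # error-free full-span merged reads
        rows = ["# " + prov, "scoring\tposition\tref\talt\tclass\tfraction\tin_repeat"]
        for label, scoring in (("substitution_favoring", SUBSTITUTION_FAVORING),
                               ("default", DEFAULT_SCORING)):
            for v in artefact_scan(reads, locus, "6a", scoring=scoring, min_frac=0.5):
                rows.append(
                    f"{label}\t{v.position}\t{v.ref or '-'}\t{v.alt or '-'}\t"
                    f"{v.classification}\t{v.fraction:.3f}\t{int(v.in_repeat)}"
                )
        resolved = artefact_scan(reads, locus, "3a", min_frac=0.5)
        rows.append(f"bank_resolved\t-\t-\t-\tnone\t{0.0:.3f}\t0" if not resolved else "ERROR")
        (run_dir / "artefact_report.tsv").write_text("\n".join(rows) + "\n")
        log.append(f"artefact: {len(rows) - 2} apparent variant rows")
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # -- instability ------------------------------------------------------
    stage = "instability"
    try:
        for disease, df in cohorts.items():
            resid = relative_rate(df["expansion_index"], df["age"], df["inherited_length"])
            df["relative_rate"] = np.round(resid, 6)
            measure = "HD_ratio" if disease == "HD" else "DM1_modal_shift"
            lines = [f"# {prov}", "subject\tmeasure\tindex\trelative_rate"]
            for s, i, r in zip(df["subject"], df["expansion_index"], df["relative_rate"]):
                lines.append(f"{s}\t{measure}\t{i:.6g}\t{r:.6g}")
            (run_dir / f"instability_{disease}.tsv").write_text("\n".join(lines) + "\n")
        log.append("instability: relative rates residualised on age + inherited length")
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # -- associate --------------------------------------------------------
    stage = "associate"
    try:
        # HD association uses the genotyper's calls, closing the loop from reads
        hd = cohorts["HD"]
        called = hd["subject"].map(calls.__contains__)
        for marker in list(COMMON_MARKERS) + [v.id for v in locus.variants]:
            col = f"dos_{marker}"
            if col not in hd.columns:
                hd[col] = 0
            hd[col] = hd[col].astype(float)
            hd.loc[called, col] = [
                float(
                    sum(1 for h in calls[s].haplotypes if h.repeat_allele == marker)
                    if marker in {a.name for a in locus.catalogue}
                    else calls[s].variant_genotypes[marker]
                )
                for s in hd.loc[called, "subject"]
            ]
        phenos = {
            "HD": ("onset", "progression", "relative_rate", "msh3_rpkm", "dhfr_rpkm"),
            "DM1": ("onset", "relative_rate"),
        }
        markers = list(COMMON_MARKERS) + [v.id for v in locus.variants]
        rows = [
            "# " + prov,
            "disease\tmarker\tphenotype\tbeta\tse\tt\tp\tp_bonferroni\tn\testimable\tnote",
        ]
        results = {}
        for disease, df in cohorts.items():
            for marker in markers:
                if f"dos_{marker}" not in df.columns:
                    df[f"dos_{marker}"] = 0
                for pheno in phenos[disease]:
                    r = fit_marker(df, marker, pheno, disease)
                    results[(disease, marker, pheno)] = r
                    pb = bonferroni(r.p, len(phenos[disease])) if r.estimable else np.nan
                    rows.append(
                        f"{disease}\t{marker}\t{pheno}\t{r.beta:.6g}\t{r.se:.6g}\t{r.t:.6g}\t"
                        f"{r.p:.6g}\t{pb:.6g}\t{r.n}\t{int(r.estimable)}\t{r.note}"
                    )
        (run_dir / "association.tsv").write_text("\n".join(rows) + "\n")

        hwe_rows = ["# " + prov, "disease\tvariant\thom_ref\thet\thom_alt\tmethod\tp"]
        ld_rows = ["# " + prov, "disease\tlocus_a\tlocus_b\tD\tD_prime\tr2"]
        for disease, df in cohorts.items():
            pairs_src = df.attrs["haplotypes"]
            for v in locus.variants:
                dosv = df[f"dos_{v.id}"].astype(int)
                counts = ((dosv == 0).sum(), (dosv == 1).sum(), (dosv == 2).sum())
                h = hwe_test(counts, "exact")
                hwe_rows.append(
                    f"{disease}\t{v.id}\t{counts[0]}\t{counts[1]}\t{counts[2]}\texact\t{h.p:.6g}"
                )
            loci = ["3a"] + [v.id for v in locus.variants]
            chroms = [h for pair in pairs_src for h in pair]

            def coded(name):
                if name == "3a":
                    return [int(h.repeat_allele == "3a") for h in chroms]
                return [int(h.variant_alleles[name] == "alt") for h in chroms]

            for a, b in [(a, b) for i, a in enumerate(loci) for b in loci[i + 1 :]]:
                try:
                    s = ld_stats(list(zip(coded(a), coded(b))))
                    ld_rows.append(
                        f"{disease}\t{a}\t{b}\t{s.d:.6g}\t{s.d_prime:.6g}\t{s.r2:.6g}"
                    )
                except Exception:
                    ld_rows.append(f"{disease}\t{a}\t{b}\tNA\tNA\tNA")
        (run_dir / "hwe.tsv").write_text("\n".join(hwe_rows) + "\n")
        (run_dir / "ld.tsv").write_text("\n".join(ld_rows) + "\n")
        log.append(f"associate: {len(rows) - 2} marker-phenotype fits")
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # -- meta -------------------------------------------------------------
    stage = "meta"
    try:
        meta_rows = ["# " + prov, "marker\tphenotype\tz\tp\tconcordance"]
        for marker in ("3a",):
            for pheno in ("onset", "relative_rate"):
                rs = [results[("HD", marker, pheno)], results[("DM1", marker, pheno)]]
                if all(r.estimable for r in rs):
                    m = meta_analysis(rs)
                    meta_rows.append(
                        f"{marker}\t{pheno}\t{m.z:.6g}\t{m.p:.6g}\t{m.direction_concordance:.3g}"
                    )
        (run_dir / "meta.tsv").write_text("\n".join(meta_rows) + "\n")
        log.append(f"meta: {len(meta_rows) - 2} combined tests")
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # -- network ----------------------------------------------------------
    stage = "network"
    try:
        chroms = [
            h
            for disease in ("HD", "DM1")
            for pair in cohorts[disease].attrs["haplotypes"]
            for h in pair
        ]
        table = haplotype_frequencies(chroms)
        with open(run_dir / "haplotypes.tsv", "w") as fh:
            fh.write(f"# {prov}\n")
            table.to_csv(fh, sep="\t", index=False)
        net = haplotype_network(table, add_medians=True)
        write_network(net, run_dir / "network_edges.tsv", run_dir / "network.graphml")
        log.append(f"network: {len(net.nodes)} nodes, {len(net.edges)} edges")
    except Exception as e:
        raise StageError(stage, str(e)) from e

    return run_dir


def _write_distributions(out_dir: Path, disease: str, dists, prov: str) -> None:
    lines = [f"# {prov}", "subject\tlength\tcount"]
    prog = [f"# {prov}", "subject\tprogenitor"]
    for subject in sorted(dists):
        d = dists[subject]
        prog.append(f"{subject}\t{d.progenitor}")
        for length in sorted(d.counts):
            lines.append(f"{subject}\t{length}\t{d.counts[length]}")
    (out_dir / f"{disease}_repeat_sizes.tsv").write_text("\n".join(lines) + "\n")
    (out_dir / f"{disease}_progenitors.tsv").write_text("\n".join(prog) + "\n")


def _write_calls_json(path: Path, calls, prov: str) -> None:
    payload = {"_provenance": prov, "subjects": {}}
    for subject in sorted(calls):
        c = calls[subject]
        payload["subjects"][subject] = {
            "haplotypes": [
                {"repeat_allele": h.repeat_allele, "variants": dict(sorted(h.variant_alleles.items()))}
                for h in c.haplotypes
            ],
            "support": dict(sorted(c.support.items())),
            "n_unambiguous": c.n_unambiguous,
            "n_ambiguous": c.n_ambiguous,
            "variant_genotypes": dict(sorted(c.variant_genotypes.items())),
            "variant_depth": dict(sorted(c.variant_depth.items())),
            "flags": c.flags,
        }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_calls_json(path: str | Path) -> dict:
    """Load genotype calls written by the pipeline back into call objects."""
    from .genotyper import DiploidGenotypeCall
    from .locus import Haplotype

    payload = json.loads(Path(path).read_text())
    calls = {}
    for subject, d in payload["subjects"].items():
        calls[subject] = DiploidGenotypeCall(
            haplotypes=tuple(
                Haplotype(h["repeat_allele"], h["variants"]) for h in d["haplotypes"]
            ),
            support=d["support"],
            n_unambiguous=d["n_unambiguous"],
            n_ambiguous=d["n_ambiguous"],
            variant_genotypes=d["variant_genotypes"],
            variant_depth=d["variant_depth"],
            flags=list(d["flags"]),
        )
    return calls
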