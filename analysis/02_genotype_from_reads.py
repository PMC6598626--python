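#!/usr/bin/env python
"""Genotype simulated paired-end amplicon reads by multi-reference alignment.

Simulates MiSeq-like read pairs (400 nt forward / 200 nt reverse) for a set
of diploid subjects, merges pairs, classifies each merged read against the
16-allele reference bank and calls phased diploid genotypes, then scores the
calls against the simulated truth. Writes results/genotyping_recovery.tsv.
"""

import argparse
import pathlib

from msh3rep import benchmarks

RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n", type=int, default=50, help="subjects to genotype")
    ap.add_argument("--coverage", type=int, default=60)
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)
    r = benchmarks.genotype_recovery(
        args.seed, n_subjects=args.n, coverage=args.coverage, error_rate=0.005
    )
    lines = [
        "n_subjects\tcoverage\terror_rate\trecovery_fraction\tno_calls",
        f"{r['n']}\t{r['coverage']}\t{r['error_rate']}\t{r['fraction']:.4f}\t{r['no_calls']}",
    ]
    (RESULTS / "genotyping_recovery.tsv").write_text("\n".join(lines) + "\n")
    print(
        f"exact phased diploid recovery: {100 * r['fraction']:.1f}% of {r['n']} subjects "
        f"at {r['coverage']}x, error rate {r['error_rate']}"
    )


if __name__ == "__main__":
    main()
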