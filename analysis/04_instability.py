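#!/usr/bin/env python
"""Somatic-instability indices and relative rates for the simulated cohorts.

Reads the repeat-size distributions written by 01_simulate_cohorts.py,
computes the disease-appropriate expansion index (HD: expansion reads
relative to progenitor reads; DM1: modal shift) and residualises it on age
and inherited repeat length. Writes results/instability_{HD,DM1}.tsv.
"""

import pathlib

import pandas as pd

from msh3rep.instability import (
    RepeatSizeDistribution,
    expansion_index_dm1,
    expansion_index_hd,
    relative_rate,
    write_indices_tsv,
)

RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"


def main():
    for disease, index_of in (("HD", expansion_index_hd), ("DM1", expansion_index_dm1)):
        cohort = pd.read_csv(RESULTS / f"cohort_{disease}.tsv", sep="\t", comment="#")
        sizes = pd.read_csv(RESULTS / f"repeat_sizes_{disease}.tsv", sep="\t")
        prog = dict(zip(cohort["subject"], cohort["inherited_length"]))
        dists = {
            s: RepeatSizeDistribution(dict(zip(g["length"], g["count"])), prog[s], subject=s)
            for s, g in sizes.groupby("subject")
        }
        subjects = list(cohort["subject"])
        idx = {s: index_of(dists[s]) for s in subjects}
        resid = relative_rate(
            [idx[s].value for s in subjects], cohort["age"], cohort["inherited_length"]
        )
        write_indices_tsv(
            RESULTS / f"instability_{disease}.tsv",
            {s: (idx[s], r) for s, r in zip(subjects, resid)},
        )
        print(
            f"{disease}: mean index {sum(v.value for v in idx.values()) / len(idx):.2f} "
            f"({idx[subjects[0]].measure}); residual SD {resid.std():.3f}"
        )


if __name__ == "__main__":
    main()
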