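"""Somatic-expansion measures over per-subject repeat-size distributions.

Somatic instability of the pathogenic CAG·CTG repeat is expansion-biased and
age-dependent: sequencing a subject's blood yields a distribution of repeat
lengths around the inherited (progenitor) allele. Two disease-specific
summaries are computed here, plus the residualised "relative rate" that both
cohorts share:

* Huntington's disease (MiSeq): the number of reads longer than the
  progenitor allele relative to the number of reads at the progenitor allele.
* DM1: the difference in repeat number between the modal allele of the
  distribution and the estimated progenitor allele.
* relative rate: the variation in either measure not explained by age and
  inherited repeat length (OLS residual); positive values mean faster
  expansion than expected.

The HD measure is implemented as the ratio N(length > progenitor) /
N(length = progenitor); a fraction-of-total variant sits behind
``mode="fraction"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import NotEstimableError, UndefinedIndexError


@dataclass(frozen=True)
class RepeatSizeDistribution:
    counts: Mapping[int, int]
    progenitor: int
    subject: str = ""

    def __post_init__(self):
        counts = {int(k): int(v) for k, v in self.counts.items()}
        if any(v < 0 for v in counts.values()):
            raise UndefinedIndexError(f"{self.subject}: negative read counts")
        if sum(counts.values()) <= 0:
            raise UndefinedIndexError(f"{self.subject}: empty repeat-size distribution")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def progenitor_missing(self) -> bool:
        return self.counts.get(self.progenitor, 0) == 0


@dataclass(frozen=True)
class ExpansionIndex:
    value: float
    measure: str  # "HD_ratio" | "HD_fraction" | "DM1_modal_shift"

    def __float__(self) -> float:
        return float(self.value)


def expansion_index_hd(dist: RepeatSizeDistribution, mode: str = "ratio") -> ExpansionIndex:
    """Expansion-read count relative to (or as a fraction of) progenitor reads."""
    n_prog = dist.counts.get(dist.progenitor, 0)
    n_exp = sum(v for k, v in dist.counts.items() if k > dist.progenitor)
    if mode == "ratio":
        if n_prog == 0:
            raise UndefinedIndexError(
                f"{dist.subject}: no reads at the progenitor length {dist.progenitor}"
            )
        return ExpansionIndex(n_exp / n_prog, "HD_ratio")
    if mode == "fraction":
        return ExpansionIndex(n_exp / dist.total, "HD_fraction")
    raise ValueError(f"unknown mode {mode!r}")


def modal_length(dist: RepeatSizeDistribution) -> int:
    """Most frequent repeat length; ties resolve to the smaller length."""
    best = max(sorted(dist.counts), key=lambda k: dist.counts[k])
    return best


def expansion_index_dm1(dist: RepeatSizeDistribution) -> ExpansionIndex:
    """Modal length minus progenitor length (contractions give negative values)."""
    return ExpansionIndex(float(modal_length(dist) - dist.progenitor), "DM1_modal_shift")


def relative_rate(
    indices: Sequence[float],
    ages: Sequence[float],
    lengths: Sequence[float],
    interaction: bool = False,
    log_transform: bool = False,
) -> np.ndarray:
    """Per-subject residual of index ~ intercept + age + length (+ age x length).

    The residuals are exactly orthogonal to the covariates and sum to zero;
    positive values mean a faster rate of somatic expansion than expected for
    the subject's age and inherited repeat length.
    """
    y = np.asarray(indices, dtype=float)
    age = np.asarray(ages, dtype=float)
    length = np.asarray(lengths, dtype=float)
    if np.isnan(y).any() or np.isnan(age).any() or np.isnan(length).any():
        raise NotEstimableError("missing covariate or index values")
    if log_transform:
        y = np.log1p(y)
    cols = {"age": age, "length": length}
    if interaction:
        cols["age_x_length"] = age * length
    X = sm.add_constant(pd.DataFrame(cols), has_constant="add")
    n, p = X.shape
    if n <= p:
        raise NotEstimableError(f"n={n} subjects cannot identify {p} parameters")
    if np.linalg.matrix_rank(X.to_numpy()) < p:
        raise NotEstimableError("rank-deficient covariate design")
    return np.asarray(sm.OLS(y, X).fit().resid)


# -- plain-text IO ---------------------------------------------------------


def read_distributions_tsv(
    counts_path: str | Path, progenitor_path: str | Path
) -> dict[str, RepeatSizeDistribution]:
    """Load (subject, length, count) rows plus a (subject, progenitor) table."""
    counts = pd.read_csv(counts_path, sep="\t", comment="#")
    prog = pd.read_csv(progenitor_path, sep="\t", comment="#").set_index("subject")
    out = {}
    for subject, grp in counts.groupby("subject"):
        out[str(subject)] = RepeatSizeDistribution(
            dict(zip(grp["length"], grp["count"])),
            int(prog.loc[subject, "progenitor"]),
            subject=str(subject),
        )
    return out


def write_indices_tsv(
    path: str | Path,
    rows: Mapping[str, tuple[ExpansionIndex, float]],
    comment: str | None = None,
) -> None:
    """Write per-subject index values and relative-rate residuals."""
    lines = []
    if comment:
        lines.append(f"# {comment}")
    lines.append("subject\tmeasure\tindex\trelative_rate")
    for subject in sorted(rows):
        idx, resid = rows[subject]
        lines.append(f"{subject}\t{idx.measure}\t{idx.value:.6g}\t{resid:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")
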