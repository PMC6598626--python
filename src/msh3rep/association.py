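"""Genotype-phenotype association and cross-disease meta-analysis.

Markers (repeat alleles or flanking variants) are scored under an additive
genetic model: the phenotype is regressed on the 0/1/2 dosage of the target
allele with disease-specific covariates (inherited CAG·CTG length; repeat
interruptions in DM1). Conditional fits add the repeat-allele dosages to the
design so that a SNP's effect is tested net of the repeat — a SNP in complete
LD with a repeat allele then becomes non-estimable, which is reported rather
than silently dropped. Cross-cohort evidence is combined with a
sample-size-weighted Z meta-analysis (inverse-variance optional), and
haplotype structure is summarised by frequencies, pairwise D'/r2 and a
minimum-spanning haplotype network with an optional median-vector pass.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import NotEstimableError
from .genotyper import DiploidGenotypeCall
from .locus import Haplotype

_RANK_TOL = 1e-8


@dataclass(frozen=True)
class AssociationResult:
    marker: str
    phenotype: str
    beta: float
    se: float
    t: float
    p: float
    n: int
    df: int
    covariates: tuple[str, ...]
    estimable: bool = True
    note: str = ""

    def z(self) -> float:
        """Signed Z equivalent of the two-sided p (direction from beta)."""
        if not self.estimable:
            raise NotEstimableError(f"{self.marker}/{self.phenotype}: not estimable")
        z = stats.norm.isf(min(max(self.p, 1e-300), 1.0) / 2)
        return math.copysign(z, self.beta) if self.beta != 0 else 0.0


@dataclass(frozen=True)
class HWEResult:
    counts: tuple[int, int, int]  # (hom-ref, het, hom-alt)
    method: str
    statistic: float
    p: float


@dataclass(frozen=True)
class LDStats:
    d: float
    d_prime: float
    r2: float
    counts: tuple[int, int, int, int]  # AB, Ab, aB, ab
    n: int


@dataclass(frozen=True)
class MetaResult:
    z: float
    p: float
    scheme: str
    weights: tuple[float, ...]
    direction_concordance: float


@dataclass(frozen=True)
class HaplotypeNetwork:
    nodes: tuple[tuple[str, tuple, int], ...]  # (name, column vector, count)
    edges: tuple[tuple[str, str, int], ...]  # (u, v, hamming distance)
    medians: tuple[tuple, ...] = ()

    def total_weight(self) -> int:
        return sum(w for _, _, w in self.edges)


# -- dosage and regression -------------------------------------------------


def additive_dosage(call: DiploidGenotypeCall, target: str) -> int:
    """Copies (0/1/2) of a repeat allele or a flanking variant's alt allele."""
    if target in call.variant_genotypes:
        return call.variant_genotypes[target]
    return sum(1 for h in call.haplotypes if h.repeat_allele == target)


def _design(dosage, covariates) -> pd.DataFrame:
    cols = {"dosage": np.asarray(dosage, dtype=float)}
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        for c in cov.columns:
            cols[str(c)] = cov[c].to_numpy(dtype=float)
    X = pd.DataFrame(cols)
    return sm.add_constant(X, has_constant="add")


def _collinear_note(X: pd.DataFrame, column: str) -> str:
    others = X.drop(columns=[column]).to_numpy()
    target = X[column].to_numpy()
    coef, *_ = np.linalg.lstsq(others, target, rcond=None)
    names = [c for c in X.columns if c != column]
    deps = [f"{n}" for n, c in zip(names, coef) if abs(c) > 1e-6]
    return f"{column} lies in the span of {{{', '.join(deps)}}}"


def fit_additive(
    phenotype: Sequence[float],
    dosage: Sequence[float],
    covariates=None,
    marker: str = "marker",
    phenotype_name: str = "phenotype",
) -> AssociationResult:
    """OLS of phenotype on allele dosage (additive model) plus covariates.

    Two-sided t test on the dosage coefficient. Zero dosage variance or a
    rank-deficient design returns ``estimable=False`` with a note naming the
    collinear columns instead of a numeric effect.
    """
    y = np.asarray(phenotype, dtype=float)
    keep = ~np.isnan(y)
    X = _design(dosage, covariates)
    if covariates is not None:
        keep &= ~X.isna().any(axis=1).to_numpy()
    y, X = y[keep], X.loc[keep]
    n, p = X.shape
    covnames = tuple(c for c in X.columns if c not in ("const", "dosage"))
    if n <= p:
        raise NotEstimableError(f"n={n} rows cannot identify {p} parameters")
    blank = dict(marker=marker, phenotype=phenotype_name, beta=np.nan, se=np.nan, t=np.nan,
                 p=np.nan, n=n, df=n - p, covariates=covnames, estimable=False)
    if np.var(X["dosage"].to_numpy()) == 0:
        return AssociationResult(**{**blank, "note": "dosage has zero variance"})
    if np.linalg.matrix_rank(X.to_numpy()) < p:
        return AssociationResult(**{**blank, "note": _collinear_note(X, "dosage")})
    fit = sm.OLS(y, X).fit()
    return AssociationResult(
        marker=marker,
        phenotype=phenotype_name,
        beta=float(fit.params["dosage"]),
        se=float(fit.bse["dosage"]),
        t=float(fit.tvalues["dosage"]),
        p=float(fit.pvalues["dosage"]),
        n=n,
        df=int(fit.df_resid),
        covariates=covnames,
    )


def conditional_fit(
    phenotype: Sequence[float],
    snp_dosage: Sequence[float],
    repeat_dosages,
    covariates=None,
    marker: str = "snp",
    phenotype_name: str = "phenotype",
) -> AssociationResult:
    """SNP effect conditioned on the repeat-allele dosages.

    The repeat dosage columns enter the design alongside the covariates; when
    the SNP dosage lies in their column space (complete LD, as for the three
    5' SNPs perfectly correlated with the 3a allele) the independent SNP
    effect does not exist and ``estimable=False`` is returned, naming the
    dependency.
    """
    rep = pd.DataFrame(repeat_dosages).reset_index(drop=True)
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        combined = pd.concat([cov, rep], axis=1)
    else:
        combined = rep if rep.shape[1] else None
    return fit_additive(
        phenotype, snp_dosage, combined, marker=marker, phenotype_name=phenotype_name
    )


DISEASE_COVARIATES = {
    ("HD", "onset"): ("inherited_length",),
    ("DM1", "onset"): ("inherited_length", "interrupted"),
    ("HD", "progression"): ("inherited_length",),
}


def fit_marker(
    cohort: pd.DataFrame, marker: str, phenotype: str, disease: str | None = None
) -> AssociationResult:
    """Additive fit of one cohort-table marker column on one phenotype column.

    Disease-specific covariates follow the analysis convention: onset is
    adjusted for inherited repeat length (plus interruptions in DM1);
    progression for inherited length; the relative rate of expansion and
    expression are analysed unadjusted (the rate is already residualised).
    """
    disease = disease or str(cohort["disease"].iloc[0])
    covnames = DISEASE_COVARIATES.get((disease, phenotype), ())
    cov = cohort[list(covnames)] if covnames else None
    return fit_additive(
        cohort[phenotype], cohort[f"dos_{marker}"], cov, marker=marker, phenotype_name=phenotype
    )


def bonferroni(p: float, n_tests: int) -> float:
    return min(1.0, p * n_tests)


# -- Hardy-Weinberg --------------------------------------------------------


def hwe_test(counts: Sequence[int], method: str = "exact") -> HWEResult:
    """HWE goodness of fit from (hom-ref, het, hom-alt) genotype counts.

    ``chi2``: 1-df goodness-of-fit against p^2 : 2pq : q^2 expectations.
    ``exact``: Levene-Haldane exact test, full enumeration of heterozygote
    counts compatible with the allele counts (no mid-p correction).
    Monomorphic samples give p = 1 by convention.
    """
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("negative genotype counts")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("empty genotype table")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return HWEResult((n_aa, n_ab, n_bb), method, 0.0, 1.0)
    if method == "chi2":
        p_a = n_a / (2 * n)
        exp = np.array([n * p_a**2, 2 * n * p_a * (1 - p_a), n * (1 - p_a) ** 2])
        obs = np.array([n_aa, n_ab, n_bb], dtype=float)
        statistic = float(np.sum((obs - exp) ** 2 / exp))
        return HWEResult((n_aa, n_ab, n_bb), "chi2", statistic, float(stats.chi2.sf(statistic, 1)))
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    rare = min(n_a, n_b)
    probs = _hwe_het_probabilities(n, rare)
    p_obs = probs.get(n_ab, 0.0)
    p_val = min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))
    return HWEResult((n_aa, n_ab, n_bb), "exact", float(n_ab), p_val)


def _hwe_het_probabilities(n: int, rare: int) -> dict[int, float]:
    """Levene-Haldane distribution of the heterozygote count given allele counts."""
    from math import lgamma

    def logfac(x):
        return lgamma(x + 1)

    common = 2 * n - rare
    logs = {}
    for het in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - het) // 2
        hom_common = (common - het) // 2
        logs[het] = (
            het * math.log(2)
            + logfac(n)
            - logfac(hom_rare)
            - logfac(het)
            - logfac(hom_common)
            + logfac(rare)
            + logfac(common)
            - logfac(2 * n)
        )
    mx = max(logs.values())
    tot = sum(math.exp(v - mx) for v in logs.values())
    return {het: math.exp(v - mx) / tot for het, v in logs.items()}


# -- linkage disequilibrium ------------------------------------------------


def ld_stats(haplotype_pairs: Sequence[tuple[int, int]]) -> LDStats:
    """D, D' and r2 from phased two-locus haplotypes coded 1 = target allele.

    Standard normalisation: D = pAB - pA pB; D' = D / Dmax with Dmax chosen by
    the sign of D; r2 = D^2 / (pA pa pB pb). Monomorphic loci are undefined.
    """
    arr = np.asarray(haplotype_pairs, dtype=int)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 phased haplotypes of two loci")
    n = arr.shape[0]
    p_a = arr[:, 0].mean()
    p_b = arr[:, 1].mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise NotEstimableError("monomorphic locus: LD undefined")
    p_ab = np.mean((arr[:, 0] == 1) & (arr[:, 1] == 1))
    d = p_ab - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = d / d_max if d_max > 0 else 0.0
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    counts = (
        int(np.sum((arr[:, 0] == 1) & (arr[:, 1] == 1))),
        int(np.sum((arr[:, 0] == 1) & (arr[:, 1] == 0))),
        int(np.sum((arr[:, 0] == 0) & (arr[:, 1] == 1))),
        int(np.sum((arr[:, 0] == 0) & (arr[:, 1] == 0))),
    )
    def snap(x, lo, hi):
        # clamp into bounds and absorb float roundoff at the boundaries
        x = float(np.clip(x, lo, hi))
        for b in (lo, 0.0, hi):
            if abs(x - b) < 1e-9:
                return b
        return x

    return LDStats(float(d), snap(d_prime, -1.0, 1.0), snap(r2, 0.0, 1.0), counts, n)


def ld_from_counts(n_ab: int, n_aB: int, n_Ab: int, n_bb: int) -> LDStats:
    """LD from the four phased haplotype counts (AB, Ab, aB, ab)."""
    pairs = (
        [(1, 1)] * n_ab + [(1, 0)] * n_aB + [(0, 1)] * n_Ab + [(0, 0)] * n_bb
    )
    return ld_stats(pairs)


# -- haplotype frequencies and network ------------------------------------


def haplotype_frequencies(haplotypes: Sequence[Haplotype]) -> pd.DataFrame:
    """Count distinct phased haplotypes over 2n chromosomes and name them.

    Names Hap1, Hap2, ... are assigned in descending frequency, ties broken
    lexicographically on the (repeat allele, variant alleles) identity, so the
    naming is invariant to subject order.
    """
    if not haplotypes:
        raise ValueError("no phased haplotypes supplied")
    counts = Counter(h.key() for h in haplotypes)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(counts.values())
    rows = []
    for i, (key, c) in enumerate(ranked, start=1):
        allele, variants = key
        rows.append(
            {
                "haplotype": f"Hap{i}",
                "repeat_allele": allele,
                **{vid: state for vid, state in variants},
                "count": c,
                "frequency": c / total,
            }
        )
    return pd.DataFrame(rows)


def _hamming(u: tuple, v: tuple) -> int:
    return sum(a != b for a, b in zip(u, v))


def _msn_edges(vectors: Mapping[str, tuple]) -> list[tuple[str, str, int]]:
    """Minimum spanning network: Kruskal in equal-weight batches, all ties kept."""
    names = sorted(vectors)
    parent = {x: x for x in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    all_edges = sorted(
        (( _hamming(vectors[u], vectors[v]), u, v) for u, v in itertools.combinations(names, 2))
    )
    kept = []
    for _, batch in itertools.groupby(all_edges, key=lambda e: e[0]):
        batch = list(batch)
        addable = [(w, u, v) for w, u, v in batch if find(u) != find(v)]
        for w, u, v in addable:
            kept.append((u, v, w))
        for _, u, v in addable:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[rv] = ru
    return kept


def _column_median(vs: Sequence[tuple]) -> tuple | None:
    med = []
    for col in zip(*vs):
        c = Counter(col).most_common()
        if len(c) > 1 and c[0][1] == c[1][1]:
            return None  # no majority in this column
        med.append(c[0][0])
    return tuple(med)


def haplotype_network(
    hap_table: pd.DataFrame, add_medians: bool = False
) -> HaplotypeNetwork:
    """Minimum spanning network over haplotype Hamming distances.

    Nodes are the observed haplotypes sized by count; every co-minimal edge is
    kept (epsilon = 0). ``add_medians=True`` runs one round of median-vector
    insertion: the column-majority vector of an observed triple is added (as a
    zero-count node) if it strictly reduces the total edge weight, best
    candidate first — a single-pass simplification of full median joining.
    A single haplotype yields a single-node network.
    """
    cols = [c for c in hap_table.columns if c not in ("haplotype", "count", "frequency")]
    vectors = {
        str(row["haplotype"]): tuple(row[c] for c in cols) for _, row in hap_table.iterrows()
    }
    counts = {str(row["haplotype"]): int(row["count"]) for _, row in hap_table.iterrows()}
    edges = _msn_edges(vectors)
    medians: list[tuple] = []
    if add_medians and len(vectors) >= 3:
        base_weight = sum(w for _, _, w in edges)
        candidates = {}
        observed = set(vectors.values())
        for triple in itertools.combinations(sorted(vectors), 3):
            med = _column_median([vectors[t] for t in triple])
            if med is None or med in observed:
                continue
            trial = dict(vectors)
            trial[f"mv_{med}"] = med
            w = sum(e[2] for e in _msn_edges(trial))
            if w < base_weight:
                candidates[med] = w
        if candidates:
            best = min(sorted(candidates), key=lambda m: candidates[m])
            medians.append(best)
            vectors[f"Median1"] = best
            counts[f"Median1"] = 0
            edges = _msn_edges(vectors)
    nodes = tuple((name, vectors[name], counts[name]) for name in sorted(vectors))
    return HaplotypeNetwork(nodes=nodes, edges=tuple(edges), medians=tuple(medians))


def write_network(network: HaplotypeNetwork, edge_tsv: str | Path, graphml: str | Path) -> None:
    import networkx as nx

    lines = ["from\tto\tdistance"]
    for u, v, w in network.edges:
        lines.append(f"{u}\t{v}\t{w}")
    Path(edge_tsv).write_text("\n".join(lines) + "\n")
    g = nx.Graph()
    for name, vec, count in network.nodes:
        g.add_node(name, count=count, haplotype="|".join(map(str, vec)))
    for u, v, w in network.edges:
        g.add_edge(u, v, weight=w)
    nx.write_graphml(g, str(graphml))


# -- meta-analysis ---------------------------------------------------------


def meta_z(zs: Sequence[float], ns: Sequence[float]) -> float:
    """Sample-size-weighted combined Z: sum(sqrt(N_i) Z_i) / sqrt(sum N_i)."""
    zs = np.asarray(zs, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if zs.size == 0:
        raise ValueError("meta-analysis needs at least one study")
    if np.any(ns <= 0):
        raise ValueError("study sizes must be positive")
    return float(np.sum(np.sqrt(ns) * zs) / np.sqrt(np.sum(ns)))


def meta_analysis(
    results: Sequence[AssociationResult],
    scheme: str = "sample_size",
    orientations: Sequence[int] | None = None,
) -> MetaResult:
    """Fixed-effect meta-analysis across cohorts.

    Default scheme combines signed Zs with sqrt(N) weights (protective,
    negative effects carry negative Z); ``inverse_variance`` pools betas with
    1/se^2 weights. ``orientations`` (+1/-1 per study) flips studies whose
    effect allele was coded in the opposite direction.
    """
    results = [r for r in results]
    if not results:
        raise ValueError("meta-analysis needs at least one study")
    if orientations is None:
        orientations = [1] * len(results)
    if len(orientations) != len(results):
        raise ValueError("one orientation per study required")
    if any(not r.estimable for r in results):
        raise NotEstimableError("cannot meta-analyse non-estimable study results")
    if scheme == "sample_size":
        zs = [o * r.z() for o, r in zip(orientations, results)]
        ns = [r.n for r in results]
        z = meta_z(zs, ns)
        weights = tuple(math.sqrt(n) for n in ns)
    elif scheme == "inverse_variance":
        w = np.array([1.0 / r.se**2 for r in results])
        betas = np.array([o * r.beta for o, r in zip(orientations, results)])
        beta = float(np.sum(w * betas) / np.sum(w))
        se = float(1.0 / math.sqrt(np.sum(w)))
        z = beta / se
        zs = [o * r.z() for o, r in zip(orientations, results)]
        weights = tuple(float(x) for x in w)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    p = float(2 * stats.norm.sf(abs(z)))
    signs = [math.copysign(1.0, zz) for zz in zs if zz != 0]
    if signs and z != 0:
        concordance = sum(1 for s in signs if s == math.copysign(1.0, z)) / len(signs)
    else:
        concordance = 1.0
    return MetaResult(z=z, p=p, scheme=scheme, weights=weights, direction_concordance=concordance)
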