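"""From paired amplicon FASTQ to phased diploid repeat + SNP genotypes.

The genotyping strategy follows the multi-reference idea: merged reads are
aligned against a bank of reference renderings, one per catalogue repeat
allele, and each read votes for the allele it fits best. This is what makes
repeat-length genotypes reliable at this locus; aligning everything to the
single six-unit reference instead produces phantom variants (see
``artefact_scan``), which is how the imputed SNP rs557874766 arose from the
three-unit allele.

Phasing is read-backed only: one merged read spans the whole amplicon, so
flanking-variant alleles co-occur with a repeat allele on the same molecule.
"""

from __future__ import annotations

import hashlib
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import (
    AlignmentResult,
    DEFAULT_SCORING,
    Scoring,
    align_to_reference,
    alignment_score,
)
from .errors import AlignmentError, MergeError, NoCallError
from .locus import Haplotype, LocusModel, reference_bank, revcomp

#: band half-width used for banked alignment of substitution-only reads; wide
#: enough for the repeat-length difference corridor plus indel-variant drift.
DEFAULT_BAND = 25


@dataclass(frozen=True)
class MergedRead:
    name: str
    sequence: str
    qualities: tuple[int, ...]
    merged: bool
    overlap: int

    def __post_init__(self):
        if self.merged and len(self.sequence) != len(self.qualities):
            raise MergeError(f"read {self.name!r}: sequence/quality length mismatch")


@dataclass(frozen=True)
class ReadClassification:
    """Best-fitting reference allele for one read, with the score margin."""

    best_allele: str
    best_score: int
    margin: int
    ambiguous: bool
    co_optimal: tuple[str, ...] = ()


@dataclass(frozen=True)
class ApparentVariant:
    """A pileup call produced by forcing reads onto a single reference."""

    position: int
    ref: str
    alt: str
    fraction: float
    classification: str  # substitution | insertion | deletion
    in_repeat: bool

    def __post_init__(self):
        if not (0.0 < self.fraction <= 1.0):
            raise AlignmentError("supporting fraction must be in (0, 1]")


@dataclass
class DiploidGenotypeCall:
    haplotypes: tuple[Haplotype, Haplotype]
    support: dict[str, int]  # unambiguous reads per repeat-allele class
    n_unambiguous: int
    n_ambiguous: int
    variant_genotypes: dict[str, int]  # variant id -> alt-allele count (0/1/2)
    variant_depth: dict[str, int]
    flags: list[str] = field(default_factory=list)

    @property
    def repeat_genotype(self) -> tuple[str, str]:
        return tuple(sorted(h.repeat_allele for h in self.haplotypes))

    def haplotype_keys(self) -> frozenset:
        """Order-free identity of the diploid call (for truth comparison)."""
        return frozenset(Counter(h.key() for h in self.haplotypes).items())


# -- read merging ----------------------------------------------------------


def merge_pair(
    name: str,
    fwd_seq: str,
    fwd_qual: Sequence[int],
    rev_seq: str,
    rev_qual: Sequence[int],
    min_overlap: int = 10,
    max_overlap_mismatch_frac: float = 0.1,
) -> MergedRead:
    """Merge one read pair by the best ungapped overlap.

    The reverse read is reverse-complemented; every overlap length from
    ``min_overlap`` up is scored by mismatch count, the lowest mismatch
    fraction wins (ties to the longer overlap), and overlap disagreements are
    resolved to the higher-quality base (ties to the forward base). A pair
    whose best overlap still exceeds the mismatch threshold is returned
    unmerged (forward read retained) with ``merged=False``.
    """
    rc = revcomp(rev_seq)
    rq = np.asarray(rev_qual[::-1], dtype=np.int64)
    fq = np.asarray(fwd_qual, dtype=np.int64)
    f = np.frombuffer(fwd_seq.encode(), dtype=np.uint8)
    r = np.frombuffer(rc.encode(), dtype=np.uint8)
    max_l = min(len(f), len(r))
    if min_overlap < 1 or max_l < min_overlap:
        return MergedRead(name, fwd_seq, tuple(fwd_qual), False, 0)
    best_frac, best_l, best_mm = np.inf, 0, 0
    for L in range(min_overlap, max_l + 1):
        mm = int(np.count_nonzero(f[len(f) - L :] != r[:L]))
        frac = mm / L
        if frac < best_frac or (frac == best_frac and L > best_l):
            best_frac, best_l, best_mm = frac, L, mm
    if best_frac > max_overlap_mismatch_frac:
        return MergedRead(name, fwd_seq, tuple(fwd_qual), False, 0)
    L = best_l
    ov_f, ov_r = f[len(f) - L :].copy(), r[:L]
    qv_f, qv_r = fq[len(f) - L :].copy(), rq[:L]
    take_rev = qv_r > qv_f
    ov_f[take_rev] = ov_r[take_rev]
    qv = np.maximum(qv_f, qv_r)
    seq = fwd_seq[: len(f) - L] + ov_f.tobytes().decode() + rc[L:]
    quals = tuple(int(x) for x in np.concatenate([fq[: len(f) - L], qv, rq[L:]]))
    return MergedRead(name, seq, quals, True, L)


def merge_pairs(
    fwd_reads: Sequence[tuple[str, str, Sequence[int]]],
    rev_reads: Sequence[tuple[str, str, Sequence[int]]],
    min_overlap: int = 10,
    max_overlap_mismatch_frac: float = 0.1,
) -> list[MergedRead]:
    """Merge paired (name, sequence, qualities) streams, in order."""
    if len(fwd_reads) != len(rev_reads):
        raise MergeError(
            f"unpaired input: {len(fwd_reads)} forward vs {len(rev_reads)} reverse reads"
        )
    return [
        merge_pair(fn, fs, fquals, rs, rquals, min_overlap, max_overlap_mismatch_frac)
        for (fn, fs, fquals), (_, rs, rquals) in zip(fwd_reads, rev_reads)
    ]


# -- classification --------------------------------------------------------


def classify_read(
    read: str,
    bank: Mapping[str, str],
    scoring: Scoring = DEFAULT_SCORING,
    band: int | None = DEFAULT_BAND,
) -> ReadClassification:
    """Align one read to every reference in the bank and pick the best allele.

    Co-optimal top scores are never resolved silently: the read is flagged
    ambiguous (margin 0) and excluded from genotype support downstream; the
    reported best allele is then the alphabetically first co-optimal one.
    """
    if len(bank) < 2:
        raise AlignmentError("reference bank needs at least two allele renderings")
    scores = {rid: alignment_score(read, seq, scoring, band=band) for rid, seq in bank.items()}
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    best_allele, best = ranked[0]
    second = ranked[1][1]
    margin = best - second
    co = tuple(rid for rid, s in ranked if s == best)
    return ReadClassification(best_allele, best, margin, ambiguous=len(co) > 1, co_optimal=co)


def classify_reads(
    reads: Iterable[str],
    bank: Mapping[str, str],
    scoring: Scoring = DEFAULT_SCORING,
    band: int | None = DEFAULT_BAND,
) -> list[ReadClassification]:
    """Classify many reads with memoisation over identical read sequences."""
    cache: dict[str, ReadClassification] = {}
    out = []
    for seq in reads:
        c = cache.get(seq)
        if c is None:
            c = cache[seq] = classify_read(seq, bank, scoring, band)
        out.append(c)
    return out


# -- variant extraction and diploid calling -------------------------------


def _variant_state(
    aln: AlignmentResult, read: str, locus: LocusModel, allele_name: str, vid: str
) -> str | None:
    """Read's allele at one flanking variant, or None if unreadable there."""
    v = locus.variant(vid)
    n_units = locus.allele(allele_name).n_units
    pos = locus.map_offset(v.offset, n_units)
    if not (aln.start <= pos <= aln.end):
        return None
    if v.kind == "snp":
        qi = aln.query_index_at(pos)
        if qi is None:
            return None
        base = read[qi]
        if base == v.ref:
            return "ref"
        return "alt" if base == v.alt else None
    if v.kind == "del":
        qi = aln.query_index_at(pos)
        if qi is None:
            return "alt"
        return "ref" if read[qi] == v.ref else None
    # insertion
    return "alt" if pos in aln.insertion_sites else "ref"


def call_genotype(
    classified: Sequence[tuple[str, ReadClassification]],
    locus: LocusModel,
    min_depth: int = 30,
    min_hap_frac: float = 0.2,
    scoring: Scoring = DEFAULT_SCORING,
    band: int | None = DEFAULT_BAND,
) -> DiploidGenotypeCall:
    """Call the phased diploid genotype from classified merged reads.

    The repeat genotype is the top one or two allele classes each supported by
    at least ``min_hap_frac`` of unambiguous reads. Flanking variants are then
    called per haplotype from the reads assigned to that allele class (phasing
    by co-occurrence on the same merged read); repeat homozygotes get both
    haplotypes from partitioning reads on their variant-allele vectors.
    """
    bank = reference_bank(locus)
    unamb = [(seq, c) for seq, c in classified if not c.ambiguous]
    n_amb = len(classified) - len(unamb)
    if len(unamb) < min_depth:
        raise NoCallError(f"{len(unamb)} unambiguous reads < min_depth={min_depth}")
    support = Counter(c.best_allele for _, c in unamb)
    total = len(unamb)
    eligible = sorted(
        (a for a, n in support.items() if n >= min_hap_frac * total),
        key=lambda a: (-support[a], a),
    )
    if not eligible:
        raise NoCallError("no repeat allele reaches min_hap_frac support")
    flags: list[str] = []
    if len(eligible) > 2:
        flags.append("contamination:" + ",".join(eligible))
    called_alleles = eligible[:2]
    minor = set(support) - set(called_alleles)
    if minor:
        flags.append("minor_allele_reads:" + ",".join(sorted(minor)))

    # per-read variant-allele vectors, grouped by assigned allele class
    vids = [v.id for v in locus.variants]
    vectors: dict[str, list[dict[str, str | None]]] = defaultdict(list)
    aln_cache: dict[tuple[str, str], AlignmentResult] = {}
    for seq, c in unamb:
        if c.best_allele not in called_alleles:
            continue
        key = (seq, c.best_allele)
        aln = aln_cache.get(key)
        if aln is None:
            aln = aln_cache[key] = align_to_reference(
                seq, bank[c.best_allele], scoring, reference_id=c.best_allele, band=band
            )
        vectors[c.best_allele].append(
            {vid: _variant_state(aln, seq, locus, c.best_allele, vid) for vid in vids}
        )

    def majority(states: list[str | None]) -> str:
        votes = Counter(s for s in states if s is not None)
        if not votes:
            return "ref"  # uncovered variant: reference by convention, depth 0 recorded
        return max(sorted(votes), key=lambda s: votes[s])

    if len(called_alleles) == 2:
        haps = tuple(
            Haplotype(a, {vid: majority([vec[vid] for vec in vectors[a]]) for vid in vids})
            for a in called_alleles
        )
    else:
        a = called_alleles[0]
        complete = Counter(
            tuple((vid, vec[vid]) for vid in vids)
            for vec in vectors[a]
            if all(vec[vid] is not None for vid in vids)
        )
        if not complete:
            raise NoCallError("no read covers all flanking variants")
        ranked = sorted(complete.items(), key=lambda kv: (-kv[1], kv[0]))
        h1 = Haplotype(a, dict(ranked[0][0]))
        n_vec = sum(complete.values())
        if len(ranked) > 1 and ranked[1][1] >= min_hap_frac * n_vec:
            h2 = Haplotype(a, dict(ranked[1][0]))
        else:
            h2 = h1
        haps = (h1, h2)

    variant_genotypes = {
        vid: sum(1 for h in haps if h.variant_alleles[vid] == "alt") for vid in vids
    }
    variant_depth = {
        vid: sum(
            1 for a in called_alleles for vec in vectors[a] if vec[vid] is not None
        )
        for vid in vids
    }
    return DiploidGenotypeCall(
        haplotypes=haps,
        support=dict(support),
        n_unambiguous=total,
        n_ambiguous=n_amb,
        variant_genotypes=variant_genotypes,
        variant_depth=variant_depth,
        flags=flags,
    )


def genotype_reads(
    reads: Sequence[str],
    locus: LocusModel,
    scoring: Scoring = DEFAULT_SCORING,
    min_depth: int = 30,
    min_hap_frac: float = 0.2,
    band: int | None = DEFAULT_BAND,
) -> DiploidGenotypeCall:
    """Convenience wrapper: classify merged read sequences, then call."""
    bank = reference_bank(locus)
    cls = classify_reads(reads, bank, scoring, band)
    return call_genotype(list(zip(reads, cls)), locus, min_depth, min_hap_frac, scoring, band)


# -- phantom-variant demonstrator ------------------------------------------


def artefact_scan(
    reads: Sequence[str],
    locus: LocusModel,
    reference_allele: str,
    scoring: Scoring = DEFAULT_SCORING,
    min_frac: float = 0.5,
    band: int | None = None,
) -> list[ApparentVariant]:
    """Force all reads onto a single allele reference and pile up the damage.

    When the reads come from an allele of a different repeat length, the
    alignments fabricate variants: under gap-hostile scoring an apparent
    substitution inside the repeat (the phantom-SNP mechanism), under
    gap-friendly scoring a unit-multiple deletion. When the reads come from
    the same allele the scan is empty — and so it is when the multi-reference
    genotyper is used instead, which is the artefact's resolution.
    """
    ref = reference_bank(locus)[reference_allele]
    n_units = locus.allele(reference_allele).n_units
    rep_lo, rep_hi = locus.repeat_interval(n_units)
    coverage = np.zeros(len(ref) + 1, dtype=np.int64)
    sub_counts: Counter = Counter()  # (pos, alt base)
    del_counts: Counter = Counter()  # pos
    ins_counts: Counter = Counter()  # (pos, inserted seq)
    aln_cache: dict[str, AlignmentResult] = {}
    for seq in reads:
        aln = aln_cache.get(seq)
        if aln is None:
            aln = aln_cache[seq] = align_to_reference(
                seq, ref, scoring, reference_id=reference_allele, band=band
            )
        coverage[aln.start : aln.end + 1] += 1
        qi, rp = 0, aln.start - 1
        for op, n in aln.ops:
            if op == "M":
                for t in range(n):
                    if seq[qi + t] != ref[rp + t]:
                        sub_counts[(rp + t + 1, seq[qi + t])] += 1
                qi += n
                rp += n
            elif op == "I":
                ins_counts[(rp, seq[qi : qi + n])] += 1
                qi += n
            else:
                for t in range(n):
                    del_counts[rp + t + 1] += 1
                rp += n
    if coverage[rep_lo : rep_hi + 1].sum() == 0:
        raise AlignmentError("no reads cover the repeat region of the chosen reference")
    out: list[ApparentVariant] = []
    for (pos, alt), n in sub_counts.items():
        frac = n / coverage[pos]
        if frac >= min_frac:
            out.append(
                ApparentVariant(pos, ref[pos - 1], alt, frac, "substitution", rep_lo <= pos <= rep_hi)
            )
    for pos, n in del_counts.items():
        frac = n / coverage[pos]
        if frac >= min_frac:
            out.append(
                ApparentVariant(pos, ref[pos - 1], "", frac, "deletion", rep_lo <= pos <= rep_hi)
            )
    for (pos, ins), n in ins_counts.items():
        cov = coverage[pos] if pos >= 1 else coverage[1]
        frac = n / cov if cov else 0.0
        if cov and frac >= min_frac:
            out.append(
                ApparentVariant(pos, "", ins, frac, "insertion", rep_lo <= pos <= rep_hi)
            )
    out.sort(key=lambda v: (v.position, v.classification, v.alt))
    return out


# -- writers ---------------------------------------------------------------


def write_sam(
    path: str | Path,
    records: Sequence[tuple[MergedRead, AlignmentResult | None]],
    locus: LocusModel,
    comment: str | None = None,
) -> None:
    """Write merged reads against their best allele reference as plain-text SAM.

    Mandatory fields only; the header carries one @SQ line per bank allele with
    an MD5 of its rendering, so homozygote haplotypes can be confirmed in any
    SAM viewer. Unclassified reads are written unmapped.
    """
    import pysam

    bank = reference_bank(locus)
    names = list(bank)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": a, "LN": len(bank[a]), "M5": hashlib.md5(bank[a].encode()).hexdigest()}
            for a in names
        ],
    }
    if comment:
        header["CO"] = [comment]
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read, aln in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = read.name
            seg.query_sequence = read.sequence
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in read.qualities)
            )
            if aln is None:
                seg.is_unmapped = True
            else:
                seg.reference_id = names.index(aln.reference_id)
                seg.reference_start = aln.start - 1
                seg.mapping_quality = 60
                # leading/trailing read-vs-gap runs become soft clips in SAM
                ops = list(aln.ops)
                cig = []
                for idx, (op, n) in enumerate(ops):
                    if op == "I" and (idx == 0 or idx == len(ops) - 1):
                        cig.append((4, n))
                    else:
                        cig.append(({"M": 0, "I": 1, "D": 2}[op], n))
                seg.cigartuples = cig
            out.write(seg)


def write_variant_tsv(
    path: str | Path, calls: Mapping[str, DiploidGenotypeCall], locus: LocusModel
) -> None:
    """VCF-like long-format TSV of flanking-variant genotypes (1-based POS)."""
    lines = ["CHROM\tPOS\tID\tREF\tALT\tsubject\tgenotype\tdepth"]
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    for subject in sorted(calls):
        call = calls[subject]
        for v in locus.variants:
            lines.append(
                f"{locus.locus_id}\t{v.offset}\t{v.id}\t{v.ref or '-'}\t{v.alt or '-'}\t"
                f"{subject}\t{gt[call.variant_genotypes[v.id]]}\t{call.variant_depth[v.id]}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
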