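"""Model of the MSH3/DHFR exon-1 tandem-repeat locus.

The locus is a ~500 bp amplicon containing a polymorphic 9-bp tandem repeat
that overlaps *MSH3* exon 1 and the *DHFR* promoter (head-to-head genes on
opposite strands). Alleles are ordered concatenations of 9-bp repeat units,
each unit coding three Pro/Ala residues in the MSH3 reading frame; the repeat
is flanked by a highly polymorphic region carrying six SNPs and a 1-bp indel.

Coordinates are 1-based and inclusive on the MSH3 coding strand. The rendering
of the six-unit reference allele ("6a") with all flanking variants at their
reference state defines the locus reference frame; variant offsets are stated
in that frame and re-mapped automatically for alleles of other lengths.

The shipped default locus is synthetic: the five unit sequences, flank
sequences and variant offsets are deterministic stand-ins that satisfy every
structural constraint of the real locus (unit length, Pro/Ala coding, three
5'-of-repeat SNPs in complete LD with the three-unit allele, 1-bp deletion)
without reproducing unpublished sequence. A user-supplied real locus can be
loaded from the same JSON schema.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .errors import LocusError

UNIT_LENGTH = 9
REFERENCE_UNIT_COUNT = 6  # the "6a" allele is the locus reference frame

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatUnit:
    """One 9-bp repeat unit and its coding potential (three Pro/Ala codons)."""

    id: str
    sequence: str
    peptide: str = ""

    def __post_init__(self):
        if len(self.sequence) != UNIT_LENGTH:
            raise LocusError(f"unit {self.id!r}: sequence must be 9 bp, got {len(self.sequence)}")
        translated = str(Seq(self.sequence).translate())
        if not self.peptide:
            object.__setattr__(self, "peptide", translated)
        elif self.peptide != translated:
            raise LocusError(
                f"unit {self.id!r}: declared peptide {self.peptide!r} != translation {translated!r}"
            )
        if set(self.peptide) - {"P", "A"}:
            raise LocusError(f"unit {self.id!r}: peptide {self.peptide!r} is not all Pro/Ala")


@dataclass(frozen=True)
class RepeatAllele:
    """An ordered unit composition, named like '3a' (length prefix, frequency suffix)."""

    name: str
    units: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "units", tuple(self.units))
        prefix = "".join(c for c in self.name if c.isdigit())
        if prefix and int(prefix) != self.n_units:
            raise LocusError(
                f"allele {self.name!r}: numeric prefix disagrees with {self.n_units} units"
            )

    @property
    def n_units(self) -> int:
        return len(self.units)


@dataclass(frozen=True)
class FlankingVariant:
    """A flanking SNP or 1-bp indel at a 1-based offset in the 6a reference frame.

    ``alt == ""`` encodes a 1-bp deletion of the reference base at ``offset``;
    ``ref == ""`` encodes a 1-bp insertion immediately after ``offset``.
    """

    id: str
    offset: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.ref == self.alt:
            raise LocusError(f"variant {self.id!r}: ref == alt")
        if self.kind == "snp":
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise LocusError(f"variant {self.id!r}: SNP alleles must be single bases")
        elif len(self.ref) + len(self.alt) != 1:
            raise LocusError(f"variant {self.id!r}: only 1-bp indels are supported")

    @property
    def kind(self) -> str:
        if self.ref and self.alt:
            return "snp"
        return "del" if self.alt == "" else "ins"


@dataclass(frozen=True)
class Haplotype:
    """A phased chromosome: one repeat allele plus an allele at every flanking variant."""

    repeat_allele: str
    variant_alleles: Mapping[str, str]
    name: str | None = None

    def __post_init__(self):
        bad = {v for v in self.variant_alleles.values()} - {"ref", "alt"}
        if bad:
            raise LocusError(f"haplotype: variant alleles must be 'ref'/'alt', got {bad}")
        object.__setattr__(self, "variant_alleles", dict(self.variant_alleles))

    def key(self) -> tuple:
        """Hashable identity used for counting/phasing (ignores the display name)."""
        return (self.repeat_allele, tuple(sorted(self.variant_alleles.items())))


@dataclass(frozen=True)
class LocusModel:
    left_flank: str
    right_flank: str
    unit_alphabet: tuple[RepeatUnit, ...]
    catalogue: tuple[RepeatAllele, ...]
    variants: tuple[FlankingVariant, ...]
    strand_note: str = "MSH3 coding strand; DHFR is transcribed from the opposite strand"
    locus_id: str = "MSH3_DHFR_repeat"

    def __post_init__(self):
        object.__setattr__(self, "unit_alphabet", tuple(self.unit_alphabet))
        object.__setattr__(self, "catalogue", tuple(self.catalogue))
        object.__setattr__(self, "variants", tuple(self.variants))
        units = self.units_by_id()
        for allele in self.catalogue:
            missing = set(allele.units) - set(units)
            if missing:
                raise LocusError(f"allele {allele.name!r} uses unknown units {sorted(missing)}")
        ref_len = len(self.left_flank) + UNIT_LENGTH * REFERENCE_UNIT_COUNT + len(self.right_flank)
        lo, hi = self.repeat_interval()
        for v in self.variants:
            if not (1 <= v.offset <= ref_len):
                raise LocusError(f"variant {v.id!r}: offset {v.offset} outside amplicon")
            if lo <= v.offset <= hi:
                raise LocusError(f"variant {v.id!r}: offset {v.offset} inside the repeat")
            if v.ref:
                base = self._reference_base(v.offset)
                if base != v.ref:
                    raise LocusError(
                        f"variant {v.id!r}: reference base at {v.offset} is {base!r}, not {v.ref!r}"
                    )
        if len({v.id for v in self.variants}) != len(self.variants):
            raise LocusError("duplicate variant ids")

    # -- lookups ---------------------------------------------------------

    def units_by_id(self) -> dict[str, RepeatUnit]:
        return {u.id: u for u in self.unit_alphabet}

    def allele(self, name: str) -> RepeatAllele:
        for a in self.catalogue:
            if a.name == name:
                return a
        raise LocusError(f"unknown repeat allele {name!r}")

    def variant(self, vid: str) -> FlankingVariant:
        for v in self.variants:
            if v.id == vid:
                return v
        raise LocusError(f"unknown flanking variant {vid!r}")

    def repeat_interval(self, n_units: int = REFERENCE_UNIT_COUNT) -> tuple[int, int]:
        """1-based inclusive span of the repeat in the rendering of an n-unit allele."""
        start = len(self.left_flank) + 1
        return start, start + UNIT_LENGTH * n_units - 1

    def map_offset(self, offset: int, n_units: int) -> int:
        """Map a 6a-frame offset onto the rendering of an allele with n_units units."""
        _, ref_end = self.repeat_interval()
        if offset > ref_end:
            return offset + UNIT_LENGTH * (n_units - REFERENCE_UNIT_COUNT)
        return offset

    def all_ref_haplotype(self, allele_name: str) -> Haplotype:
        return Haplotype(allele_name, {v.id: "ref" for v in self.variants})

    def _reference_base(self, offset: int) -> str:
        ref = render_allele_sequence(self, self.all_ref_haplotype(self._six_unit_name()))
        return ref[offset - 1]

    def _six_unit_name(self) -> str:
        for a in self.catalogue:
            if a.n_units == REFERENCE_UNIT_COUNT:
                return a.name
        raise LocusError("catalogue has no six-unit allele to define the reference frame")


# -- operations -----------------------------------------------------------


def render_allele_sequence(locus: LocusModel, hap: Haplotype) -> str:
    """Render the full amplicon sequence of one haplotype.

    Left flank + concatenated 9-bp units + right flank, with the haplotype's
    flanking-variant substitutions/indels applied at offsets re-mapped for the
    allele's repeat length. Deterministic.
    """
    allele = locus.allele(hap.repeat_allele)
    units = locus.units_by_id()
    seq = locus.left_flank + "".join(units[u].sequence for u in allele.units) + locus.right_flank
    edits = []
    for v in locus.variants:
        state = hap.variant_alleles.get(v.id)
        if state is None:
            raise LocusError(f"haplotype missing an allele for variant {v.id!r}")
        if state == "alt":
            edits.append((locus.map_offset(v.offset, allele.n_units), v))
    # apply right-to-left so earlier offsets stay valid
    for offset, v in sorted(edits, reverse=True):
        i = offset - 1
        if v.kind == "snp":
            seq = seq[:i] + v.alt + seq[i + 1 :]
        elif v.kind == "del":
            seq = seq[:i] + seq[i + 1 :]
        else:  # insertion after `offset`
            seq = seq[: i + 1] + v.alt + seq[i + 1 :]
    return seq


def translate_repeat(locus: LocusModel, allele: RepeatAllele | str) -> str:
    """Peptide encoded by the repeat of one allele (3 residues per unit, all Pro/Ala)."""
    if isinstance(allele, str):
        allele = locus.allele(allele)
    units = locus.units_by_id()
    missing = set(allele.units) - set(units)
    if missing:
        raise LocusError(f"allele {allele.name!r} uses unknown units {sorted(missing)}")
    return "".join(units[u].peptide for u in allele.units)


def name_alleles(
    catalogue: Iterable[RepeatAllele], freqs: Mapping[str, float]
) -> tuple[RepeatAllele, ...]:
    """Assign names: repeat-length prefix, then a/b/c... in descending frequency.

    '3a' is the most common three-unit allele. Ties are broken lexicographically
    by the comma-joined unit-id string, which also makes the operation
    idempotent and invariant to the input order.
    """
    catalogue = list(catalogue)
    for a in catalogue:
        if a.name not in freqs:
            raise LocusError(f"no frequency supplied for allele {a.name!r}")
    renamed = []
    by_length: dict[int, list[RepeatAllele]] = {}
    for a in catalogue:
        by_length.setdefault(a.n_units, []).append(a)
    for n, group in by_length.items():
        group.sort(key=lambda a: (-freqs[a.name], ",".join(a.units)))
        if len(group) > len(string.ascii_lowercase):
            raise LocusError(f"more than 26 alleles of length {n}")
        for suffix, a in zip(string.ascii_lowercase, group):
            renamed.append(replace(a, name=f"{n}{suffix}"))
    renamed.sort(key=lambda a: (a.n_units, a.name))
    return tuple(renamed)


# -- JSON schema -----------------------------------------------------------


def locus_to_dict(locus: LocusModel) -> dict:
    return {
        "locus_id": locus.locus_id,
        "strand_note": locus.strand_note,
        "left_flank": locus.left_flank,
        "right_flank": locus.right_flank,
        "units": [
            {"id": u.id, "sequence": u.sequence, "peptide": u.peptide} for u in locus.unit_alphabet
        ],
        "catalogue": [{"name": a.name, "units": list(a.units)} for a in locus.catalogue],
        "variants": [
            {"id": v.id, "offset": v.offset, "ref": v.ref, "alt": v.alt} for v in locus.variants
        ],
    }


def locus_from_dict(d: dict) -> LocusModel:
    return LocusModel(
        left_flank=d["left_flank"],
        right_flank=d["right_flank"],
        unit_alphabet=tuple(
            RepeatUnit(u["id"], u["sequence"], u.get("peptide", "")) for u in d["units"]
        ),
        catalogue=tuple(RepeatAllele(a["name"], tuple(a["units"])) for a in d["catalogue"]),
        variants=tuple(
            FlankingVariant(v["id"], v["offset"], v["ref"], v["alt"]) for v in d["variants"]
        ),
        strand_note=d.get("strand_note", ""),
        locus_id=d.get("locus_id", "locus"),
    )


def write_locus_json(locus: LocusModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(locus_to_dict(locus), indent=2) + "\n")


def read_locus_json(path: str | Path) -> LocusModel:
    return locus_from_dict(json.loads(Path(path).read_text()))


def export_reference_bank(locus: LocusModel, path: str | Path) -> None:
    """Write one FASTA record per catalogue allele (all-ref rendering, id = allele name)."""
    records = [
        SeqRecord(
            Seq(render_allele_sequence(locus, locus.all_ref_haplotype(a.name))),
            id=a.name,
            description=f"{locus.locus_id} {a.n_units}x9bp",
        )
        for a in locus.catalogue
    ]
    SeqIO.write(records, str(path), "fasta")


def reference_bank(locus: LocusModel) -> dict[str, str]:
    """All-ref renderings of every catalogue allele, keyed by allele name."""
    return {
        a.name: render_allele_sequence(locus, locus.all_ref_haplotype(a.name))
        for a in locus.catalogue
    }


# -- default synthetic locus ----------------------------------------------

#: Five 9-bp units, codons drawn from {CCA,CCT,CCG,GCA,GCT,GCG}, pairwise
#: distinguishable at >=1 position. U1 is the reference unit (6 x U1 = the 6a
#: reference allele). U2 differs from U1 at a single base (position 7), which
#: is what makes the 3a-vs-6a misalignment manifest as an apparent SNP.
DEFAULT_UNITS = (
    RepeatUnit("U1", "CCACCGCCT"),  # Pro-Pro-Pro (reference unit)
    RepeatUnit("U2", "CCACCGGCT"),  # Pro-Pro-Ala
    RepeatUnit("U3", "GCACCGCCT"),  # Ala-Pro-Pro
    RepeatUnit("U4", "CCTCCGCCT"),  # Pro-Pro-Pro (synonymous DNA variant of U1)
    RepeatUnit("U5", "GCAGCGGCT"),  # Ala-Ala-Ala
)

#: Sixteen alleles spanning 3-9 units, with the four common alleles of both
#: disease cohorts (3a, 6a, 7a, 8a) present.
DEFAULT_CATALOGUE = (
    RepeatAllele("3a", ("U1", "U2", "U1")),
    RepeatAllele("3b", ("U1", "U1", "U1")),
    RepeatAllele("4a", ("U1", "U2", "U1", "U1")),
    RepeatAllele("4b", ("U1", "U1", "U1", "U1")),
    RepeatAllele("5a", ("U1", "U2", "U1", "U1", "U1")),
    RepeatAllele("5b", ("U1", "U3", "U1", "U1", "U1")),
    RepeatAllele("6a", ("U1",) * 6),
    RepeatAllele("6b", ("U1", "U2", "U1", "U1", "U1", "U1")),
    RepeatAllele("6c", ("U1", "U4", "U1", "U1", "U1", "U1")),
    RepeatAllele("7a", ("U1",) * 7),
    RepeatAllele("7b", ("U1", "U2") + ("U1",) * 5),
    RepeatAllele("7c", ("U1", "U5") + ("U1",) * 5),
    RepeatAllele("8a", ("U1",) * 8),
    RepeatAllele("8b", ("U1", "U2") + ("U1",) * 6),
    RepeatAllele("9a", ("U1",) * 9),
    RepeatAllele("9b", ("U1", "U3") + ("U1",) * 7),
)

_FLANK_SEED = 58314  # fixed: the default locus is one object, not a random family
_FLANK_LEN = 250


def _draw_flanks(rng: np.random.Generator) -> tuple[str, str]:
    bases = np.array(list("ACGT"))
    left = "".join(rng.choice(bases, _FLANK_LEN))
    right = "".join(rng.choice(bases, _FLANK_LEN))
    return left, right


def _locally_distinct(seq: str, i: int) -> bool:
    """True if seq[i] differs from both neighbours (keeps 1-bp indels unambiguous)."""
    return 0 < i < len(seq) - 1 and seq[i] != seq[i - 1] and seq[i] != seq[i + 1]


def _pick_offset(seq: str, target0: int) -> int:
    for i in range(target0, len(seq) - 1):
        if _locally_distinct(seq, i):
            return i
    raise LocusError("no locally distinct position found for a default variant")


_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}


def default_locus() -> LocusModel:
    """The shipped synthetic default locus.

    Three SNPs 5' of the repeat (labels borrowed from the variants reported in
    complete LD with the 3a allele), three SNPs and a 1-bp deletion 3' of it.
    Offsets are deterministic functions of the seeded flank sequences.
    """
    rng = np.random.default_rng(_FLANK_SEED)
    left, right = _draw_flanks(rng)
    repeat_len = UNIT_LENGTH * REFERENCE_UNIT_COUNT
    variants = []
    for vid, target0 in (("rs151182735", 39), ("rs10168", 94), ("rs2250063", 149)):
        i = _pick_offset(left, target0)
        variants.append(FlankingVariant(vid, i + 1, left[i], _TRANSVERSION[left[i]]))
    right_start = _FLANK_LEN + repeat_len  # 0-based offset of right flank in the 6a frame
    for vid, target0 in (("rs1105524", 34), ("rs1650697", 94), ("rs1677658", 154)):
        i = _pick_offset(right, target0)
        variants.append(FlankingVariant(vid, right_start + i + 1, right[i], _TRANSVERSION[right[i]]))
    i = _pick_offset(right, 194)
    variants.append(FlankingVariant("msh3_1bp_del", right_start + i + 1, right[i], ""))
    return LocusModel(
        left_flank=left,
        right_flank=right,
        unit_alphabet=DEFAULT_UNITS,
        catalogue=DEFAULT_CATALOGUE,
        variants=tuple(variants),
    )
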