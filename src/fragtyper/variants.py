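"""Mutation parsing, allele resolution, and normalization.

Small variants arrive in many shapes: VCF rows, TSV tables, plain
``chr:pos:ref:alt`` strings, one- or zero-based coordinates, with or without
the VCF anchor base, with deletions written as ``alt="-"`` and insertions as
``ref="-"``. Indels additionally admit many equivalent (pos, ref, alt)
triples inside repeat tracts. Everything downstream (window construction,
CIGAR evidence matching, reporting) assumes one canonical representation:
1-based, anchored, parsimonious, left-aligned — the convention produced by
``bcftools norm`` for biallelic small variants. This module converts any
supported input into that canonical :class:`Mutation`.

The normalization algorithm is the standard left-align-and-trim fixed point:
repeatedly trim a shared terminal base (extending left with the preceding
reference base whenever an allele would become empty), then trim shared
leading bases while both alleles keep length >= 2.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .errors import (
    ComplexVariantError,
    ParseError,
    ReferenceMismatchError,
    UnrepresentableVariantError,
)
from .reference import as_reference

_ALLELE_RE = re.compile(r"^[ACGTN]+$")
_MISSING_ALLELES = {"", "-", "."}

ONE_BASED = "one_based"
ZERO_BASED = "zero_based"


class MutationType(str, enum.Enum):
    SNV = "SNV"
    MNV = "MNV"
    INS = "INS"
    DEL = "DEL"
    COMPLEX = "COMPLEX"


@dataclass(frozen=True)
class RawVariant:
    """A variant as supplied by the user, before any harmonization."""

    chrom: str
    pos: int
    ref: str
    alt: str
    source_format: str = "colon_string"  # vcf | tsv | colon_string
    coordinate_base: str = ONE_BASED

    def __post_init__(self):
        if not self.chrom:
            raise ParseError("empty chromosome name")
        if self.pos < 0:
            raise ParseError(f"negative position {self.pos}")


@dataclass(frozen=True)
class Mutation:
    """A small variant in canonical VCF-style representation.

    ``pos`` is the 1-based position of the first REF base. For indels the
    first base of REF and ALT is the shared anchor base.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    mtype: MutationType
    normalized: bool = False

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def end(self) -> int:
        """1-based position of the last REF base."""
        return self.pos + len(self.ref) - 1

    @property
    def indel_length(self) -> int:
        """Net length change (positive for insertions)."""
        return len(self.alt) - len(self.ref)

    def __str__(self) -> str:
        return self.id


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def parse_variants(
    source,
    format_hint: str | None = None,
    coordinate_base: str = ONE_BASED,
) -> list[RawVariant]:
    """Parse mutations from a VCF/TSV file, a list of colon strings, or a
    single colon string.

    Order is preserved; multi-allelic VCF rows are split into one
    :class:`RawVariant` per ALT allele. VCF input is 1-based by standard
    regardless of ``coordinate_base``.
    """
    if coordinate_base not in (ONE_BASED, ZERO_BASED):
        raise ParseError(f"unknown coordinate_base {coordinate_base!r}")
    if isinstance(source, (list, tuple)):
        if not source:
            raise ParseError("empty input: no mutations provided")
        return [_parse_colon_string(s, coordinate_base) for s in source]
    path = Path(str(source))
    fmt = format_hint or _sniff_format(path)
    if fmt == "vcf":
        return _parse_vcf(path)
    if fmt == "tsv":
        return _parse_tsv(path, coordinate_base)
    if fmt == "colon_string":
        return [_parse_colon_string(str(source), coordinate_base)]
    raise ParseError(f"unknown mutation format {fmt!r}")


def _sniff_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".vcf", ".vcf.gz", ".bcf")):
        return "vcf"
    if path.exists():
        return "tsv"
    if str(path).count(":") >= 3:
        return "colon_string"
    raise ParseError(f"cannot read mutations from {path}: file not found")


def _parse_colon_string(s: str, coordinate_base: str) -> RawVariant:
    parts = s.strip().split(":")
    if len(parts) != 4:
        raise ParseError(
            f"malformed mutation string {s!r}: expected 4 colon-separated "
            f"fields chrom:pos:ref:alt, got {len(parts)}"
        )
    chrom, pos_s, ref, alt = parts
    try:
        pos = int(pos_s)
    except ValueError as e:
        raise ParseError(f"malformed mutation string {s!r}: position {pos_s!r} "
                         "is not an integer") from e
    return RawVariant(chrom, pos, ref, alt, "colon_string", coordinate_base)


def _parse_vcf(path: Path) -> list[RawVariant]:
    out: list[RawVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                out.append(RawVariant(rec.chrom, rec.pos, rec.ref or "", alt,
                                      "vcf", ONE_BASED))
    if not out:
        raise ParseError(f"empty input: no variant records in {path}")
    return out


def _parse_tsv(path: Path, coordinate_base: str) -> list[RawVariant]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError as e:
        raise ParseError(f"empty input: {path}") from e
    required = ["chrom", "pos", "ref", "alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(
            f"TSV {path} is missing required columns {missing}; found header: "
            f"{list(df.columns)}"
        )
    if df.empty:
        raise ParseError(f"empty input: no rows in {path}")
    out = []
    for _, row in df.iterrows():
        try:
            pos = int(row["pos"])
        except (TypeError, ValueError) as e:
            raise ParseError(f"non-integer position {row['pos']!r} in {path}") from e
        out.append(RawVariant(str(row["chrom"]), pos,
                              _na_to_empty(row["ref"]), _na_to_empty(row["alt"]),
                              "tsv", coordinate_base))
    return out


def _na_to_empty(x) -> str:
    return "" if x is None or (isinstance(x, float) and pd.isna(x)) else str(x)


# ---------------------------------------------------------------------------
# allele resolution
# ---------------------------------------------------------------------------

def resolve_alleles(v: RawVariant, reference) -> Mutation:
    """Convert a raw variant to anchored VCF representation (not yet
    normalized).

    Missing alleles ("-", ".", "") are resolved by prepending the reference
    base immediately left of the event and decrementing ``pos``; an anchorless
    insertion at ``pos`` is taken to insert immediately *before* ``pos``.
    Zero-based positions are shifted to one-based. The REF allele is checked
    against the FASTA.
    """
    reference = as_reference(reference)
    pos = v.pos + 1 if v.coordinate_base == ZERO_BASED else v.pos
    ref = _clean_allele(v.ref)
    alt = _clean_allele(v.alt)
    if not ref and not alt:
        raise ParseError(f"variant {v.chrom}:{v.pos} has neither REF nor ALT")
    for name, allele in (("REF", ref), ("ALT", alt)):
        if allele and not _ALLELE_RE.match(allele):
            raise ComplexVariantError(
                f"{name} allele {allele!r} of {v.chrom}:{v.pos} contains "
                "characters outside ACGTN (symbolic and breakend ALTs are "
                "not supported)"
            )
    if pos < 1:
        raise ParseError(f"position {pos} < 1 for {v.chrom}")
    if ref:
        observed = reference.fetch(v.chrom, pos, pos + len(ref) - 1)
        if observed != ref:
            raise ReferenceMismatchError(
                f"REF allele {ref!r} at {v.chrom}:{pos} contradicts the "
                f"reference FASTA ({observed!r})"
            )
    if not ref or not alt:
        if pos == 1:
            raise UnrepresentableVariantError(
                f"anchorless variant at {v.chrom}:1 cannot be anchored: no "
                "reference base to the left"
            )
        anchor = reference.fetch(v.chrom, pos - 1, pos - 1)
        ref = anchor + ref
        alt = anchor + alt
        pos -= 1
    if ref == alt:
        raise ParseError(f"REF equals ALT ({ref!r}) at {v.chrom}:{pos}")
    return Mutation(v.chrom, pos, ref, alt, _classify(ref, alt), normalized=False)


def _clean_allele(a: str) -> str:
    a = (a or "").strip().upper()
    return "" if a in _MISSING_ALLELES else a


def _classify(ref: str, alt: str) -> MutationType:
    if len(ref) == len(alt):
        return MutationType.SNV if len(ref) == 1 else MutationType.MNV
    return MutationType.INS if len(alt) > len(ref) else MutationType.DEL


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(m: Mutation, reference) -> Mutation:
    """Left-align and trim ``m`` to its canonical parsimonious representation.

    Idempotent. If left-shifting would run off the contig start, shifting
    stops at position 1 and the result is still marked normalized. Variants
    that remain length-changing block substitutions after trimming are
    rejected as COMPLEX.
    """
    if m.normalized:
        return m
    reference = as_reference(reference)
    pos, ref, alt = m.pos, m.ref, m.alt

    while True:
        if ref and alt and ref[-1] == alt[-1]:
            last = ref[-1]
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 1:
                    # cannot extend left of the contig: undo and stop
                    ref, alt = ref + last, alt + last
                    break
                prev = reference.fetch(m.chrom, pos - 1, pos - 1)
                ref, alt = prev + ref, prev + alt
                pos -= 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1

    mtype = _classify(ref, alt)
    if mtype in (MutationType.INS, MutationType.DEL):
        if min(len(ref), len(alt)) != 1 or ref[0] != alt[0]:
            raise ComplexVariantError(
                f"{m.chrom}:{pos}:{ref}:{alt} is a length-changing block "
                "substitution (COMPLEX); only SNV/MNV and simple indels are "
                "supported"
            )
    return Mutation(m.chrom, pos, ref, alt, mtype, normalized=True)


def resolve_and_normalize(raw: Iterable[RawVariant], reference) -> list[Mutation]:
    """Convenience: resolve then normalize a batch, preserving order."""
    reference = as_reference(reference)
    return [normalize(resolve_alleles(v, reference), reference) for v in raw]


def apply_mutation(contig_seq: str, m: Mutation) -> str:
    """Apply ``m`` to a full contig sequence (1-based Mutation coordinates)."""
    i = m.pos - 1
    if contig_seq[i : i + len(m.ref)] != m.ref:
        raise ReferenceMismatchError(
            f"cannot apply {m}: sequence has "
            f"{contig_seq[i:i + len(m.ref)]!r} at {m.pos}"
        )
    return contig_seq[:i] + m.alt + contig_seq[i + len(m.ref):]
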