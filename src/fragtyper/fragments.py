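"""Read selection, pairing into fragments, and CIGAR walking.

A cfDNA *fragment* is the original molecule, observed as a paired-end
template. This module fetches BAM reads around a mutation, applies the
configured flag/quality filters, reconstructs one :class:`Fragment` per
template, and provides the shared per-base alignment walk
(:func:`alignment_profile`) used by both feature extraction and genotyping.

All coordinates exposed here are 1-based fully closed; BAM's 0-based
half-open coordinates are converted at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pysam

from ._instrument import CIGAR_OPS
from .errors import ContigNotFoundError, MalformedRecordError, MissingIndexError
from .variants import Mutation

# CIGAR op classes (SAM spec)
QUERY_OPS = frozenset("MIS=X")
REF_OPS = frozenset("MDN=X")
_PYSAM_OPS = "MIDNSHP=X"


@dataclass(frozen=True)
class AlignedRead:
    """One BAM alignment, in 1-based closed reference coordinates.

    ``ref_end`` is the last reference base consumed by the alignment
    (M/D/N/=/X ops); soft clips extend beyond [ref_start, ref_end] but do not
    move it.
    """

    qname: str
    flag: int
    chrom: str
    ref_start: int
    mapq: int
    cigar: tuple[tuple[str, int], ...]
    seq: str
    baseq: Optional[tuple[int, ...]]
    is_reverse: bool
    is_read1: bool
    tlen: int = 0

    def __post_init__(self):
        qlen = sum(l for op, l in self.cigar if op in QUERY_OPS)
        if self.seq and qlen != len(self.seq):
            raise MalformedRecordError(
                f"read {self.qname}: CIGAR consumes {qlen} query bases but "
                f"SEQ has {len(self.seq)}"
            )

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(l for op, l in self.cigar if op in REF_OPS) - 1

    @property
    def leading_softclip(self) -> int:
        for op, l in self.cigar:
            if op == "H":
                continue
            return l if op == "S" else 0
        return 0

    @property
    def trailing_softclip(self) -> int:
        for op, l in reversed(self.cigar):
            if op == "H":
                continue
            return l if op == "S" else 0
        return 0

    @property
    def cigarstring(self) -> str:
        return "".join(f"{l}{op}" for op, l in self.cigar)

    @classmethod
    def from_pysam(cls, seg: pysam.AlignedSegment) -> "AlignedRead":
        if seg.cigartuples is None:
            raise MalformedRecordError(f"read {seg.query_name}: missing CIGAR")
        cigar = tuple((_PYSAM_OPS[op], l) for op, l in seg.cigartuples)
        quals = seg.query_qualities
        return cls(
            qname=seg.query_name,
            flag=seg.flag,
            chrom=seg.reference_name,
            ref_start=seg.reference_start + 1,
            mapq=seg.mapping_quality,
            cigar=cigar,
            seq=seg.query_sequence or "",
            baseq=tuple(quals) if quals is not None else None,
            is_reverse=seg.is_reverse,
            is_read1=seg.is_read1,
            tlen=seg.template_length,
        )


@dataclass(frozen=True)
class IndelEvent:
    """An I/D/N CIGAR event. ``anchor`` is the 1-based reference position of
    the base immediately preceding the event (the VCF anchor)."""

    op: str  # I, D or N
    anchor: int
    length: int
    seq: str = ""  # inserted bases, for I

    @property
    def ref_span(self) -> tuple[int, int]:
        """Reference interval consumed (empty for insertions)."""
        if self.op == "I":
            return (self.anchor + 1, self.anchor)
        return (self.anchor + 1, self.anchor + self.length)


@dataclass
class Fragment:
    """A sequenced template: one or two primary alignments sharing a qname."""

    fragment_id: str
    left_read: AlignedRead
    right_read: Optional[AlignedRead]
    outer_start: int
    outer_end: int
    proper_pair: bool
    flags: set = field(default_factory=set)

    @property
    def reads(self) -> list[AlignedRead]:
        return [r for r in (self.left_read, self.right_read) if r is not None]

    @property
    def is_paired(self) -> bool:
        return self.right_read is not None

    @classmethod
    def from_reads(cls, a: AlignedRead, b: Optional[AlignedRead] = None,
                   flags: Iterable[str] = ()) -> "Fragment":
        flags = set(flags)
        if b is None:
            return cls(a.qname, a, None, a.ref_start, a.ref_end,
                       bool(a.flag & 0x2), flags)
        # left read = smaller aligned start; stable tie-break on read1 first
        if (b.ref_start, b.is_reverse) < (a.ref_start, a.is_reverse):
            a, b = b, a
        if a.is_reverse == b.is_reverse:
            flags.add("same_orientation_pair")
        elif a.is_reverse and not b.is_reverse:
            flags.add("outward_facing_pair")
        return cls(
            a.qname, a, b,
            min(a.ref_start, b.ref_start), max(a.ref_end, b.ref_end),
            bool(a.flag & 0x2), flags,
        )


@dataclass
class SelectionConfig:
    """Filters applied before pairing reads into fragments.

    Defaults are permissive: unmapped, secondary, supplementary, QC-fail and
    duplicate reads are dropped; no MAPQ floor; proper pairing not required.
    ``pair_gap_bp`` widens the index query so that pairs whose reads flank the
    mutation window without covering it are still recovered (fragment-level
    overlap uses the outer span of the pair).
    """

    window_bp: int = 600
    min_mapq: int = 0
    drop_duplicates: bool = True
    drop_secondary: bool = True
    drop_supplementary: bool = True
    drop_qcfail: bool = True
    require_proper_pair: bool = False
    required_flags: int = 0
    forbidden_flags: int = 0
    pair_gap_bp: int = 1000

    def __post_init__(self):
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")


def passes_filters(seg: pysam.AlignedSegment, cfg: SelectionConfig) -> bool:
    if seg.is_unmapped:
        return False
    if cfg.drop_secondary and seg.is_secondary:
        return False
    if cfg.drop_supplementary and seg.is_supplementary:
        return False
    if cfg.drop_duplicates and seg.is_duplicate:
        return False
    if cfg.drop_qcfail and seg.is_qcfail:
        return False
    if seg.mapping_quality < cfg.min_mapq:
        return False
    if cfg.required_flags and (seg.flag & cfg.required_flags) != cfg.required_flags:
        return False
    if cfg.forbidden_flags and (seg.flag & cfg.forbidden_flags):
        return False
    return True


def mutation_window(m: Mutation, cfg: SelectionConfig) -> tuple[int, int]:
    """The 1-based closed selection window around a mutation."""
    return (max(1, m.pos - cfg.window_bp),
            m.pos + len(m.ref) - 1 + cfg.window_bp)


def select_fragments(bam, m: Mutation, cfg: SelectionConfig | None = None
                     ) -> list[Fragment]:
    """Select fragments whose outer span intersects the mutation window.

    ``bam`` may be a path or an open :class:`pysam.AlignmentFile`. Reads
    failing the configured filters are removed before pairing; templates with
    a missing/unmapped/other-contig mate are kept as single-read fragments
    with an explanatory flag. Output order is deterministic:
    (outer_start, fragment_id).
    """
    cfg = cfg or SelectionConfig()
    own = isinstance(bam, (str, Path))
    af = pysam.AlignmentFile(str(bam)) if own else bam
    try:
        if not af.has_index():
            raise MissingIndexError(
                f"BAM {af.filename.decode() if af.filename else ''} has no "
                "index; create one with 'samtools index'"
            )
        if m.chrom not in af.references:
            raise ContigNotFoundError(
                f"contig {m.chrom!r} absent from BAM header; header contigs: "
                f"{', '.join(af.references)}"
            )
        win_lo, win_hi = mutation_window(m, cfg)
        fetch_lo = max(0, win_lo - 1 - cfg.pair_gap_bp)
        fetch_hi = win_hi + cfg.pair_gap_bp

        groups: dict[str, list[pysam.AlignedSegment]] = {}
        for seg in af.fetch(m.chrom, fetch_lo, fetch_hi):
            if not passes_filters(seg, cfg):
                continue
            groups.setdefault(seg.query_name, []).append(seg)

        fragments = []
        for qname, segs in groups.items():
            segs.sort(key=lambda s: (s.reference_start, s.is_read2))
            flags: set[str] = set()
            if len(segs) > 2:
                flags.add("extra_alignments")
                segs = segs[:2]
            if len(segs) == 1:
                s = segs[0]
                if s.is_paired:
                    if s.mate_is_unmapped:
                        flags.add("mate_unmapped")
                    elif s.next_reference_id != s.reference_id:
                        flags.add("mate_other_contig")
                    else:
                        flags.add("mate_missing")
                frag = Fragment.from_reads(AlignedRead.from_pysam(s), None, flags)
            else:
                frag = Fragment.from_reads(AlignedRead.from_pysam(segs[0]),
                                           AlignedRead.from_pysam(segs[1]), flags)
            if frag.outer_end < win_lo or frag.outer_start > win_hi:
                continue
            if cfg.require_proper_pair and not frag.proper_pair:
                continue
            fragments.append(frag)
        fragments.sort(key=lambda f: (f.outer_start, f.fragment_id))
        return fragments
    finally:
        if own:
            af.close()


def alignment_profile(r: AlignedRead) -> list[tuple[Optional[int], Optional[int], str]]:
    """Per-base correspondence map of an alignment.

    Returns one tuple ``(ref_pos, query_index, op)`` per consumed base:
    M/=/X emit both coordinates, I/S emit only the query index, D/N only the
    reference position; H/P emit nothing. Both coordinate streams are
    strictly increasing.
    """
    out: list[tuple[Optional[int], Optional[int], str]] = []
    ref = r.ref_start
    q = 0
    for op, length in r.cigar:
        if op in ("M", "=", "X"):
            for i in range(length):
                out.append((ref + i, q + i, op))
            ref += length
            q += length
        elif op in ("I", "S"):
            for i in range(length):
                out.append((None, q + i, op))
            q += length
        elif op in ("D", "N"):
            for i in range(length):
                out.append((ref + i, None, op))
            ref += length
        elif op in ("H", "P"):
            continue
        else:
            raise MalformedRecordError(f"read {r.qname}: unknown CIGAR op {op!r}")
    if r.seq and q != len(r.seq):
        raise MalformedRecordError(
            f"read {r.qname}: CIGAR consumes {q} query bases, SEQ has {len(r.seq)}"
        )
    CIGAR_OPS.add(len(out))
    return out


def indel_events(r: AlignedRead) -> list[IndelEvent]:
    """I/D/N events of a read with their VCF-style anchors."""
    events = []
    ref = r.ref_start
    q = 0
    for op, length in r.cigar:
        if op in ("M", "=", "X"):
            ref += length
            q += length
        elif op == "I":
            events.append(IndelEvent("I", ref - 1, length, r.seq[q:q + length]))
            q += length
        elif op == "S":
            q += length
        elif op in ("D", "N"):
            events.append(IndelEvent(op, ref - 1, length))
            ref += length
    return events
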