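"""Fragmentomic feature extraction.

The central quantity is the indel-aware fragment size: the physical length
of the cfDNA molecule, rather than the SAM TLEN field, which is the
reference span between the outermost aligned ends and is therefore blind to
insertions, deletions and soft-clipped bases. A deletion inside the
template inflates TLEN by the deletion length; an insertion deflates it;
soft clips at the outer ends hide real molecule bases (or adapter
read-through, depending on origin — hence the policy switch).

    size = (outer_end - outer_start + 1) + inserted_bp - deleted_bp
           [+ outer soft-clipped bp if keep_outer_softclips]

Indel events are collected from both mates' CIGARs; an event that both
mates could observe (it lies inside both aligned spans) is counted once.
If the mates disagree inside that shared region, the higher-MAPQ read wins
(tie: left read) and the fragment is flagged ``size_discordant_mates``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .fragments import AlignedRead, Fragment, IndelEvent, indel_events
from .reference import as_reference

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SizePolicy:
    """How to treat soft clips and reference skips in the size computation.

    keep_outer_softclips: count soft-clipped bases at the fragment's
        outermost ends as molecule bases (appropriate when clipping reflects
        genuine unaligned molecule sequence). Set False to treat them as
        technical artifacts such as adapter read-through.
    count_N_as_deletion: subtract N (reference skip) ops from the size like
        deletions; cfDNA data should not contain them, so their presence is
        flagged either way.
    """

    keep_outer_softclips: bool = True
    count_N_as_deletion: bool = True


@dataclass
class FragmentFeatures:
    """Per-fragment fragmentomic features (see module docstring for the size
    formula). ``size_bp`` and ``inner_distance_bp`` are None for single-read
    or non-convergent fragments; motifs are None near contig edges."""

    size_bp: Optional[int]
    tlen_abs: Optional[int]
    inner_distance_bp: Optional[int]
    motif5: Optional[str]
    motif3: Optional[str]
    motif3_top: Optional[str]
    outer_start: int
    outer_end: int
    softclip5_out: int
    softclip3_out: int
    softclip_inner: int
    n_insertions_bp: int
    n_deletions_bp: int
    flags: set = field(default_factory=set)


@dataclass
class SizeResult:
    size_bp: Optional[int]
    n_insertions_bp: int
    n_deletions_bp: int
    flags: set


def _observable_by(e: IndelEvent, read: AlignedRead) -> bool:
    """Could ``read`` report this event in its own CIGAR?

    A deletion/skip needs aligned flanking bases on both sides
    (anchor and anchor+length+1); an insertion needs anchor and anchor+1.
    """
    if e.op == "I":
        return read.ref_start <= e.anchor and read.ref_end >= e.anchor + 1
    return read.ref_start <= e.anchor and read.ref_end >= e.anchor + e.length + 1


def _event_key(e: IndelEvent):
    return (e.op, e.anchor, e.length, e.seq)


def fragment_size(f: Fragment, policy: SizePolicy | None = None) -> SizeResult:
    """Indel-aware fragment size with mate deduplication.

    Requires a convergent (forward/reverse) pair; single-read and
    non-convergent fragments get ``size_bp=None`` with a flag.
    """
    policy = policy or SizePolicy()
    flags: set[str] = set()
    if f.right_read is None:
        return SizeResult(None, 0, 0, {"single_read_no_size"})
    left, right = f.left_read, f.right_read
    if left.is_reverse or not right.is_reverse:
        return SizeResult(None, 0, 0, {"non_convergent_pair"})

    ev_left = indel_events(left)
    ev_right = indel_events(right)
    solo = [e for e in ev_left if not _observable_by(e, right)]
    solo += [e for e in ev_right if not _observable_by(e, left)]
    shared_left = [e for e in ev_left if _observable_by(e, right)]
    shared_right = [e for e in ev_right if _observable_by(e, left)]
    if sorted(map(_event_key, shared_left)) == sorted(map(_event_key, shared_right)):
        shared = shared_left
    else:
        flags.add("size_discordant_mates")
        winner = left if left.mapq >= right.mapq else right
        shared = shared_left if winner is left else shared_right
    events = solo + shared

    n_ins = sum(e.length for e in events if e.op == "I")
    n_del = sum(e.length for e in events if e.op == "D")
    n_skip = sum(e.length for e in events if e.op == "N")
    if n_skip:
        flags.add("refskip_in_cigar")
        if policy.count_N_as_deletion:
            n_del += n_skip

    span = f.outer_end - f.outer_start + 1
    size = span + n_ins - n_del
    if policy.keep_outer_softclips:
        s5, s3, _ = softclip_counts(f)
        size += s5 + s3
    return SizeResult(size, n_ins, n_del, flags)


def inner_distance(f: Fragment) -> Optional[int]:
    """Reference-space gap between the mates' inner aligned ends; negative
    when the aligned spans overlap. None for single-read fragments."""
    if f.right_read is None:
        return None
    return f.right_read.ref_start - f.left_read.ref_end - 1


def softclip_counts(f: Fragment) -> tuple[int, int, int]:
    """(softclip5_out, softclip3_out, softclip_inner).

    A clip is *outer* when it extends past the fragment's outermost aligned
    boundary: a leading clip of a read starting at ``outer_start`` (5') or a
    trailing clip of a read ending at ``outer_end`` (3'). When both mates
    carry an outer clip at the same boundary (fully overlapping reads) the
    larger one is counted — they represent the same molecule bases. All
    remaining soft clips are inner.
    """
    reads = f.reads
    total = sum(r.leading_softclip + r.trailing_softclip for r in reads)
    s5 = max((r.leading_softclip for r in reads if r.ref_start == f.outer_start),
             default=0)
    s3 = max((r.trailing_softclip for r in reads if r.ref_end == f.outer_end),
             default=0)
    return s5, s3, total - s5 - s3


def end_motifs(f: Fragment, reference, k: int = 5
               ) -> tuple[Optional[str], Optional[str], Optional[str], set]:
    """Reference-derived k-mer end motifs, both reading 5'->3' into the
    fragment from their respective ends.

    Returns (motif5, motif3, motif3_top, flags). ``motif3`` is the reverse
    complement of the top-strand bases at the 3' end (the convention of the
    end-motif literature); ``motif3_top`` is the raw top-strand string so
    either convention is recoverable. Motifs anchor at the *aligned* outer
    ends; fragments with outer soft clips are flagged because the true
    molecule end may extend past the anchor. A motif is None when the
    fragment end lies within k-1 bases of a contig edge.
    """
    if k < 1:
        raise ValueError("motif length k must be >= 1")
    reference = as_reference(reference)
    flags: set[str] = set()
    chrom = f.left_read.chrom
    clen = reference.contig_length(chrom)
    motif5 = motif3 = motif3_top = None
    if f.outer_start + k - 1 <= clen:
        motif5 = reference.fetch(chrom, f.outer_start, f.outer_start + k - 1)
    else:
        flags.add("motif5_at_contig_edge")
    if f.outer_end - k + 1 >= 1:
        motif3_top = reference.fetch(chrom, f.outer_end - k + 1, f.outer_end)
        motif3 = revcomp(motif3_top)
    else:
        flags.add("motif3_at_contig_edge")
    s5, s3, _ = softclip_counts(f)
    if s5 or s3:
        flags.add("outer_softclip_motif_anchor")
    return motif5, motif3, motif3_top, flags


def compute_features(f: Fragment, reference, policy: SizePolicy | None = None,
                     k: int = 5) -> FragmentFeatures:
    """All fragmentomic features for one fragment."""
    policy = policy or SizePolicy()
    size = fragment_size(f, policy)
    s5, s3, s_in = softclip_counts(f)
    motif5, motif3, motif3_top, motif_flags = end_motifs(f, reference, k)
    tlen_abs = None
    if f.is_paired:
        tlen_abs = abs(f.left_read.tlen) or abs(f.right_read.tlen) or None
    return FragmentFeatures(
        size_bp=size.size_bp,
        tlen_abs=tlen_abs,
        inner_distance_bp=inner_distance(f),
        motif5=motif5,
        motif3=motif3,
        motif3_top=motif3_top,
        outer_start=f.outer_start,
        outer_end=f.outer_end,
        softclip5_out=s5,
        softclip3_out=s3,
        softclip_inner=s_in,
        n_insertions_bp=size.n_insertions_bp,
        n_deletions_bp=size.n_deletions_bp,
        flags=size.flags | motif_flags | set(f.flags),
    )
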