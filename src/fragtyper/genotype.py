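"""Read- and fragment-level mutation genotyping.

Each read overlapping a mutation is compared, over a type-specific reference
window, against the wild-type haplotype (the reference sequence) and the
mutated haplotype (the reference with the mutation applied). For SNVs/MNVs
the window is the substituted bases, with a one-base flanking extension used
only to flag potentially larger events. For indels the window runs from the
anchor base through the indel context and any perfect repeats of the
indel unit, plus one terminating base — wide enough that the two haplotypes
remain distinguishable in repetitive contexts.

Indel genotyping additionally scans the CIGAR: an I/D operation of the
expected type and length whose left-aligned anchor matches the mutation is
direct evidence, and takes precedence over the sequence comparison (a
conflict is kept as MUT but flagged).

Read calls aggregate to a fragment call: concordant mates decide directly,
an ambiguous mate defers to a definite one, and irreconcilable definite
conflicts are non-informative. Fragment-level VAF is mutated fragments over
informative (MUT+WT+OTH) fragments; genotypes are aggregated per fragment,
never per read, so overlapping mates are not double counted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import ComplexVariantError
from .fragments import AlignedRead, Fragment, alignment_profile, indel_events
from .reference import as_reference
from .variants import Mutation, MutationType, normalize

INDEL_TYPES = (MutationType.INS, MutationType.DEL)


class ReadStatus(str, enum.Enum):
    WT = "WT"
    MUT = "MUT"
    OTH = "OTH"
    AMBIGUOUS = "AMBIGUOUS"


class FragmentStatus(str, enum.Enum):
    MUT = "MUT"
    WT = "WT"
    OTH = "OTH"
    NI = "NI"


class Resolution(str, enum.Enum):
    CONCORDANT = "concordant"
    SINGLE_READ = "single_read"
    FLAG_RESOLVED = "flag_resolved"
    DISCREPANT = "discrepant"
    AMBIGUOUS = "ambiguous"


class CigarEvidence(str, enum.Enum):
    NONE = "none"
    EXPECTED_INDEL = "expected_indel"
    OTHER_INDEL = "other_indel"


@dataclass
class WindowSpec:
    """Reference window and the two haplotypes compared against reads."""

    chrom: str
    w_start: int
    w_end: int
    ref_hap: str
    alt_hap: str
    mutation: Mutation
    extended_interval: Optional[tuple[int, int]] = None  # SNV/MNV only
    flank_bases: dict = field(default_factory=dict)  # ref base at w_start-1 / w_end+1
    edge_truncated: bool = False


@dataclass
class ReadCall:
    status: ReadStatus
    flags: set = field(default_factory=set)
    cigar_evidence: CigarEvidence = CigarEvidence.NONE


@dataclass
class FragmentCall:
    status: FragmentStatus
    resolution: Resolution


@dataclass
class VafSummary:
    n_mut: int
    n_wt: int
    n_oth: int
    n_ni: int
    vaf: Optional[float]

    @property
    def n_informative(self) -> int:
        return self.n_mut + self.n_wt + self.n_oth

    @property
    def n_fragments(self) -> int:
        return self.n_informative + self.n_ni


# ---------------------------------------------------------------------------
# window construction
# ---------------------------------------------------------------------------

def build_window(m: Mutation, reference) -> WindowSpec:
    """Construct the comparison window for a normalized mutation.

    SNV/MNV: window = the substituted bases; extended interval = +-1 base.
    INS/DEL: window = anchor base through all perfect reference copies of the
    indel unit plus one terminating base, so a read matching the truncated
    wild-type haplotype cannot also match the mutated one.
    """
    if not m.normalized:
        m = normalize(m, reference)
    reference = as_reference(reference)
    clen = reference.contig_length(m.chrom)
    edge_truncated = False
    w_start = m.pos
    if m.mtype in INDEL_TYPES:
        unit = m.alt[1:] if m.mtype is MutationType.INS else m.ref[1:]
        scan = m.pos + 1
        while scan + len(unit) - 1 <= clen and \
                reference.fetch(m.chrom, scan, scan + len(unit) - 1) == unit:
            scan += len(unit)
        w_end = scan  # one terminating base past the repeat tract
        if w_end > clen:
            w_end = clen
            edge_truncated = True
        extended = None
    elif m.mtype in (MutationType.SNV, MutationType.MNV):
        w_end = m.pos + len(m.ref) - 1
        extended = (max(1, m.pos - 1), min(clen, w_end + 1))
    else:
        raise ComplexVariantError(f"cannot genotype COMPLEX variant {m}")

    ref_hap = reference.fetch(m.chrom, w_start, w_end)
    tail_start = m.pos + len(m.ref)
    tail = reference.fetch(m.chrom, tail_start, w_end) if tail_start <= w_end else ""
    alt_hap = m.alt + tail
    flank_bases = {}
    if extended is not None:
        for p in extended:
            if p < w_start or p > w_end:
                flank_bases[p] = reference.fetch(m.chrom, p, p)
    return WindowSpec(m.chrom, w_start, w_end, ref_hap, alt_hap, m,
                      extended, flank_bases, edge_truncated)


# ---------------------------------------------------------------------------
# read-level comparison
# ---------------------------------------------------------------------------

@dataclass
class WindowObservation:
    observed: str
    truncated_left: bool
    truncated_right: bool
    covered: bool
    quals: tuple[int, ...]


def read_window_sequence(r: AlignedRead, w: WindowSpec) -> WindowObservation:
    """The read's query bases over the window's reference interval.

    Inserted bases anchored strictly inside the interval appear in query
    order; soft-clipped bases never do. Truncation booleans record whether
    the read's aligned span starts after ``w_start`` or ends before
    ``w_end``.
    """
    covered = r.ref_start <= w.w_end and r.ref_end >= w.w_start
    truncated_left = r.ref_start > w.w_start
    truncated_right = r.ref_end < w.w_end
    if not covered:
        return WindowObservation("", truncated_left, truncated_right, False, ())
    bases: list[str] = []
    quals: list[int] = []
    last_ref = r.ref_start - 1
    for ref_pos, q_idx, op in alignment_profile(r):
        if op in ("M", "=", "X"):
            if w.w_start <= ref_pos <= w.w_end:
                bases.append(r.seq[q_idx])
                if r.baseq is not None:
                    quals.append(r.baseq[q_idx])
            last_ref = ref_pos
        elif op == "I":
            # anchored inside the window (not at its right edge)
            if w.w_start <= last_ref <= w.w_end - 1:
                bases.append(r.seq[q_idx])
                if r.baseq is not None:
                    quals.append(r.baseq[q_idx])
        elif op in ("D", "N"):
            last_ref = ref_pos
        # S consumes query but is never part of the observation
    return WindowObservation("".join(bases), truncated_left, truncated_right,
                             True, tuple(quals))


def cigar_indel_scan(r: AlignedRead, m: Mutation, reference,
                     w: Optional[WindowSpec] = None
                     ) -> tuple[CigarEvidence, bool]:
    """Scan the read CIGAR for evidence of the expected indel.

    Each I/D event is left-aligned against the reference (the same
    normalization applied to input mutations) before comparison, so
    right-shifted CIGAR encodings in repeat tracts still match. Returns
    (evidence, other_indel_present); evidence is EXPECTED_INDEL when an
    event of the expected type and length normalizes to the mutation's
    anchor, OTHER_INDEL when only different events overlap the window.
    """
    if m.mtype not in INDEL_TYPES:
        raise ValueError("cigar_indel_scan applies to indels only")
    reference = as_reference(reference)
    if w is None:
        w = build_window(m, reference)
    expected_op = "I" if m.mtype is MutationType.INS else "D"
    expected_len = abs(m.indel_length)
    found_expected = False
    found_other = False
    for e in indel_events(r):
        if e.anchor < 1:
            found_other = True
            continue
        is_expected = False
        if e.op == expected_op and e.length == expected_len:
            anchor_base = reference.fetch(m.chrom, e.anchor, e.anchor)
            if e.op == "D":
                ref_a = reference.fetch(m.chrom, e.anchor, e.anchor + e.length)
                alt_a = anchor_base
            else:
                ref_a = anchor_base
                alt_a = anchor_base + e.seq
            try:
                nm = normalize(
                    Mutation(m.chrom, e.anchor, ref_a, alt_a,
                             MutationType.DEL if e.op == "D" else MutationType.INS),
                    reference)
            except ComplexVariantError:
                nm = None
            if nm is not None and nm.pos == m.pos and \
                    abs(nm.indel_length) == expected_len and nm.mtype == m.mtype:
                is_expected = True
        if is_expected:
            found_expected = True
        else:
            span_lo, span_hi = e.ref_span
            if e.op == "I":
                overlaps = w.w_start <= e.anchor <= w.w_end
            else:
                overlaps = span_lo <= w.w_end and span_hi >= w.w_start
            if overlaps:
                found_other = True
    if found_expected:
        return CigarEvidence.EXPECTED_INDEL, found_other
    if found_other:
        return CigarEvidence.OTHER_INDEL, True
    return CigarEvidence.NONE, False


def _sequence_verdict(obs: WindowObservation, w: WindowSpec) -> ReadStatus:
    """Compare the observed window bases against both haplotypes.

    A read that fully spans the window must equal one haplotype exactly.
    A truncated read anchors at the side it does cover: its observation is
    compared against same-length prefixes (right truncation) or suffixes
    (left truncation) of both haplotypes; when those coincide — e.g. a read
    ending inside a homopolymer run — the read cannot distinguish the
    alleles and is AMBIGUOUS. A read truncated on both sides has no anchor
    at all and is always AMBIGUOUS.
    """
    n = len(obs.observed)
    if obs.truncated_left and obs.truncated_right:
        return ReadStatus.AMBIGUOUS
    if not obs.truncated_left and not obs.truncated_right:
        cand_ref, cand_alt = w.ref_hap, w.alt_hap
    elif obs.truncated_right:
        cand_ref, cand_alt = w.ref_hap[:n], w.alt_hap[:n]
    else:
        cand_ref = w.ref_hap[-n:] if n else ""
        cand_alt = w.alt_hap[-n:] if n else ""
    match_ref = obs.observed == cand_ref
    match_alt = obs.observed == cand_alt
    if match_ref and match_alt:
        return ReadStatus.AMBIGUOUS
    if match_alt:
        return ReadStatus.MUT
    if match_ref:
        return ReadStatus.WT
    return ReadStatus.OTH


def genotype_read(r: AlignedRead, m: Mutation, w: WindowSpec,
                  min_baseq: int = 0, reference=None) -> ReadCall:
    """Assign WT/MUT/OTH/AMBIGUOUS to one read.

    SNV/MNV use the sequence comparison alone; indels give precedence to
    CIGAR evidence (``reference`` is then required to left-align observed
    events). ``min_baseq`` > 0 turns any window base below the threshold
    into AMBIGUOUS with flag low_baseq.
    """
    flags: set[str] = set()
    obs = read_window_sequence(r, w)
    if not obs.covered:
        return ReadCall(ReadStatus.AMBIGUOUS, {"no_coverage"})

    truncated = obs.truncated_left or obs.truncated_right
    if truncated or w.edge_truncated:
        flags.add("truncated_window")
    seq_status = _sequence_verdict(obs, w)

    if min_baseq > 0 and obs.quals and min(obs.quals) < min_baseq:
        flags.add("low_baseq")
        seq_status = ReadStatus.AMBIGUOUS

    evidence = CigarEvidence.NONE
    if m.mtype in INDEL_TYPES:
        if reference is None:
            raise ValueError("indel genotyping requires the reference")
        evidence, has_other = cigar_indel_scan(r, m, reference, w)
        if evidence is CigarEvidence.EXPECTED_INDEL:
            if seq_status not in (ReadStatus.MUT, ReadStatus.AMBIGUOUS):
                flags.add("cigar_seq_discordant")
            status = ReadStatus.MUT
        else:
            status = seq_status
        if has_other:
            flags.add("other_indel_present")
    else:
        status = seq_status
        # flanking check: MUT/WT on the core window but mismatching reference
        # context suggests a larger event; flags only, never the status
        if status in (ReadStatus.MUT, ReadStatus.WT) and w.extended_interval:
            if _flank_mismatch(r, w):
                flags.add("possible_larger_event")
    return ReadCall(status, flags, evidence)


def _flank_mismatch(r: AlignedRead, w: WindowSpec) -> bool:
    if not w.flank_bases:
        return False
    base_at = {ref_pos: r.seq[q_idx]
               for ref_pos, q_idx, op in alignment_profile(r)
               if op in ("M", "=", "X")}
    for p, ref_base in w.flank_bases.items():
        read_base = base_at.get(p)
        if read_base is not None and read_base != ref_base:
            return True
    return False


# ---------------------------------------------------------------------------
# fragment aggregation
# ---------------------------------------------------------------------------

def genotype_fragment(call1: ReadCall, call2: Optional[ReadCall] = None
                      ) -> FragmentCall:
    """Aggregate read calls into a fragment call.

    A mate that is absent or has no coverage leaves a single informative
    read; equal statuses are concordant; one ambiguous mate defers to the
    definite one; two unequal definite statuses are discrepant. Discrepant
    and ambiguous fragments are non-informative.
    """
    if call2 is not None and "no_coverage" in call2.flags:
        call2 = None
    if call1 is not None and "no_coverage" in call1.flags:
        call1, call2 = call2, None
    if call1 is None:
        return FragmentCall(FragmentStatus.NI, Resolution.AMBIGUOUS)
    s1 = call1.status
    if call2 is None:
        if s1 is ReadStatus.AMBIGUOUS:
            return FragmentCall(FragmentStatus.NI, Resolution.AMBIGUOUS)
        return FragmentCall(FragmentStatus(s1.value), Resolution.SINGLE_READ)
    s2 = call2.status
    if s1 == s2:
        if s1 is ReadStatus.AMBIGUOUS:
            return FragmentCall(FragmentStatus.NI, Resolution.AMBIGUOUS)
        return FragmentCall(FragmentStatus(s1.value), Resolution.CONCORDANT)
    if s1 is ReadStatus.AMBIGUOUS or s2 is ReadStatus.AMBIGUOUS:
        definite = s2 if s1 is ReadStatus.AMBIGUOUS else s1
        return FragmentCall(FragmentStatus(definite.value), Resolution.FLAG_RESOLVED)
    return FragmentCall(FragmentStatus.NI, Resolution.DISCREPANT)


def genotype_fragment_reads(f: Fragment, m: Mutation, w: WindowSpec,
                            min_baseq: int = 0, reference=None
                            ) -> tuple[FragmentCall, list[ReadCall]]:
    """Genotype every read of a fragment and aggregate."""
    calls = [genotype_read(r, m, w, min_baseq, reference) for r in f.reads]
    if len(calls) == 1:
        frag_call = genotype_fragment(calls[0], None)
    else:
        frag_call = genotype_fragment(calls[0], calls[1])
    return frag_call, calls


def locus_vaf(calls: Iterable[FragmentCall]) -> VafSummary:
    """Fragment-level VAF: MUT / (MUT + WT + OTH); NI excluded."""
    n = {s: 0 for s in FragmentStatus}
    for c in calls:
        n[c.status] += 1
    denom = n[FragmentStatus.MUT] + n[FragmentStatus.WT] + n[FragmentStatus.OTH]
    vaf = n[FragmentStatus.MUT] / denom if denom else None
    return VafSummary(n[FragmentStatus.MUT], n[FragmentStatus.WT],
                      n[FragmentStatus.OTH], n[FragmentStatus.NI], vaf)
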