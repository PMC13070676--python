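"""Shared fixtures: a small deterministic reference with planted contexts,
plus helpers to build reads and BAMs by hand."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from fragtyper.fragments import AlignedRead, Fragment
from fragtyper.reference import InMemoryReference, ReferenceAccessor

# planted contexts (1-based start -> sequence) on chr1
CHR1_PLANTS = {
    97: "GCGAT",       # 100='A', 101='T': anchorless-deletion example
    199: "CATGC",      # 200..202='ATG' flanked by C: MNV trim example
    300: "TCAAAAG",    # A-homopolymer run 302..305 for left-alignment
    400: "CCTGAACGTA",  # motif example: motif5 at 400 reads CCTGA
    500: "ATGTGC",     # TG-repeat insertion context (anchor at 500)
    601: "CAAAAG",     # deletion window example: C A A A A G
}

CHRX_PLANTS = {99: "TCAAAG"}  # T C A A A context at 99..104


def _build_contig(length: int, seed: int, plants: dict) -> str:
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), size=length))
    for start, ctx in plants.items():
        seq[start - 1 : start - 1 + len(ctx)] = list(ctx)
    return "".join(seq)


@pytest.fixture(scope="session")
def contigs() -> dict:
    return {
        "chr1": _build_contig(2000, 11, CHR1_PLANTS),
        "chrX": _build_contig(500, 12, CHRX_PLANTS),
    }


@pytest.fixture(scope="session")
def reference(contigs) -> InMemoryReference:
    return InMemoryReference(contigs)


@pytest.fixture(scope="session")
def fasta_path(tmp_path_factory, contigs):
    path = tmp_path_factory.mktemp("ref") / "ref.fa"
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    pysam.faidx(str(path))
    return path


@pytest.fixture()
def fasta_reference(fasta_path) -> ReferenceAccessor:
    return ReferenceAccessor(fasta_path)


def parse_cigar(s: str) -> tuple:
    out = []
    num = ""
    for ch in s:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return tuple(out)


def make_read(chrom="chr1", pos=100, cigar="100M", seq=None, qname="q1",
              mapq=60, is_reverse=False, is_read1=True, flag=None, tlen=0,
              baseq=None, reference=None, inserted="", clipped="") -> AlignedRead:
    """Build an AlignedRead; if ``seq`` is None it is synthesized from the
    reference (M bases), ``inserted`` (I bases, consumed in order) and
    ``clipped`` (S bases, consumed in order)."""
    cig = parse_cigar(cigar)
    if seq is None:
        assert reference is not None, "need reference to synthesize seq"
        parts = []
        ref_pos = pos
        ins = list(inserted)
        clip = list(clipped)
        for op, l in cig:
            if op in "M=X":
                parts.append(reference.fetch(chrom, ref_pos, ref_pos + l - 1))
                ref_pos += l
            elif op == "I":
                parts.append("".join(ins[:l]))
                del ins[:l]
            elif op == "S":
                got = "".join(clip[:l]) if clip else "N" * l
                parts.append(got.ljust(l, "N"))
                del clip[:l]
            elif op in "DN":
                ref_pos += l
        seq = "".join(parts)
    if flag is None:
        flag = 0x1 | 0x2
        if is_reverse:
            flag |= 0x10
        flag |= 0x40 if is_read1 else 0x80
    if baseq is None:
        baseq = tuple([37] * len(seq))
    return AlignedRead(qname=qname, flag=flag, chrom=chrom, ref_start=pos,
                       mapq=mapq, cigar=cig, seq=seq, baseq=tuple(baseq),
                       is_reverse=is_reverse, is_read1=is_read1, tlen=tlen)


def make_pair(chrom, left_pos, left_cigar, right_pos, right_cigar,
              reference=None, qname="q1", left_seq=None, right_seq=None,
              left_mapq=60, right_mapq=60, tlen=None, **kw) -> Fragment:
    r1 = make_read(chrom, left_pos, left_cigar, seq=left_seq, qname=qname,
                   mapq=left_mapq, is_reverse=False, is_read1=True,
                   reference=reference, **kw)
    r2 = make_read(chrom, right_pos, right_cigar, seq=right_seq, qname=qname,
                   mapq=right_mapq, is_reverse=True, is_read1=False,
                   reference=reference, **kw)
    if tlen is None:
        tlen = max(r1.ref_end, r2.ref_end) - min(r1.ref_start, r2.ref_start) + 1
    import dataclasses
    r1 = dataclasses.replace(r1, tlen=tlen)
    r2 = dataclasses.replace(r2, tlen=-tlen)
    return Fragment.from_reads(r1, r2)


def write_bam(path, contigs: dict, records: list, index: bool = True):
    """Write records (dicts with qname/flag/pos/cigar/seq[/mapq/mpos/tlen])
    to a coordinate-sorted BAM."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": n, "LN": ln} for n, ln in contigs.items()]}
    names = list(contigs)
    records = sorted(records, key=lambda r: (names.index(r.get("chrom", names[0])),
                                             r["pos"], r["qname"]))
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec["qname"]
            seg.flag = rec.get("flag", 0)
            seg.reference_id = names.index(rec.get("chrom", names[0]))
            seg.reference_start = rec["pos"] - 1  # dicts use 1-based
            seg.mapping_quality = rec.get("mapq", 60)
            seg.cigarstring = rec["cigar"]
            seg.query_sequence = rec["seq"]
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(rec["seq"]))
            seg.next_reference_id = rec.get("mate_tid", seg.reference_id)
            seg.next_reference_start = rec.get("mpos", rec["pos"]) - 1
            seg.template_length = rec.get("tlen", 0)
            out.write(seg)
    if index:
        pysam.index(str(path))
    return path
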