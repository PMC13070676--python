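"""Synthetic cfDNA data with per-fragment ground truth.

The simulator builds everything by construction rather than by running an
aligner: a random reference contig with planted mutation contexts, molecules
drawn from a bimodal cfDNA size distribution (mononucleosomal ~167 bp plus a
shorter tumor-like component ~145 bp), paired 100 bp reads cut from each
molecule, and CIGAR strings computed from the known edit operations. Mutated
molecules are sampled from the alternate haplotype, so the variant appears in
both SEQ and CIGAR exactly as an aligner would report it (optionally in a
right-shifted, non-left-aligned CIGAR encoding inside repeat tracts).

TLEN is deliberately written as the signed outer reference span — the SAM
convention that is blind to indels — reproducing the discrepancy between
TLEN-based and indel-aware fragment sizes that motivates the package.

Every fragment carries a :class:`TruthRecord` (true molecule length, true
status, soft-clip provenance, injected error positions), making the
simulator the oracle for the feature and genotyping test suites. Soft clips
come in three flavors: none (adapter-trimmed data, the default),
``read_through`` adapter bases appended when the molecule is shorter than
the read (artifacts; not part of the molecule), and ``genuine`` unaligned
molecule bases at the fragment ends (part of the molecule).

With a fixed seed all outputs are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .errors import FragtyperError
from .fragments import AlignedRead, Fragment
from .reference import InMemoryReference
from .variants import (
    Mutation,
    MutationType,
    RawVariant,
    apply_mutation,
    normalize,
    resolve_alleles,
)

_BASES = np.array(list("ACGT"))

READ1_FLAG = 0x1 | 0x2 | 0x20 | 0x40  # paired, proper, mate reverse, first
READ2_FLAG = 0x1 | 0x2 | 0x10 | 0x80  # paired, proper, reverse, second


@dataclass(frozen=True)
class SizeComponent:
    mean: float
    sd: float
    weight: float


DEFAULT_SIZE_MODEL: tuple[SizeComponent, ...] = (
    SizeComponent(167.0, 10.0, 0.8),
    SizeComponent(145.0, 8.0, 0.2),
)


@dataclass
class SoftclipModel:
    """How soft clips are generated.

    label: None (no clips; adapter-trimmed reads), "read_through" (adapter
    bases appended when molecule < read length; artifacts), or "genuine"
    (unaligned molecule bases at the fragment's outer ends).
    """

    label: Optional[str] = None
    prob: float = 1.0
    min_len: int = 1
    max_len: int = 10


@dataclass
class PlantedMutation:
    """A mutation to plant, in anchored 1-based (pos, ref, alt) form, with
    the fraction of molecules drawn from the alternate haplotype."""

    pos: int
    ref: str
    alt: str
    vaf: float
    context: Optional[str] = None       # sequence to plant around the site
    context_start: Optional[int] = None  # 1-based start of `context`

    def __post_init__(self):
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError("vaf must be in [0, 1]")


@dataclass
class SimScenario:
    seed: int = 0
    contig: str = "sim1"
    contig_length: int = 20_000
    mutations: Sequence[PlantedMutation] = ()
    depth: int = 200                  # fragments per locus
    size_model: tuple[SizeComponent, ...] = DEFAULT_SIZE_MODEL
    mut_size_model: Optional[tuple[SizeComponent, ...]] = None
    size_bounds: tuple[int, int] = (60, 500)
    read_length: int = 100
    error_rate: float = 0.0
    softclip: SoftclipModel = field(default_factory=SoftclipModel)
    base_qual: int = 37
    mapq: int = 60
    alt_rep_prob: float = 0.0  # emit right-shifted indel CIGAR encodings


@dataclass
class TruthRecord:
    fragment_id: str
    mutation_id: str
    true_status: str            # MUT or WT at the fragment's own locus
    true_size_bp: int
    clip_label: str             # none | read_through | genuine
    clip5: int
    clip3: int
    tlen: int
    errors: tuple = ()          # (read_no, query_index, ref_pos or -1)


@dataclass
class SimRead:
    pos: int                    # 1-based leftmost aligned position
    cigar: tuple
    seq: str
    flag: int
    tlen: int

    @property
    def ref_end(self) -> int:
        return self.pos + sum(l for op, l in self.cigar if op in "MDN=X") - 1


@dataclass
class SimFragment:
    qname: str
    chrom: str
    reads: list            # [SimRead, SimRead] in (read1, read2) order
    truth: TruthRecord

    def to_fragment(self, base_qual: int = 37, mapq: int = 60) -> Fragment:
        """Materialize as an in-memory Fragment, bypassing BAM I/O."""
        aligned = []
        for i, sr in enumerate(self.reads):
            aligned.append(AlignedRead(
                qname=self.qname, flag=sr.flag, chrom=self.chrom,
                ref_start=sr.pos, mapq=mapq, cigar=sr.cigar, seq=sr.seq,
                baseq=tuple([base_qual] * len(sr.seq)),
                is_reverse=bool(sr.flag & 0x10), is_read1=(i == 0),
                tlen=sr.tlen,
            ))
        return Fragment.from_reads(aligned[0],
                                   aligned[1] if len(aligned) > 1 else None)


@dataclass
class SimResult:
    scenario: SimScenario
    contig: str
    reference_seq: str
    reference: InMemoryReference
    mutations: list          # normalized Mutation per locus
    fragments: list          # SimFragment


@dataclass
class SimOutput:
    fasta: Path
    bam: Path
    truth: Path
    mutations_tsv: Path
    result: SimResult


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

def build_reference(scn: SimScenario, rng: np.random.Generator) -> str:
    seq = list(rng.choice(_BASES, size=scn.contig_length))
    for pm in scn.mutations:
        if pm.context is not None:
            if pm.context_start is None:
                raise FragtyperError("context requires context_start")
            s = pm.context_start - 1
            if s < 0 or s + len(pm.context) > scn.contig_length:
                raise FragtyperError("context exceeds contig bounds")
            seq[s:s + len(pm.context)] = list(pm.context.upper())
    for pm in scn.mutations:
        s = pm.pos - 1
        if s < 1 or s + len(pm.ref) >= scn.contig_length:
            raise FragtyperError(
                f"mutation at {pm.pos} too close to contig bounds")
        seq[s:s + len(pm.ref)] = list(pm.ref.upper())
    out = "".join(seq)
    for pm in scn.mutations:
        if out[pm.pos - 1 : pm.pos - 1 + len(pm.ref)] != pm.ref.upper():
            raise FragtyperError(
                f"mutation context impossible at {pm.pos}: planted mutations "
                "or contexts overlap inconsistently")
    return out


# ---------------------------------------------------------------------------
# fragment construction
# ---------------------------------------------------------------------------

def _draw_size(scn: SimScenario, rng, mutated: bool) -> int:
    model = scn.mut_size_model if (mutated and scn.mut_size_model) else scn.size_model
    weights = np.array([c.weight for c in model], dtype=float)
    weights /= weights.sum()
    c = model[int(rng.choice(len(model), p=weights))]
    lo, hi = scn.size_bounds
    return int(np.clip(round(rng.normal(c.mean, c.sd)), lo, hi))


def _hap_and_refmap(ref_seq: str, m: Optional[Mutation]) -> tuple[str, list]:
    """Alternate-haplotype sequence and a map hap-coordinate -> reference
    position (None for inserted bases). Identity when m is None."""
    if m is None:
        return ref_seq, list(range(1, len(ref_seq) + 1))
    hap = apply_mutation(ref_seq, m)
    len_r, len_a = len(m.ref), len(m.alt)
    pre = list(range(1, m.pos))
    if len_r == len_a:
        mid = list(range(m.pos, m.pos + len_a))
    elif len_a > len_r:          # insertion: anchor maps, inserted bases don't
        mid = [m.pos] + [None] * (len_a - 1)
    else:                        # deletion: only the anchor remains
        mid = [m.pos]
    post = list(range(m.pos + len_r, len(ref_seq) + 1))
    refmap = pre + mid + post
    assert len(refmap) == len(hap)
    return hap, refmap


def _build_read(hap: str, refmap: list, mol_start: int, mol_len: int,
                c5: int, c3: int, rl: int, which: int,
                adapter: bool, rng) -> Optional[SimRead]:
    """Cut one read from the molecule and derive its CIGAR.

    Molecule = hap[mol_start .. mol_start+mol_len-1] (1-based hap coords);
    positions within c5 of the molecule start or c3 of its end are genuine
    unaligned bases (soft-clipped). Read 1 is the molecule prefix, read 2
    the suffix, both of length min(rl, mol_len); when the molecule is
    shorter than the read and ``adapter`` is set, random adapter bases pad
    the read past the molecule end (read-through).
    """
    n = min(rl, mol_len)
    if which == 1:
        hap_positions = range(mol_start, mol_start + n)
    else:
        hap_positions = range(mol_start + mol_len - n, mol_start + mol_len)
    bases = []
    states = []  # "S" | "I" | ("M", ref_pos)
    for x in hap_positions:
        bases.append(hap[x - 1])
        pos_in_mol = x - mol_start + 1
        if pos_in_mol <= c5 or pos_in_mol > mol_len - c3:
            states.append("S")
        else:
            rp = refmap[x - 1]
            states.append("I" if rp is None else ("M", rp))
    if adapter and mol_len < rl:
        pad = ["".join(rng.choice(_BASES, size=rl - mol_len))]
        if which == 1:
            bases.extend(pad[0])
            states.extend(["S"] * (rl - mol_len))
        else:  # read 2 reads through the molecule 5' end: pad on the left
            bases = list(pad[0]) + bases
            states = ["S"] * (rl - mol_len) + states
    # edge insertions are unanchored -> soft clips
    i = 0
    while i < len(states) and states[i] in ("S", "I"):
        states[i] = "S"
        i += 1
    i = len(states) - 1
    while i >= 0 and states[i] in ("S", "I"):
        states[i] = "S"
        i -= 1
    if not any(isinstance(s, tuple) for s in states):
        return None  # no aligned base; caller resamples

    cigar: list[tuple[str, int]] = []

    def emit(op: str, length: int):
        if length <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + length)
        else:
            cigar.append((op, length))

    ref_start = None
    last_ref = None
    for s in states:
        if s == "S":
            emit("S", 1)
        elif s == "I":
            emit("I", 1)
        else:
            rp = s[1]
            if last_ref is not None and rp > last_ref + 1:
                emit("D", rp - last_ref - 1)
            if ref_start is None:
                ref_start = rp
            emit("M", 1)
            last_ref = rp
    flag = READ1_FLAG if which == 1 else READ2_FLAG
    return SimRead(ref_start, tuple(cigar), "".join(bases), flag, 0)


def shift_deletion_right(read: SimRead, ref_seq: str, steps: int = 1
                         ) -> SimRead:
    """Re-encode the first deletion of a CIGAR ``steps`` positions to the
    right when the repeat structure allows — an equivalent, non-left-aligned
    alignment of the same read (what a right-shifting aligner could emit)."""
    cigar = list(read.cigar)
    for _ in range(steps):
        idx = next((i for i, (op, _) in enumerate(cigar) if op == "D"), None)
        if idx is None or idx == 0 or idx == len(cigar) - 1:
            break
        a_op, a_len = cigar[idx - 1]
        b_op, b_len = cigar[idx + 1]
        d_len = cigar[idx][1]
        if a_op != "M" or b_op != "M" or b_len < 2:
            break
        s = read.pos + sum(l for op, l in cigar[:idx] if op in "MDN=X")
        if s + d_len > len(ref_seq) or ref_seq[s - 1] != ref_seq[s + d_len - 1]:
            break
        cigar[idx - 1] = ("M", a_len + 1)
        cigar[idx + 1] = ("M", b_len - 1)
    return dataclasses.replace(read, cigar=tuple(cigar))


def _inject_errors(reads: list, scn: SimScenario, rng) -> list[tuple]:
    if scn.error_rate <= 0:
        return []
    logged = []
    for rno, sr in enumerate(reads, start=1):
        seq = list(sr.seq)
        hits = np.nonzero(rng.random(len(seq)) < scn.error_rate)[0]
        if len(hits) == 0:
            continue
        # query index -> ref pos for logging
        ref_of: dict[int, int] = {}
        q = 0
        rp = sr.pos
        for op, l in sr.cigar:
            if op in "M=X":
                for i in range(l):
                    ref_of[q + i] = rp + i
                q += l
                rp += l
            elif op in "IS":
                q += l
            elif op in "DN":
                rp += l
        for qi in hits:
            old = seq[qi]
            choices = [b for b in "ACGT" if b != old]
            seq[qi] = choices[int(rng.integers(3))]
            logged.append((rno, int(qi), ref_of.get(int(qi), -1)))
        reads[rno - 1] = dataclasses.replace(sr, seq="".join(seq))
    return logged


def simulate_fragments(scn: SimScenario) -> SimResult:
    """Generate all fragments of a scenario in memory (no files)."""
    rng = np.random.default_rng(scn.seed)
    ref_seq = build_reference(scn, rng)
    reference = InMemoryReference({scn.contig: ref_seq})
    mutations = []
    for pm in scn.mutations:
        raw = RawVariant(scn.contig, pm.pos, pm.ref, pm.alt)
        mutations.append(normalize(resolve_alleles(raw, reference), reference))

    fragments: list[SimFragment] = []
    clip_cfg = scn.softclip
    for locus_idx, (pm, m) in enumerate(zip(scn.mutations, mutations)):
        hap_alt, refmap_alt = _hap_and_refmap(ref_seq, m)
        hap_wt, refmap_wt = _hap_and_refmap(ref_seq, None)
        # event footprint on the alternate haplotype: anchor .. one base past
        # the ALT allele; a mutated fragment must have >= 1 read spanning it
        ev_lo, ev_hi = m.pos, m.pos + len(m.alt)
        for j in range(scn.depth):
            mutated = bool(rng.random() < pm.vaf)
            hap, refmap = (hap_alt, refmap_alt) if mutated else (hap_wt, refmap_wt)
            allele_len = len(m.alt) if mutated else len(m.ref)
            frag = None
            for _attempt in range(200):
                L = _draw_size(scn, rng, mutated)
                c5 = c3 = 0
                if clip_cfg.label == "genuine" and rng.random() < clip_cfg.prob:
                    c5 = int(rng.integers(clip_cfg.min_len, clip_cfg.max_len + 1))
                    c3 = int(rng.integers(clip_cfg.min_len, clip_cfg.max_len + 1))
                if L - c5 - c3 < allele_len + 4:
                    continue
                lo = max(1, m.pos + allele_len + 1 + c3 - L)
                hi = min(m.pos - c5, len(hap) - L + 1)
                if hi < lo:
                    continue
                mol_start = int(rng.integers(lo, hi + 1))
                if mutated and m.mtype in (MutationType.INS, MutationType.DEL):
                    # aligned (non-clipped) hap-coordinate span of each read
                    n = min(scn.read_length, L)
                    a1 = (mol_start + c5,
                          min(mol_start + n - 1, mol_start + L - 1 - c3))
                    a2 = (max(mol_start + L - n, mol_start + c5),
                          mol_start + L - 1 - c3)
                    if not any(a[0] <= ev_lo and a[1] >= ev_hi for a in (a1, a2)):
                        continue
                adapter = clip_cfg.label == "read_through"
                r1 = _build_read(hap, refmap, mol_start, L, c5, c3,
                                 scn.read_length, 1, adapter, rng)
                r2 = _build_read(hap, refmap, mol_start, L, c5, c3,
                                 scn.read_length, 2, adapter, rng)
                if r1 is None or r2 is None:
                    continue
                if mutated and scn.alt_rep_prob > 0 and rng.random() < scn.alt_rep_prob:
                    r1 = shift_deletion_right(r1, ref_seq)
                    r2 = shift_deletion_right(r2, ref_seq)
                frag = (L, c5, c3, r1, r2)
                break
            if frag is None:
                raise FragtyperError(
                    f"could not place a fragment at locus {m} "
                    f"(size bounds {scn.size_bounds}, contig too small?)")
            L, c5, c3, r1, r2 = frag
            span = max(r1.ref_end, r2.ref_end) - min(r1.pos, r2.pos) + 1
            sign1 = 1 if r1.pos <= r2.pos else -1
            r1 = dataclasses.replace(r1, tlen=sign1 * span)
            r2 = dataclasses.replace(r2, tlen=-sign1 * span)
            reads = [r1, r2]
            errors = _inject_errors(reads, scn, rng)
            qname = f"frag{locus_idx}_{j:05d}"
            clip_label = "none"
            if c5 or c3:
                clip_label = "genuine"
            elif clip_cfg.label == "read_through" and L < scn.read_length:
                clip_label = "read_through"
            truth = TruthRecord(
                fragment_id=qname, mutation_id=m.id,
                true_status="MUT" if mutated else "WT",
                true_size_bp=L, clip_label=clip_label, clip5=c5, clip3=c3,
                tlen=span, errors=tuple(errors),
            )
            fragments.append(SimFragment(qname, scn.contig, reads, truth))
    return SimResult(scn, scn.contig, ref_seq, reference, mutations, fragments)


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def simulate(scn: SimScenario, out_dir) -> SimOutput:
    """Run the scenario and write reference FASTA (+.fai), coordinate-sorted
    indexed BAM, truth TSV, and a mutations TSV usable as workflow input."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    res = simulate_fragments(scn)

    fasta = out_dir / "reference.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{res.contig}\n")
        for i in range(0, len(res.reference_seq), 60):
            fh.write(res.reference_seq[i:i + 60] + "\n")
    pysam.faidx(str(fasta))

    bam = out_dir / "reads.bam"
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": res.contig, "LN": len(res.reference_seq)}]}
    segments = []
    for sf in res.fragments:
        r1, r2 = sf.reads
        for sr, mate in ((r1, r2), (r2, r1)):
            segments.append((sr.pos - 1, sf.qname, sr, mate))
    segments.sort(key=lambda t: (t[0], t[1], t[2].flag))
    with pysam.AlignmentFile(str(bam), "wb", header=header) as out:
        for pos0, qname, sr, mate in segments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = qname
            seg.flag = sr.flag
            seg.reference_id = 0
            seg.reference_start = pos0
            seg.mapping_quality = res.scenario.mapq
            seg.cigarstring = "".join(f"{l}{op}" for op, l in sr.cigar)
            seg.query_sequence = sr.seq
            seg.query_qualities = pysam.qualitystring_to_array(
                chr(res.scenario.base_qual + 33) * len(sr.seq))
            seg.next_reference_id = 0
            seg.next_reference_start = mate.pos - 1
            seg.template_length = sr.tlen
            out.write(seg)
    pysam.index(str(bam))

    truth = out_dir / "truth.tsv"
    rows = []
    for sf in res.fragments:
        t = sf.truth
        rows.append({
            "fragment_id": t.fragment_id, "mutation_id": t.mutation_id,
            "true_status": t.true_status, "true_size_bp": t.true_size_bp,
            "clip_label": t.clip_label, "clip5": t.clip5, "clip3": t.clip3,
            "tlen": t.tlen,
            "errors": ";".join(f"{r}:{q}:{p}" for r, q, p in t.errors) or ".",
        })
    pd.DataFrame(rows).to_csv(truth, sep="\t", index=False)

    muts = out_dir / "mutations.tsv"
    pd.DataFrame(
        [{"chrom": m.chrom, "pos": m.pos, "ref": m.ref, "alt": m.alt}
         for m in res.mutations]
    ).to_csv(muts, sep="\t", index=False)
    return SimOutput(fasta, bam, truth, muts, res)


# ---------------------------------------------------------------------------
# representation enumeration (normalization oracle)
# ---------------------------------------------------------------------------

def enumerate_equivalent_representations(m: Mutation, reference,
                                         window: int = 25) -> list[RawVariant]:
    """All raw representations denoting the same edited sequence as ``m``.

    Brute force: every candidate (pos, ref, alt) in a window around the site
    is kept iff applying it to the reference yields the same edited sequence
    as applying ``m`` (apply-and-compare). Anchored and anchorless forms and
    both coordinate conventions are emitted. For substitutions only the
    minimal representation exists; for indels every shift position appears.
    """
    from .reference import as_reference

    reference = as_reference(reference)
    clen = reference.contig_length(m.chrom)
    lo = max(1, m.pos - window)
    hi = min(clen, m.pos + len(m.ref) + window)
    seq = reference.fetch(m.chrom, lo, hi)
    p0 = m.pos - lo
    edited = seq[:p0] + m.alt + seq[p0 + len(m.ref):]
    d = len(m.alt) - len(m.ref)

    reps: list[RawVariant] = []
    seen = set()
    max_ref_len = max(len(m.ref), len(m.alt)) + 1
    for q0 in range(len(seq) + 1):
        for lr in range(0, max_ref_len + 1):
            la = lr + d
            if la < 0 or q0 + lr > len(seq):
                continue
            if lr == 0 and la == 0:
                continue
            ref_cand = seq[q0:q0 + lr]
            alt_cand = edited[q0:q0 + la]
            if ref_cand == alt_cand:
                continue
            if seq[:q0] + alt_cand + seq[q0 + lr:] != edited:
                continue
            if d == 0:
                # substitutions: keep only the trimmed minimal form
                if lr > 0 and la > 0 and (ref_cand[0] == alt_cand[0]
                                          or ref_cand[-1] == alt_cand[-1]):
                    continue
            pos1 = lo + q0
            if pos1 == 1 and (lr == 0 or la == 0):
                continue  # anchorless form at the contig start is unrepresentable
            key = (pos1, ref_cand, alt_cand)
            if key in seen:
                continue
            seen.add(key)
            ref_s = ref_cand or "-"
            alt_s = alt_cand or "-"
            reps.append(RawVariant(m.chrom, pos1, ref_s, alt_s,
                                   "colon_string", "one_based"))
            reps.append(RawVariant(m.chrom, pos1 - 1, ref_s, alt_s,
                                   "colon_string", "zero_based"))
    return reps


# ---------------------------------------------------------------------------
# YAML scenarios
# ---------------------------------------------------------------------------

def scenario_from_yaml(path) -> SimScenario:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise FragtyperError(f"scenario file {path} is not a mapping")
    kwargs = dict(raw)
    if "size_model" in kwargs:
        kwargs["size_model"] = tuple(SizeComponent(**c) for c in kwargs["size_model"])
    if kwargs.get("mut_size_model"):
        kwargs["mut_size_model"] = tuple(
            SizeComponent(**c) for c in kwargs["mut_size_model"])
    if "softclip" in kwargs:
        kwargs["softclip"] = SoftclipModel(**kwargs["softclip"])
    if "size_bounds" in kwargs:
        kwargs["size_bounds"] = tuple(kwargs["size_bounds"])
    kwargs["mutations"] = tuple(
        PlantedMutation(**pm) for pm in kwargs.get("mutations", []))
    return SimScenario(**kwargs)
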