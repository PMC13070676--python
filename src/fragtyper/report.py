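"""Workflow orchestration and the per-fragment output table.

:func:`run_workflow` ties the modules together: normalize each input
mutation, select overlapping fragments from the BAM, extract fragmentomic
features, genotype reads and fragments, and assemble one table row per
(fragment x mutation) with a per-locus VAF summary attached as metadata.

The table serializes as TSV with a small ``#``-prefixed metadata header
(per-locus VAF counts and locus status) so that a written table round-trips
losslessly through :func:`read_table`. Missing values are written as "NA";
an empty flag set is written as ".".
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import FragtyperError, ParseError
from .features import SizePolicy, compute_features
from .fragments import SelectionConfig, select_fragments
from .genotype import (
    VafSummary,
    build_window,
    genotype_fragment_reads,
    locus_vaf,
)
from .reference import as_reference
from .variants import Mutation, parse_variants, resolve_and_normalize

logger = logging.getLogger("fragtyper")

#: stable column order of the fragment table
COLUMNS = [
    "mutation_id", "fragment_id", "chrom", "outer_start", "outer_end",
    "size_bp", "tlen_abs", "inner_distance_bp", "motif5", "motif3",
    "motif3_top", "softclip5_out", "softclip3_out", "softclip_inner",
    "n_insertions_bp", "n_deletions_bp", "status", "resolution", "flags",
]

VERBOSE_COLUMNS = [
    "read1_flag", "read1_mapq", "read1_cigar", "read1_status",
    "read1_mean_baseq_window",
    "read2_flag", "read2_mapq", "read2_cigar", "read2_status",
    "read2_mean_baseq_window",
]

_INT_COLS = ["outer_start", "outer_end", "size_bp", "tlen_abs",
             "inner_distance_bp", "softclip5_out", "softclip3_out",
             "softclip_inner", "n_insertions_bp", "n_deletions_bp",
             "read1_flag", "read1_mapq", "read2_flag", "read2_mapq"]


@dataclass
class WorkflowConfig:
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    size_policy: SizePolicy = field(default_factory=SizePolicy)
    motif_k: int = 5
    min_baseq: int = 0
    verbose_reads: bool = False
    threads: int = 1


@dataclass
class FragmentTable:
    """The primary output: one row per (fragment x mutation), plus per-locus
    VAF summaries and status messages."""

    df: pd.DataFrame
    vaf: dict = field(default_factory=dict)           # mutation_id -> VafSummary
    locus_status: dict = field(default_factory=dict)  # mutation_id -> str

    def __len__(self) -> int:
        return len(self.df)

    def write(self, path) -> None:
        write_table(self, path)

    @classmethod
    def read(cls, path) -> "FragmentTable":
        return read_table(path)


def _locus_rows(bam, reference, m: Mutation, cfg: WorkflowConfig):
    """Process one mutation; returns (rows, VafSummary)."""
    window = build_window(m, reference)
    frags = select_fragments(bam, m, cfg.selection)
    rows = []
    calls = []
    for f in frags:
        feats = compute_features(f, reference, cfg.size_policy, cfg.motif_k)
        frag_call, read_calls = genotype_fragment_reads(
            f, m, window, cfg.min_baseq, reference)
        calls.append(frag_call)
        flags = set(feats.flags)
        for rc in read_calls:
            flags |= rc.flags
        row = {
            "mutation_id": m.id,
            "fragment_id": f.fragment_id,
            "chrom": m.chrom,
            "outer_start": feats.outer_start,
            "outer_end": feats.outer_end,
            "size_bp": feats.size_bp,
            "tlen_abs": feats.tlen_abs,
            "inner_distance_bp": feats.inner_distance_bp,
            "motif5": feats.motif5,
            "motif3": feats.motif3,
            "motif3_top": feats.motif3_top,
            "softclip5_out": feats.softclip5_out,
            "softclip3_out": feats.softclip3_out,
            "softclip_inner": feats.softclip_inner,
            "n_insertions_bp": feats.n_insertions_bp,
            "n_deletions_bp": feats.n_deletions_bp,
            "status": frag_call.status.value,
            "resolution": frag_call.resolution.value,
            "flags": ";".join(sorted(flags)) if flags else ".",
        }
        if cfg.verbose_reads:
            for i in (1, 2):
                read = f.reads[i - 1] if len(f.reads) >= i else None
                rc = read_calls[i - 1] if len(read_calls) >= i else None
                row[f"read{i}_flag"] = read.flag if read else None
                row[f"read{i}_mapq"] = read.mapq if read else None
                row[f"read{i}_cigar"] = read.cigarstring if read else None
                row[f"read{i}_status"] = rc.status.value if rc else None
        rows.append(row)
    return rows, locus_vaf(calls)


def run_workflow(bam, mutations, reference, config: WorkflowConfig | None = None
                 ) -> FragmentTable:
    """Run the full pipeline for every mutation.

    ``bam`` is a path to a coordinate-sorted indexed BAM; ``mutations`` a
    VCF/TSV path, list of ``chr:pos:ref:alt`` strings, or list of
    :class:`Mutation`; ``reference`` a FASTA path or accessor. Output
    ordering is deterministic: (mutation input order, outer_start,
    fragment_id), and is independent of ``config.threads``. A failure at one
    locus is recorded in ``locus_status`` and does not abort other loci.
    """
    cfg = config or WorkflowConfig()
    ref = as_reference(reference)
    if isinstance(mutations, (list, tuple)) and mutations and \
            all(isinstance(m, Mutation) for m in mutations):
        muts = [m if m.normalized else _renorm(m, ref) for m in mutations]
    else:
        raw = parse_variants(mutations)
        muts = resolve_and_normalize(raw, ref)
    if not muts:
        raise ParseError("no mutations")

    def task(m: Mutation):
        # each task opens its own file handles when parallel (pysam/pyfaidx
        # handles are not thread-safe)
        local_ref = as_reference(reference) if cfg.threads > 1 and \
            not isinstance(reference, dict) and \
            isinstance(reference, (str, Path)) else ref
        try:
            rows, vaf = _locus_rows(bam, local_ref, m, cfg)
            if not rows:
                logger.warning("no fragments overlap %s", m.id)
            else:
                logger.info("%s: %d fragments, VAF=%s", m.id, len(rows),
                            f"{vaf.vaf:.4f}" if vaf.vaf is not None else "NA")
            return rows, vaf, "ok"
        except FragtyperError as e:
            logger.error("locus %s failed: %s", m.id, e)
            return [], None, f"error: {e}"

    if cfg.threads > 1:
        with ThreadPoolExecutor(max_workers=cfg.threads) as pool:
            results = list(pool.map(task, muts))
    else:
        results = [task(m) for m in muts]

    all_rows = []
    vaf_by_locus = {}
    locus_status = {}
    for m, (rows, vaf, status) in zip(muts, results):
        all_rows.extend(rows)
        if vaf is not None:
            vaf_by_locus[m.id] = vaf
        locus_status[m.id] = status

    columns = COLUMNS + (VERBOSE_COLUMNS if cfg.verbose_reads else [])
    columns = [c for c in columns if not all_rows or c in all_rows[0]
               or c in COLUMNS]
    df = pd.DataFrame(all_rows, columns=columns if all_rows else COLUMNS)
    df = _with_schema_dtypes(df)
    return FragmentTable(df, vaf_by_locus, locus_status)


def _renorm(m: Mutation, ref) -> Mutation:
    from .variants import normalize
    return normalize(m, ref)


def _with_schema_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    for c in df.columns:
        if c in _INT_COLS:
            df[c] = df[c].astype("Int64")
        elif c not in ():
            df[c] = df[c].astype("string")
    return df


# ---------------------------------------------------------------------------
# TSV serialization
# ---------------------------------------------------------------------------

def write_table(t: FragmentTable, path) -> None:
    """Tab-separated, UTF-8, newline-terminated; metadata in '#' comments."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for mid, v in t.vaf.items():
            vaf_s = "NA" if v.vaf is None else repr(v.vaf)
            fh.write(f"#vaf\t{mid}\t{v.n_mut}\t{v.n_wt}\t{v.n_oth}\t{v.n_ni}"
                     f"\t{vaf_s}\n")
        for mid, status in t.locus_status.items():
            fh.write(f"#locus_status\t{mid}\t{status}\n")
        t.df.to_csv(fh, sep="\t", index=False, na_rep="NA",
                    lineterminator="\n")


def read_table(path) -> FragmentTable:
    path = Path(path)
    vaf = {}
    locus_status = {}
    n_meta = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "#vaf":
                _, mid, n_mut, n_wt, n_oth, n_ni, _vaf_s = parts
                n_mut, n_wt, n_oth, n_ni = map(int, (n_mut, n_wt, n_oth, n_ni))
                denom = n_mut + n_wt + n_oth
                vaf[mid] = VafSummary(n_mut, n_wt, n_oth, n_ni,
                                      n_mut / denom if denom else None)
            elif parts[0] == "#locus_status":
                locus_status[parts[1]] = parts[2]
    df = pd.read_csv(path, sep="\t", skiprows=n_meta, na_values=["NA"],
                     keep_default_na=False, dtype="string")
    df = _with_schema_dtypes(df)
    return FragmentTable(df, vaf, locus_status)
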