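"""Reference genome access.

Two interchangeable accessors expose the same minimal interface used across
the package: 1-based fully-closed ``fetch``, ``contig_length`` and membership
testing. :class:`ReferenceAccessor` wraps an indexed FASTA on disk (via
pyfaidx); :class:`InMemoryReference` holds contig strings directly and is used
by the simulator and by tests.
"""

from __future__ import annotations

from pathlib import Path

from pyfaidx import Fasta

from .errors import ContigNotFoundError


class InMemoryReference:
    """Reference backed by a dict of contig name -> sequence string."""

    def __init__(self, contigs: dict[str, str]):
        self._contigs = {name: seq.upper() for name, seq in contigs.items()}

    @property
    def contigs(self) -> list[str]:
        return list(self._contigs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._contigs

    def contig_length(self, chrom: str) -> int:
        self._check(chrom)
        return len(self._contigs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return uppercase bases over the 1-based closed interval [start, end]."""
        self._check(chrom)
        seq = self._contigs[chrom]
        if start < 1 or end > len(seq) or start > end + 1:
            raise ValueError(
                f"interval {chrom}:{start}-{end} out of bounds (contig length {len(seq)})"
            )
        return seq[start - 1 : end]

    def _check(self, chrom: str) -> None:
        if chrom not in self._contigs:
            raise ContigNotFoundError(
                f"contig {chrom!r} not found; available: {', '.join(self._contigs)}"
            )


class ReferenceAccessor:
    """Indexed FASTA accessor with 1-based closed coordinates.

    The .fai index is created on first open if absent (requires write access
    next to the FASTA, as is conventional).
    """

    def __init__(self, fasta: str | Path):
        self.path = Path(fasta)
        self._fasta = Fasta(str(self.path), sequence_always_upper=True, rebuild=True)

    @property
    def contigs(self) -> list[str]:
        return list(self._fasta.keys())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fasta

    def contig_length(self, chrom: str) -> int:
        self._check(chrom)
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        self._check(chrom)
        n = len(self._fasta[chrom])
        if start < 1 or end > n or start > end + 1:
            raise ValueError(
                f"interval {chrom}:{start}-{end} out of bounds (contig length {n})"
            )
        if end < start:
            return ""
        return self._fasta[chrom][start - 1 : end].seq

    def _check(self, chrom: str) -> None:
        if chrom not in self._fasta:
            raise ContigNotFoundError(
                f"contig {chrom!r} not found in {self.path}; "
                f"available: {', '.join(self.contigs)}"
            )

    def close(self) -> None:
        self._fasta.close()


def as_reference(obj) -> "ReferenceAccessor | InMemoryReference":
    """Coerce a path, accessor, or dict into a reference accessor."""
    if isinstance(obj, (ReferenceAccessor, InMemoryReference)):
        return obj
    if isinstance(obj, dict):
        return InMemoryReference(obj)
    return ReferenceAccessor(obj)
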