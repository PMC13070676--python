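"""Lightweight operation counter used to verify linear-time CIGAR handling.

Counts elementary per-base steps taken by CIGAR walks so that tests can
assert runtime scales as O(fragments x read length) without relying on wall
clock.
"""

from __future__ import annotations


class OpCounter:
    __slots__ = ("count",)

    def __init__(self):
        self.count = 0

    def add(self, n: int) -> None:
        self.count += n

    def reset(self) -> None:
        self.count = 0


CIGAR_OPS = OpCounter()
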