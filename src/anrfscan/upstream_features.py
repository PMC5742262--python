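"""Polypurine (PP) block detection upstream of a candidate nested start codon.

A PP block is a maximal uninterrupted run of purines (A/G). Blocks are
reported when the run's last nucleotide lies within a fixed window
upstream of the nested AUG; run lengths are reported in full even when
they exceed the 18-25 nt band observed for the matryoshka signature
(the signature check annotates, rather than caps, long runs).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .seqio import Transcript

_PURINE_RUN = re.compile(r"[AG]+")


@dataclass
class PolypurineBlock:
    """A maximal purine run upstream of an AUG.

    ``start`` is 1-based in transcript coordinates; ``distance_to_aug`` is
    the gap in nt between the block's last nucleotide and the first
    nucleotide of the AUG (0 when adjacent).
    """

    start: int
    length: int
    distance_to_aug: int

    @property
    def end(self) -> int:
        return self.start + self.length - 1


def find_polypurine(
    t: Transcript, anrf_start: int, window: int = 60, min_len: int = 18
) -> list[PolypurineBlock]:
    """Maximal A/G runs of length >= ``min_len`` ending within ``window`` nt
    upstream of the AUG at ``anrf_start`` (1-based), sorted by start."""
    if window < min_len:
        raise ValueError(f"window ({window}) must be >= min_len ({min_len})")
    lo = anrf_start - window  # 1-based bound on the run's last nt
    hi = anrf_start - 1
    blocks = []
    for m in _PURINE_RUN.finditer(t.seq):
        run_start = m.start() + 1
        run_end = m.end()  # 1-based inclusive
        if run_end - run_start + 1 < min_len:
            continue
        if lo <= run_end <= hi:
            blocks.append(
                PolypurineBlock(
                    start=run_start,
                    length=run_end - run_start + 1,
                    distance_to_aug=anrf_start - run_end - 1,
                )
            )
    return blocks
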