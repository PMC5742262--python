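"""Translatability scoring of candidate sORFs.

A candidate is called translatable when the mean per-hexamer
log-likelihood ratio (natural log) of its in-frame hexamers under a
coding vs. background hexamer model meets a threshold. In-frame hexamers
are dicodons read at step 3 from the first nt of the AUG, stop codon
excluded; background hexamers are counted at step 1 over noncoding
training sequences. This is a deliberately simple, fully documented
CDS-likeness measure in the family of hexamer scores used by coding
potential tools; it is the one stage of the pipeline whose absolute
calls depend on the training sets supplied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping

from .seqio import OrfRecord

log = logging.getLogger(__name__)

ALPHABET = "ACGT"
N_HEXAMERS = 4 ** 6
ALL_HEXAMERS = ["".join(p) for p in product(ALPHABET, repeat=6)]


class CodingError(ValueError):
    pass


@dataclass
class HexamerModel:
    """Smoothed in-frame (coding) and all-frame (background) hexamer frequencies."""

    coding_freqs: Mapping[str, float]
    background_freqs: Mapping[str, float]
    pseudocount: float
    trained_on: str = ""

    def llr(self, hexamer: str) -> float:
        return math.log(self.coding_freqs[hexamer] / self.background_freqs[hexamer])


@dataclass
class CodingScore:
    llr: float
    threshold: float
    translatable: bool


def _count(seqs: Iterable[str], step: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in seqs:
        s = seq.upper().replace("U", "T")
        for i in range(0, len(s) - 5, step):
            hexamer = s[i : i + 6]
            if all(c in ALPHABET for c in hexamer):
                counts[hexamer] = counts.get(hexamer, 0) + 1
    return counts


def _smooth(counts: dict[str, int], pseudocount: float) -> dict[str, float]:
    total = sum(counts.values()) + pseudocount * N_HEXAMERS
    return {h: (counts.get(h, 0) + pseudocount) / total for h in ALL_HEXAMERS}


def train_hexamer_model(
    coding_seqs: list[str],
    noncoding_seqs: list[str],
    pseudocount: float = 1.0,
    trained_on: str = "user-supplied",
) -> HexamerModel:
    """Train the hexamer model from coding and noncoding nucleotide sequences.

    Coding sequences are assumed CDS-aligned (frame 0 at their first nt) and
    contribute in-frame (step 3) hexamers; noncoding sequences contribute
    hexamers at every offset (step 1). Counts are add-``pseudocount``
    smoothed over all 4096 hexamers. Sequences shorter than 6 nt are skipped
    with a warning.
    """
    if not coding_seqs or not noncoding_seqs:
        raise CodingError("both training sets must be non-empty")
    if pseudocount <= 0:
        raise CodingError("pseudocount must be positive")
    for label, seqs in (("coding", coding_seqs), ("noncoding", noncoding_seqs)):
        short = sum(1 for s in seqs if len(s) < 6)
        if short:
            log.warning("%d %s training sequence(s) shorter than 6 nt skipped", short, label)
    return HexamerModel(
        coding_freqs=_smooth(_count(coding_seqs, step=3), pseudocount),
        background_freqs=_smooth(_count(noncoding_seqs, step=1), pseudocount),
        pseudocount=pseudocount,
        trained_on=trained_on,
    )


def score_sequence(cds: str, model: HexamerModel) -> float:
    """Mean in-frame hexamer LLR of a stop-free coding region."""
    hexamers = [cds[i : i + 6] for i in range(0, len(cds) - 5, 3)]
    hexamers = [h for h in hexamers if all(c in ALPHABET for c in h)]
    if len(hexamers) < 2:
        raise CodingError("coding region yields fewer than 2 in-frame hexamers")
    return sum(model.llr(h) for h in hexamers) / len(hexamers)


def coding_score(orf: OrfRecord, model: HexamerModel, threshold: float = 0.0) -> CodingScore:
    """Score an ORF's translatability.

    Requires the ORF to span at least 12 nt (>= 2 in-frame hexamers after
    excluding the stop codon).
    """
    if orf.end - orf.start + 1 < 12:
        raise CodingError(
            f"ORF {orf.transcript_id}:{orf.start}-{orf.end} too short to score (<12 nt)"
        )
    cds = orf.seq[:-3]  # stop codon excluded
    llr = score_sequence(cds, model)
    return CodingScore(llr=llr, threshold=threshold, translatable=llr >= threshold)


def save_model(model: HexamerModel, path: str | Path) -> None:
    """Serialize to a flat text format: header lines then hexamer/coding/background."""
    with open(path, "w") as fh:
        fh.write(f"# pseudocount\t{model.pseudocount!r}\n")
        fh.write(f"# trained_on\t{model.trained_on}\n")
        for h in ALL_HEXAMERS:
            fh.write(f"{h}\t{model.coding_freqs[h]!r}\t{model.background_freqs[h]!r}\n")


def load_model(path: str | Path) -> HexamerModel:
    coding: dict[str, float] = {}
    background: dict[str, float] = {}
    pseudocount = 1.0
    trained_on = ""
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("\t")
                if key == "pseudocount":
                    pseudocount = float(val)
                elif key == "trained_on":
                    trained_on = val
                continue
            h, c, b = line.split("\t")
            coding[h] = float(c)
            background[h] = float(b)
    if len(coding) != N_HEXAMERS:
        raise CodingError(f"model file {path} has {len(coding)} hexamers, expected {N_HEXAMERS}")
    return HexamerModel(coding, background, pseudocount, trained_on)
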