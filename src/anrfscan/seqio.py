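"""Sequence ingestion, alphabet normalization, and ORF enumeration.

Transcripts are handled on the forward (mRNA sense) strand in DNA alphabet;
``U`` is normalized to ``T`` on input. ORFs are AUG-initiated, terminated by
the first in-frame stop codon, and reported in 1-based inclusive transcript
coordinates with the stop codon included in the span but excluded from the
peptide. Codons containing ``N`` never match a start or stop codon.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id

log = logging.getLogger(__name__)

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_TABLE1 = unambiguous_dna_by_id[1].forward_table

# IUPAC nucleotide ambiguity codes other than N are collapsed to N on input.
_AMBIGUOUS = set("RYSWKMBDHV")
_VALID = set("ACGTN")


class SeqioError(ValueError):
    """Raised for malformed FASTA input or impossible ORF queries."""


@dataclass
class Transcript:
    """A single mRNA sequence.

    Parameters
    ----------
    id : str
        Record identifier, unique within a run.
    seq : str
        Nucleotide sequence, A/C/G/T/N after normalization.
    main_orf_hint : tuple of (int, int), optional
        Annotated main-ORF coordinates (1-based, inclusive, stop included).
        When present, :func:`find_main_orf` returns it verbatim after
        validation instead of applying the longest-ORF rule.
    """

    id: str
    seq: str
    main_orf_hint: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqioError("transcript id must be non-empty")
        self.seq = normalize_seq(self.seq, context=self.id)

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class OrfRecord:
    """A located ORF with coordinates, frame offset, and translated peptide.

    ``start`` is the first nt of the AUG, ``end`` the last nt of the stop
    codon, both 1-based inclusive. ``frame_offset`` is the reading-frame
    shift relative to the main ORF: 0 for the main ORF itself, 1 or 2 for
    nested alternative-frame ORFs. For records produced by
    :func:`enumerate_orfs` (kind ``"orf"``) it is the absolute frame
    ``(start - 1) % 3``. The peptide excludes the stop.
    """

    transcript_id: str
    start: int
    end: int
    frame_offset: int
    peptide: str
    kind: str = "orf"
    strand: str = "+"
    seq: str = field(default="", repr=False)

    @property
    def length_aa(self) -> int:
        return (self.end - self.start + 1) // 3 - 1

    def validate(self, transcript: Transcript) -> None:
        """Check the record's structural invariants against its transcript."""
        span = self.end - self.start + 1
        if span % 3 != 0:
            raise SeqioError(f"ORF span {span} not divisible by 3")
        s = transcript.seq
        if s[self.start - 1 : self.start + 2] != START_CODON:
            raise SeqioError(f"ORF at {self.start} does not begin with ATG")
        if s[self.end - 3 : self.end] not in STOP_CODONS:
            raise SeqioError(f"ORF ending at {self.end} lacks a stop codon")
        if len(self.peptide) != self.length_aa:
            raise SeqioError("peptide length inconsistent with coordinates")
        if "*" in self.peptide:
            raise SeqioError("peptide contains a stop symbol")


def normalize_seq(seq: str, context: str = "") -> str:
    """Uppercase, U->T, IUPAC ambiguity codes (except N) -> N."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID
    if bad:
        mappable = bad & _AMBIGUOUS
        illegal = bad - _AMBIGUOUS
        if illegal:
            raise SeqioError(
                f"non-nucleotide characters {sorted(illegal)} in sequence {context!r}"
            )
        log.warning(
            "sequence %r: IUPAC ambiguity codes %s mapped to N",
            context,
            sorted(mappable),
        )
        s = s.translate(str.maketrans({c: "N" for c in mappable}))
    return s


def translate_cds(seq: str) -> str:
    """Translate a stop-free coding region (table 1); N-containing codons -> X."""
    return "".join(
        _TABLE1.get(seq[i : i + 3], "X") for i in range(0, len(seq) - len(seq) % 3, 3)
    )


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read a FASTA file into a list of :class:`Transcript`.

    Ids are taken from the header up to the first whitespace. Raises
    :class:`SeqioError` on a missing or empty file or duplicate ids.
    """
    path = Path(path)
    if not path.exists():
        raise SeqioError(f"no such file: {path}")
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqioError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        transcripts.append(Transcript(id=rec.id, seq=str(rec.seq)))
    if not transcripts:
        raise SeqioError(f"empty FASTA: {path}")
    return transcripts


def write_fasta(transcripts: Iterable[Transcript], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.seq), width):
                fh.write(t.seq[i : i + width] + "\n")


def _stop_positions_by_frame(seq: str) -> list[list[int]]:
    """0-based start positions of stop codons, one sorted list per frame."""
    frames: list[list[int]] = [[], [], []]
    for i in range(len(seq) - 2):
        if seq[i : i + 3] in STOP_CODONS:
            frames[i % 3].append(i)
    return frames


def enumerate_orfs(t: Transcript, min_aa: int, max_aa: int) -> list[OrfRecord]:
    """Every forward-strand AUG...stop ORF with ``min_aa <= length_aa <= max_aa``.

    Each AUG yields at most one record (first in-frame stop); AUGs with no
    downstream in-frame stop yield none. Records are sorted by start and
    carry ``kind="orf"`` with ``frame_offset`` set to the absolute frame.
    """
    if not (0 <= min_aa <= max_aa):
        raise SeqioError(f"invalid length band [{min_aa}, {max_aa}]")
    seq = t.seq
    stops = _stop_positions_by_frame(seq)
    out: list[OrfRecord] = []
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != START_CODON:
            continue
        frame_stops = stops[i % 3]
        j = bisect.bisect_left(frame_stops, i + 3)
        if j == len(frame_stops):
            continue
        stop = frame_stops[j]
        length_aa = (stop - i) // 3
        if not (min_aa <= length_aa <= max_aa):
            continue
        cds = seq[i:stop]
        out.append(
            OrfRecord(
                transcript_id=t.id,
                start=i + 1,
                end=stop + 3,
                frame_offset=i % 3,
                peptide=translate_cds(cds),
                kind="orf",
                seq=seq[i : stop + 3],
            )
        )
    return out


def find_main_orf(t: Transcript) -> OrfRecord:
    """The transcript's main ORF.

    Returns ``main_orf_hint`` verbatim (validated) when set, else the longest
    AUG-initiated ORF over the three forward frames, ties broken by the
    smaller start coordinate.
    """
    if t.main_orf_hint is not None:
        start, end = t.main_orf_hint
        if not (1 <= start < end <= t.length):
            raise SeqioError(f"{t.id}: main_orf_hint {t.main_orf_hint} out of range")
        rec = OrfRecord(
            transcript_id=t.id,
            start=start,
            end=end,
            frame_offset=0,
            peptide=translate_cds(t.seq[start - 1 : end - 3]),
            kind="main",
            seq=t.seq[start - 1 : end],
        )
        rec.validate(t)
        return rec
    candidates = enumerate_orfs(t, 0, t.length)
    if not candidates:
        raise SeqioError(f"no main ORF found in transcript {t.id!r}")
    best = max(candidates, key=lambda o: (o.length_aa, -o.start))
    best.kind = "main"
    best.frame_offset = 0
    return best


def nested_sorfs(
    t: Transcript, main: OrfRecord, min_aa: int = 10, max_aa: int = 100
) -> list[OrfRecord]:
    """Alternative-frame short ORFs nested entirely inside the main ORF.

    A nested sORF starts strictly downstream of the main AUG, ends at or
    before the main stop, and lies in a shifted frame
    (``(start - main.start) % 3 in {1, 2}``); in-frame internal AUGs are
    excluded.
    """
    out = []
    for orf in enumerate_orfs(t, min_aa, max_aa):
        if orf.start <= main.start or orf.end > main.end:
            continue
        offset = (orf.start - main.start) % 3
        if offset == 0:
            continue
        orf.kind = "nested"
        orf.frame_offset = offset
        out.append(orf)
    return out


def upstream_uorfs(t: Transcript, main: OrfRecord, min_aa: int = 1) -> list[OrfRecord]:
    """ORFs lying entirely in the 5'-UTR (end strictly before the main AUG)."""
    out = []
    for orf in enumerate_orfs(t, min_aa, t.length):
        if orf.end < main.start:
            orf.kind = "uorf"
            orf.frame_offset = (orf.start - main.start) % 3
            out.append(orf)
    return out
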