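"""Kozak-style scoring of AUG start-codon contexts.

The context window is 11 characters: 5 nt upstream, the start codon, and
3 nt downstream (positions -5..-1, AUG, +4..+6 in the standard numbering
where the A of AUG is +1). Positions falling outside the transcript are
rendered ``?`` and never count as matches.

Two reference contexts are scored:

* the plant Kozak consensus ``aMN-AUG-gS`` (M = A/C, N = any, S = G/C),
  whose four constrained positions (-3, -2, +4, +5) drive the binary
  favorable/unfavorable call;
* the dicot optimal context ``aaA(A/C)a-AUG-GCu``, scored as a 0-8 match
  count and used only for reporting and tie-breaking.

For graded comparison between two AUGs a weighted score doubles the two
positions with the strongest known effect on initiation (-3 and +4),
giving a 0-6 scale where 6 == favorable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import Transcript, SeqioError

# consensus aMN-AUG-gS: window index -> allowed nucleotides
CONSENSUS = {2: "A", 3: "AC", 8: "G", 9: "GC"}  # -3, -2, +4, +5
DEFAULT_WEIGHTS = {2: 2, 3: 1, 8: 2, 9: 1}

# dicot optimum aaA(A/C)a-AUG-GCu: window index -> allowed nucleotides
OPTIMUM = {0: "A", 1: "A", 2: "A", 3: "AC", 4: "A", 8: "G", 9: "C", 10: "T"}


@dataclass
class StartContext:
    """Scored 11-nt context of one AUG."""

    window: str
    consensus_matches: int
    weighted_score: int
    favorable: bool
    optimality_matches: int


def _normalize_window(window: str) -> str:
    return window.upper().replace("U", "T")


def consensus_match(window: str) -> tuple[bool, int, int]:
    """Favorable call, constrained-position match count, and weighted score.

    ``window`` may be a bare 11-character window or a :class:`StartContext`'s
    ``window`` field; scoring is case- and U/T-insensitive. ``?`` never
    matches.
    """
    w = _normalize_window(window)
    matches = 0
    weighted = 0
    for idx, allowed in CONSENSUS.items():
        if idx < len(w) and w[idx] in allowed:
            matches += 1
            weighted += DEFAULT_WEIGHTS[idx]
    return matches == len(CONSENSUS), matches, weighted


def optimality_score(window: str) -> int:
    """Match count (0-8) against the dicot optimal context."""
    w = _normalize_window(window)
    return sum(1 for idx, allowed in OPTIMUM.items() if idx < len(w) and w[idx] in allowed)


def score_window(window: str) -> StartContext:
    """Build a fully scored :class:`StartContext` from an 11-char window."""
    favorable, matches, weighted = consensus_match(window)
    return StartContext(
        window=window,
        consensus_matches=matches,
        weighted_score=weighted,
        favorable=favorable,
        optimality_matches=optimality_score(window),
    )


def extract_context(t: Transcript, orf_start: int) -> StartContext:
    """Extract and score the 11-nt window around the AUG at ``orf_start``.

    ``orf_start`` is 1-based; positions before the 5' end or past the 3' end
    are padded with ``?``.
    """
    s = t.seq
    if s[orf_start - 1 : orf_start + 2] != "ATG":
        raise SeqioError(
            f"{t.id}: position {orf_start} is not an AUG start codon"
        )
    chars = []
    for pos in range(orf_start - 5, orf_start + 6):  # 1-based positions
        chars.append(s[pos - 1] if 1 <= pos <= len(s) else "?")
    return score_window("".join(chars))


def compare_contexts(anrf_ctx: StartContext, main_ctx: StartContext) -> bool:
    """True iff the ANRF context is strictly more favorable than the main's.

    Primary key: weighted consensus score; ties broken by the dicot
    optimality count, strictness required on the tie-break as well.
    """
    if anrf_ctx.weighted_score != main_ctx.weighted_score:
        return anrf_ctx.weighted_score > main_ctx.weighted_score
    return anrf_ctx.optimality_matches > main_ctx.optimality_matches
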