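"""Per-transcript matryoshka scan and transcriptome-level summary.

A transcript is scanned in three stages. First its main ORF is located and
its 5'-UTR uORFs are inventoried. Each alternative-frame nested sORF is
then tested against the scan criteria:

  (a) encoded product between ``min_aa`` and ``max_aa`` residues,
  (b) translatable under the hexamer coding-potential model,
  (c) AUG in a favorable Kozak context (consensus aMN-AUG-gS).

A transcript with at least one candidate passing (a)-(c) is a matryoshka
transcript and its passing candidates are ANRFs. Each candidate is further
annotated with the three-part matryoshka signature observed for the
KPI-like gene group:

  (i)   start context strictly more favorable than the main ORF's,
  (ii)  a polypurine block of >= ``pp_min_len`` consecutive purines ending
        within ``pp_window`` nt upstream of the nested AUG,
  (iii) encoded peptide of ``sig_min_aa``-``sig_max_aa`` residues with an
        amphipathic helix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, fields as dc_fields
from pathlib import Path
from typing import Optional

import yaml

from .seqio import Transcript, OrfRecord, find_main_orf, nested_sorfs, upstream_uorfs
from .start_context import StartContext, extract_context, compare_contexts
from .coding_potential import HexamerModel, CodingScore, coding_score
from .upstream_features import PolypurineBlock, find_polypurine
from .amphipathicity import AhProfile, hydrophobic_moment, classify_ah

log = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """All tunable thresholds of the scan.

    Defaults follow the matryoshka characterization: nested sORF products of
    10-100 aa, signature peptide band 30-53 aa, polypurine blocks of >= 18 nt
    searched within 60 nt upstream of the nested AUG (covering both the
    "~30 nt" and "39 nt" observed distances), 18-25 nt annotated as the
    signature band, coding LLR threshold 0, and the conventional
    amphipathicity boundary muH >= 0.4.
    """

    min_aa: int = 10
    max_aa: int = 100
    sig_min_aa: int = 30
    sig_max_aa: int = 53
    pp_min_len: int = 18
    pp_band_max: int = 25
    pp_window: int = 60
    coding_threshold: float = 0.0
    muH_threshold: float = 0.4
    meanH_threshold: float = 0.0
    ah_window: int = 18
    ah_delta: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.min_aa <= self.sig_min_aa <= self.sig_max_aa <= self.max_aa):
            raise ValueError(
                "require min_aa <= sig_min_aa <= sig_max_aa <= max_aa, got "
                f"{self.min_aa}/{self.sig_min_aa}/{self.sig_max_aa}/{self.max_aa}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScanConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class AnrfCandidate:
    """A nested sORF with all scan evidence attached."""

    orf: OrfRecord
    context: StartContext
    coding: CodingScore
    pp_blocks: list[PolypurineBlock]
    ah_profile: AhProfile
    ah_call: bool
    passes_abc: bool
    criterion_i: bool
    criterion_ii: bool
    criterion_iii: bool

    @property
    def signature(self) -> bool:
        return self.passes_abc and self.criterion_i and self.criterion_ii and self.criterion_iii

    @property
    def pp_in_band(self) -> bool:
        """Some detected block's length lies in the 18-25 nt signature band
        (annotation only; see :class:`ScanConfig`)."""
        return any(b.length <= 25 for b in self.pp_blocks)


@dataclass
class MatryoshkaReport:
    transcript_id: str
    main_orf: OrfRecord
    main_context: StartContext
    uorfs: list[OrfRecord]
    candidates: list[AnrfCandidate]

    @property
    def n_anrf(self) -> int:
        return sum(1 for c in self.candidates if c.passes_abc)

    @property
    def matryoshka(self) -> bool:
        return self.n_anrf >= 1

    @property
    def signature_positive(self) -> bool:
        return any(c.signature for c in self.candidates)


@dataclass
class ScanSummary:
    n_transcripts: int
    n_candidates: int  # candidates passing (a)-(c), i.e. ANRFs
    n_matryoshka: int
    histogram: dict[int, int] = field(default_factory=dict)
    pct_1: Optional[float] = None
    pct_2: Optional[float] = None
    pct_3plus: Optional[float] = None


def scan_transcript(t: Transcript, cfg: ScanConfig, model: HexamerModel) -> MatryoshkaReport:
    """Run the full matryoshka scan on one transcript."""
    main = find_main_orf(t)
    main_ctx = extract_context(t, main.start)
    uorfs = upstream_uorfs(t, main)
    candidates: list[AnrfCandidate] = []
    for orf in nested_sorfs(t, main, cfg.min_aa, cfg.max_aa):
        ctx = extract_context(t, orf.start)
        coding = coding_score(orf, model, cfg.coding_threshold)
        blocks = find_polypurine(t, orf.start, window=cfg.pp_window, min_len=cfg.pp_min_len)
        if "X" in orf.peptide:  # N-derived residues: no AH call, conservatively
            profile = AhProfile(peptide=orf.peptide, window=cfg.ah_window, delta=cfg.ah_delta)
            ah = False
        else:
            profile = hydrophobic_moment(orf.peptide, window=cfg.ah_window, delta=cfg.ah_delta)
            ah = classify_ah(profile, cfg.muH_threshold, cfg.meanH_threshold)
        passes_abc = (
            cfg.min_aa <= orf.length_aa <= cfg.max_aa
            and coding.translatable
            and ctx.favorable
        )
        candidates.append(
            AnrfCandidate(
                orf=orf,
                context=ctx,
                coding=coding,
                pp_blocks=blocks,
                ah_profile=profile,
                ah_call=ah,
                passes_abc=passes_abc,
                criterion_i=compare_contexts(ctx, main_ctx),
                criterion_ii=len(blocks) > 0,
                criterion_iii=(cfg.sig_min_aa <= orf.length_aa <= cfg.sig_max_aa) and ah,
            )
        )
    log.info(
        "%s: %d uORF(s), %d nested sORF(s), %d passing (a)-(c)",
        t.id, len(uorfs), len(candidates), sum(c.passes_abc for c in candidates),
    )
    return MatryoshkaReport(
        transcript_id=t.id,
        main_orf=main,
        main_context=main_ctx,
        uorfs=uorfs,
        candidates=candidates,
    )


def summarize(reports: list[MatryoshkaReport]) -> ScanSummary:
    """Transcriptome-level ANRF-count distribution over matryoshka transcripts."""
    histogram: dict[int, int] = {}
    n_candidates = 0
    for r in reports:
        k = r.n_anrf
        n_candidates += k
        if k >= 1:
            histogram[k] = histogram.get(k, 0) + 1
    n_matryoshka = sum(histogram.values())
    summary = ScanSummary(
        n_transcripts=len(reports),
        n_candidates=n_candidates,
        n_matryoshka=n_matryoshka,
        histogram=dict(sorted(histogram.items())),
    )
    if n_matryoshka:
        summary.pct_1 = round(100.0 * histogram.get(1, 0) / n_matryoshka, 1)
        summary.pct_2 = round(100.0 * histogram.get(2, 0) / n_matryoshka, 1)
        summary.pct_3plus = round(
            100.0 * sum(v for k, v in histogram.items() if k >= 3) / n_matryoshka, 1
        )
    return summary


# ---------------------------------------------------------------------------
# report output: TSV candidate table, GFF3 features, plain-text summary

CANDIDATE_COLUMNS = [
    "transcript_id", "start", "end", "frame_offset", "length_aa", "peptide",
    "context_window", "consensus_matches", "weighted_score", "favorable",
    "optimality_matches", "coding_llr", "translatable",
    "pp_blocks", "pp_in_band", "max_muH", "ah_call",
    "passes_abc", "criterion_i", "criterion_ii", "criterion_iii", "signature",
]


def _fmt_blocks(blocks: list[PolypurineBlock]) -> str:
    return ";".join(f"{b.start}:{b.length}:{b.distance_to_aug}" for b in blocks) or "."


def _candidate_row(r: MatryoshkaReport, c: AnrfCandidate) -> list[str]:
    return [
        r.transcript_id,
        str(c.orf.start),
        str(c.orf.end),
        str(c.orf.frame_offset),
        str(c.orf.length_aa),
        c.orf.peptide,
        c.context.window,
        str(c.context.consensus_matches),
        str(c.context.weighted_score),
        str(c.context.favorable),
        str(c.context.optimality_matches),
        f"{c.coding.llr:.6f}",
        str(c.coding.translatable),
        _fmt_blocks(c.pp_blocks),
        str(c.pp_in_band),
        f"{c.ah_profile.max_muH:.6f}",
        str(c.ah_call),
        str(c.passes_abc),
        str(c.criterion_i),
        str(c.criterion_ii),
        str(c.criterion_iii),
        str(c.signature),
    ]


def _gff3_line(tid: str, ftype: str, start: int, end: int, attrs: str) -> str:
    return f"{tid}\tanrfscan\t{ftype}\t{start}\t{end}\t.\t+\t0\t{attrs}\n"


def write_reports(
    reports: list[MatryoshkaReport], summary: ScanSummary, out_prefix: str | Path
) -> dict[str, Path]:
    """Write ``<prefix>.candidates.tsv``, ``<prefix>.features.gff3`` and
    ``<prefix>.summary.txt``; deterministic row order (transcript id, start)."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "tsv": prefix.with_name(prefix.name + ".candidates.tsv"),
        "gff3": prefix.with_name(prefix.name + ".features.gff3"),
        "summary": prefix.with_name(prefix.name + ".summary.txt"),
    }
    ordered = sorted(reports, key=lambda r: r.transcript_id)

    with open(paths["tsv"], "w") as fh:
        fh.write(f"# transcripts_scanned\t{summary.n_transcripts}\n")
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for r in ordered:
            for c in sorted(r.candidates, key=lambda c: c.orf.start):
                fh.write("\t".join(_candidate_row(r, c)) + "\n")

    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for r in ordered:
            m = r.main_orf
            fh.write(_gff3_line(r.transcript_id, "main_ORF", m.start, m.end,
                                f"ID={r.transcript_id}.main"))
            for i, u in enumerate(sorted(r.uorfs, key=lambda o: o.start), 1):
                fh.write(_gff3_line(r.transcript_id, "uORF", u.start, u.end,
                                    f"ID={r.transcript_id}.uorf{i}"))
            for i, c in enumerate(sorted(r.candidates, key=lambda c: c.orf.start), 1):
                fh.write(_gff3_line(
                    r.transcript_id, "ANRF", c.orf.start, c.orf.end,
                    f"ID={r.transcript_id}.anrf{i};passes_abc={c.passes_abc};"
                    f"signature={c.signature}"))

    with open(paths["summary"], "w") as fh:
        fh.write(f"transcripts scanned\t{summary.n_transcripts}\n")
        fh.write(f"ANRFs (candidates passing a-c)\t{summary.n_candidates}\n")
        fh.write(f"matryoshka transcripts\t{summary.n_matryoshka}\n")
        if summary.n_matryoshka:
            fh.write(f"% with 1 ANRF\t{summary.pct_1:.1f}\n")
            fh.write(f"% with 2 ANRFs\t{summary.pct_2:.1f}\n")
            fh.write(f"% with >=3 ANRFs\t{summary.pct_3plus:.1f}\n")
        else:
            fh.write("% with 1 ANRF\tn/a\n% with 2 ANRFs\tn/a\n% with >=3 ANRFs\tn/a\n")
        fh.write("ANRF-count histogram\t" + (
            ";".join(f"{k}:{v}" for k, v in summary.histogram.items()) or ".") + "\n")
    return paths


def read_candidate_table(path: str | Path) -> tuple[int, "pandas.DataFrame"]:
    """Parse a candidates TSV back; returns (transcripts_scanned, table)."""
    import pandas as pd

    with open(path) as fh:
        first = fh.readline()
    n_transcripts = int(first.rstrip("\n").split("\t")[1]) if first.startswith("#") else 0
    table = pd.read_csv(path, sep="\t", comment=None, skiprows=1)
    return n_transcripts, table


def summary_from_candidate_table(path: str | Path) -> ScanSummary:
    """Recompute the :class:`ScanSummary` from a written candidates TSV."""
    n_transcripts, table = read_candidate_table(path)
    histogram: dict[int, int] = {}
    n_candidates = 0
    if len(table):
        passing = table[table["passes_abc"] == True]  # noqa: E712
        n_candidates = len(passing)
        for _, k in passing.groupby("transcript_id").size().items():
            histogram[k] = histogram.get(k, 0) + 1
    n_matryoshka = sum(histogram.values())
    summary = ScanSummary(
        n_transcripts=n_transcripts,
        n_candidates=n_candidates,
        n_matryoshka=n_matryoshka,
        histogram=dict(sorted(histogram.items())),
    )
    if n_matryoshka:
        summary.pct_1 = round(100.0 * histogram.get(1, 0) / n_matryoshka, 1)
        summary.pct_2 = round(100.0 * histogram.get(2, 0) / n_matryoshka, 1)
        summary.pct_3plus = round(
            100.0 * sum(v for k, v in histogram.items() if k >= 3) / n_matryoshka, 1
        )
    return summary
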