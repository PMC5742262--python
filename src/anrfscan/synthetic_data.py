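"""Synthetic transcriptomes with planted, manifest-verified ground truth.

Each generated transcript mimics the layout the scan targets: a 5'-UTR
(optionally opening with a start-stop uORF), an AUG-initiated main ORF whose
codons are drawn from a stylized biased codon-usage table, optionally a
nested alternative-frame sORF planted at a controlled offset with a
controlled start-codon context, an optional polypurine block planted at a
controlled distance upstream of the nested AUG, and a 3'-UTR. Non-coding
regions are drawn i.i.d. uniform over A/C/G/T.

The nested sORF's own codons are drawn from the same codon-usage table in
the *nested* frame (synonymous choices resampled so the main frame stays
stop-free), so planted sORFs carry the same hexamer signal the coding-
potential model is trained on. Plants with an amphipathic-helix peptide use
a deterministic periodic design (hydrophobic/polar faces alternating at the
helical period) verified against the hydrophobic-moment classifier at build
time; non-AH plants use seeded scrambles verified to fall below the
threshold.

To keep the manifest an exact ground truth, the generator rejection-samples
(bounded, seeded) transcripts containing accidental confounders: stray UTR
AUGs, favorable-context nested sORFs other than the plant, purine runs in
the polypurine window when no block was requested, or a longest ORF other
than the planted main ORF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .seqio import Transcript, write_fasta, find_main_orf, nested_sorfs, translate_cds
from .start_context import score_window, extract_context
from .coding_potential import HexamerModel, train_hexamer_model, score_sequence
from .amphipathicity import hydrophobic_moment, classify_ah
from .upstream_features import find_polypurine
from .anrf_scan import ScanConfig

MAX_ATTEMPTS = 1000

FAVORABLE_UP, FAVORABLE_DOWN = "AGAAA", "GGA"      # agAaa-AUG-Gga
UNFAVORABLE_UP, UNFAVORABLE_DOWN = "TTCTT", "TAC"  # fails all 4 consensus positions

_CODON_TO_AA = unambiguous_dna_by_id[1].forward_table
STOPS = ("TAA", "TAG", "TGA")


def _shift_safe(codon: str) -> bool:
    """True when the codon cannot seed a stop codon in an overlapping frame:
    no T in the last position and no TA/TG suffix starting at position 2."""
    return codon[2] != "T" and not (codon[1] == "T" and codon[2] in "AG")


def _build_codon_usage() -> dict[str, dict[str, float]]:
    """Stylized codon-bias table: per amino acid one preferred codon at
    weight 0.7, the rest sharing 0.3 (no species-realism claim). Preference
    goes to a shift-safe codon — echoing the pyrimidine-ending bias of
    highly expressed genes — so that runs of preferred codons read stop-free
    in every frame."""
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(_CODON_TO_AA.items()):
        by_aa.setdefault(aa, []).append(codon)
    usage: dict[str, dict[str, float]] = {}
    for aa, codons in by_aa.items():
        if len(codons) == 1:
            usage[aa] = {codons[0]: 1.0}
            continue
        preferred = next((c for c in codons if _shift_safe(c)), codons[0])
        rest = 0.3 / (len(codons) - 1)
        usage[aa] = {c: (0.7 if c == preferred else rest) for c in codons}
    return usage


DEFAULT_CODON_USAGE = _build_codon_usage()
AMINO_ACIDS = sorted(DEFAULT_CODON_USAGE)
NUCLEOTIDES = "ACGT"


class InfeasibleSpecError(ValueError):
    """A plant specification that cannot be realized at all."""


class GenerationError(RuntimeError):
    """Bounded resampling exhausted without a clean realization."""


# ---------------------------------------------------------------------------
# plant specifications


@dataclass
class PpBlockSpec:
    length: int = 20       # nt, signature band is 18-25
    distance: int = 39     # nt gap to the nested AUG (paper-layout default)


@dataclass
class AnrfPlant:
    offset_in_orf: int = 407       # 1-based nt position of the AUG within the main ORF
    length_aa: int = 53            # peptide length, stop excluded
    context_class: str = "favorable"
    pp_block: Optional[PpBlockSpec] = field(default_factory=PpBlockSpec)
    peptide_class: str = "AH"      # "AH" or "non-AH"


@dataclass
class PlantSpec:
    utr5_len: int = 23
    uorf: Optional[str] = "ATGCATTAA"
    main_len_aa: int = 201         # peptide length, stop excluded (ORF = 606 nt)
    anrf: Optional[AnrfPlant] = field(default_factory=AnrfPlant)
    utr3_len: int = 50
    main_context_class: str = "unfavorable"

    def validate(self) -> None:
        if self.utr5_len < 5:
            raise InfeasibleSpecError("utr5_len must be >= 5 (start-context stamp)")
        if self.uorf is not None:
            if len(self.uorf) % 3 or not self.uorf.startswith("ATG") or self.uorf[-3:] not in STOPS:
                raise InfeasibleSpecError(f"uorf {self.uorf!r} is not a start..stop codon string")
            if len(self.uorf) + 5 > self.utr5_len:
                raise InfeasibleSpecError("uorf does not fit in the 5'-UTR with the context stamp")
        if self.main_len_aa < 2:
            raise InfeasibleSpecError("main ORF must encode at least 2 residues")
        a = self.anrf
        if a is None:
            return
        if a.context_class not in ("favorable", "unfavorable"):
            raise InfeasibleSpecError(f"unknown context_class {a.context_class!r}")
        if a.peptide_class not in ("AH", "non-AH"):
            raise InfeasibleSpecError(f"unknown peptide_class {a.peptide_class!r}")
        if a.length_aa < 2:
            raise InfeasibleSpecError("nested sORF must encode at least 2 residues")
        off = a.offset_in_orf
        if (off - 1) % 3 not in (1, 2):
            raise InfeasibleSpecError(
                f"anrf offset {off} is in frame with the main ORF (frame offset must be 1 or 2)"
            )
        if off < 12:
            raise InfeasibleSpecError(
                "anrf offset must leave room for the context stamp clear of the main start"
            )
        if off + 3 * (a.length_aa + 1) - 1 > 3 * self.main_len_aa:
            raise InfeasibleSpecError(
                f"anrf of {a.length_aa} aa at offset {off} does not fit inside the "
                f"{self.main_len_aa} aa main ORF"
            )
        if a.pp_block is not None:
            b = a.pp_block
            if b.length < 1 or b.distance < 6:
                raise InfeasibleSpecError(
                    "pp block needs length >= 1 and distance >= 6 (clear of the context stamp)"
                )
            if off - b.distance - b.length < 8:
                raise InfeasibleSpecError("pp block does not fit upstream of the anrf inside the ORF")


@dataclass
class ManifestEntry:
    """Realized coordinates (1-based transcript) and expected scan outcome."""

    id: str
    utr5_len: int
    main_start: int
    main_end: int
    uorf_start: Optional[int] = None
    uorf_end: Optional[int] = None
    anrf_start: Optional[int] = None
    anrf_end: Optional[int] = None
    anrf_len_aa: Optional[int] = None
    context_class: Optional[str] = None
    peptide_class: Optional[str] = None
    pp_start: Optional[int] = None
    pp_len: Optional[int] = None
    pp_distance: Optional[int] = None
    anrf_llr: Optional[float] = None
    expected_passes_abc: bool = False
    expected_i: bool = False
    expected_ii: bool = False
    expected_iii: bool = False


# ---------------------------------------------------------------------------
# low-level sampling


def _cumulative_usage(usage: dict[str, dict[str, float]]):
    cum = {}
    for aa, table in usage.items():
        codons = list(table)
        probs = np.cumsum([table[c] for c in codons])
        cum[aa] = (codons, probs)
    return cum


_USAGE_CUM = _cumulative_usage(DEFAULT_CODON_USAGE)


def _sample_codon(aa: str, rng: np.random.Generator) -> str:
    codons, cum = _USAGE_CUM[aa]
    return codons[int(np.searchsorted(cum, rng.random(), side="right"))] if len(codons) > 1 else codons[0]


def _sample_coding(n_codons: int, rng: np.random.Generator) -> str:
    aas = [AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), n_codons)]
    return "".join(_sample_codon(aa, rng) for aa in aas)


def _sample_noncoding(n: int, rng: np.random.Generator) -> str:
    return "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, n))


def design_peptide(
    length_aa: int,
    peptide_class: str,
    rng: np.random.Generator,
    second_residue: str = "G",
    window: int = 18,
    muH_threshold: float = 0.4,
    meanH_threshold: float = 0.0,
) -> str:
    """A nested-sORF peptide of the requested amphipathicity class.

    The AH design alternates hydrophobic and polar residues by helical face
    (period 3.6 residues at 100 deg/residue) and is verified against the
    classifier; the non-AH design is a seeded scramble of the same residues
    verified to fall below the threshold. Residues 1 (Met) and 2 (fixed by
    the start-context stamp) are pinned.
    """
    phobic, polar = "LIFLV", "KSET"
    pep = ["M"]
    for i in range(1, length_aa):
        face = math.cos(math.radians(100.0 * i))
        pep.append(phobic[i % len(phobic)] if face >= 0 else polar[i % len(polar)])
    if length_aa >= 2:
        pep[1] = second_residue
    if peptide_class == "AH":
        profile = hydrophobic_moment("".join(pep), window=window)
        if not classify_ah(profile, muH_threshold, meanH_threshold):
            raise InfeasibleSpecError(
                f"cannot realize an AH peptide of {length_aa} aa (windows of {window})"
            )
        return "".join(pep)
    # non-AH: scramble the tail until the classifier rejects it
    tail = pep[2:]
    for _ in range(MAX_ATTEMPTS):
        rng.shuffle(tail)
        cand = "".join(pep[:2] + tail)
        profile = hydrophobic_moment(cand, window=window)
        if not classify_ah(profile, muH_threshold, meanH_threshold):
            return cand
    raise GenerationError(f"could not scramble a non-AH peptide of {length_aa} aa")


# ---------------------------------------------------------------------------
# planting


def _main_frame_stop_free(cds: str, n_codons: int) -> bool:
    return all(cds[i : i + 3] not in STOPS for i in range(0, 3 * n_codons, 3))


def plant_anrf(
    main_cds: str,
    spec: AnrfPlant,
    rng: np.random.Generator,
    model: Optional[HexamerModel] = None,
    n_tries: int = 10,
) -> tuple[str, str]:
    """Plant a nested alternative-frame sORF into a main coding region.

    ``main_cds`` is the main ORF nucleotide string including its stop codon.
    Returns the modified string and the planted nested peptide. Synonymous
    choices for the nested codons are repaired locally, bounded, until the
    main frame remains stop-free; when a hexamer model is given, the best-
    scoring of ``n_tries`` clean realizations is kept so planted sORFs are
    as coding-like as their synonymous freedom allows.
    """
    off = spec.offset_in_orf  # 1-based within the ORF
    length = spec.length_aa
    n_codons = len(main_cds) // 3 - 1
    up, down = (
        (FAVORABLE_UP, FAVORABLE_DOWN)
        if spec.context_class == "favorable"
        else (UNFAVORABLE_UP, UNFAVORABLE_DOWN)
    )
    second_aa = _CODON_TO_AA[down]
    peptide = design_peptide(length, spec.peptide_class, rng, second_residue=second_aa)

    start0 = off - 1  # 0-based ORF position of the nested ATG
    region_lo = start0 - 5
    region_len = 5 + 3 * (length + 1)
    # main-frame codon starts overlapping the rewritten window (stop excluded)
    c_lo = (region_lo // 3) * 3
    codon_starts = [
        c for c in range(c_lo, region_lo + region_len, 3) if c + 3 <= 3 * n_codons
    ]

    def _overlapping_nested(c: int) -> list[int]:
        """Indices of resampleable nested codons under main-frame codon c."""
        out = set()
        for pos in range(max(c, start0), min(c + 3, start0 + 3 * (length + 1))):
            j = (pos - start0) // 3
            if 2 <= j <= length:  # 0=ATG, 1=context codon are pinned
                out.add(j)
        return sorted(out)

    def _resample(codons: list[str], j: int) -> None:
        codons[j] = (
            STOPS[rng.integers(0, 3)] if j == length else _sample_codon(peptide[j], rng)
        )

    def _stop_free_extension(prefix: str, codon: str) -> bool:
        """No main-frame stop among codons completed by appending ``codon``."""
        p = len(prefix)
        trial = prefix + codon
        for c in range(max(0, p - 2), p + 3):
            if c % 3 == 0 and c + 3 <= len(trial) and trial[c : c + 3] in STOPS:
                return False
        return True

    def _greedy_codons() -> list[str]:
        """Left-to-right synonym choice maximizing the dicodon-hexamer LLR,
        preferring choices that keep the main frame stop-free."""
        codons = ["ATG", down]
        prefix = main_cds[:region_lo] + up + "ATG" + down
        for aa in peptide[2:]:
            syns = sorted(
                DEFAULT_CODON_USAGE[aa],
                key=lambda c: model.llr(codons[-1] + c),
                reverse=True,
            )
            chosen = next((s for s in syns if _stop_free_extension(prefix, s)), syns[0])
            codons.append(chosen)
            prefix += chosen
        stop = next((s for s in STOPS if _stop_free_extension(prefix, s)), STOPS[0])
        codons.append(stop)
        return codons

    best: tuple[float, str] | None = None
    for attempt in range(n_tries):
        if attempt == 0 and model is not None:
            codons = _greedy_codons()
        else:
            codons = ["ATG", down] + [_sample_codon(aa, rng) for aa in peptide[2:]]
            codons.append(STOPS[rng.integers(0, 3)])
        cand = None
        for _repair in range(100):
            region = up + "".join(codons)
            trial = main_cds[:region_lo] + region + main_cds[region_lo + region_len :]
            bad = [c for c in codon_starts if trial[c : c + 3] in STOPS]
            if not bad:
                cand = trial
                break
            progressed = False
            for c in bad:
                for j in _overlapping_nested(c):
                    _resample(codons, j)
                    progressed = True
            if not progressed:
                # the stop involves only pinned characters: this main body
                # cannot host the plant, resample it upstream
                raise GenerationError(
                    f"fixed-region main-frame stop at ORF nt {c + 1} blocks the plant"
                )
        if cand is None:
            continue
        nested_str = "".join(codons)
        scoreable = model is not None and len(nested_str) - 3 >= 9
        llr = score_sequence(nested_str[:-3], model) if scoreable else 0.0
        if best is None or llr > best[0]:
            best = (llr, cand)
        if model is None:
            break
    if best is None:
        raise GenerationError(f"could not plant anrf at offset {off} without a main-frame stop")
    return best[1], peptide


def _stamp_pp_block(seq: str, block_start0: int, length: int, rng: np.random.Generator) -> str:
    """Overwrite ``length`` positions with purines, flanked by C so the run
    is maximal and its coordinates exact."""
    purines = "".join("AG"[i] for i in rng.integers(0, 2, length))
    return seq[: block_start0 - 1] + "C" + purines + "C" + seq[block_start0 + length + 1 :]


# ---------------------------------------------------------------------------
# transcript assembly


def _assemble_once(
    tid: str, spec: PlantSpec, rng: np.random.Generator, model: Optional[HexamerModel]
) -> tuple[Transcript, ManifestEntry]:
    main_up, main_down = (
        (FAVORABLE_UP, FAVORABLE_DOWN)
        if spec.main_context_class == "favorable"
        else (UNFAVORABLE_UP, UNFAVORABLE_DOWN)
    )
    # main ORF: ATG + stamped second codon + sampled codons + stop
    body = _sample_coding(spec.main_len_aa - 2, rng)
    main_cds = "ATG" + main_down + body + STOPS[rng.integers(0, 3)]

    peptide = None
    if spec.anrf is not None:
        main_cds, peptide = plant_anrf(main_cds, spec.anrf, rng, model)
        if spec.anrf.pp_block is not None:
            b = spec.anrf.pp_block
            block_start0 = spec.anrf.offset_in_orf - 1 - b.distance - b.length
            main_cds = _stamp_pp_block(main_cds, block_start0, b.length, rng)
            if not _main_frame_stop_free(main_cds, spec.main_len_aa):
                raise GenerationError("pp stamp introduced a main-frame stop")

    # 5'-UTR: optional uORF at the very 5' end, main-context stamp at the end
    for _ in range(MAX_ATTEMPTS):
        utr5 = _sample_noncoding(spec.utr5_len, rng)
        if spec.uorf is not None:
            utr5 = spec.uorf + utr5[len(spec.uorf):]
        utr5 = utr5[:-5] + main_up
        stray = [
            i for i in range(len(utr5) - 2)
            if utr5[i : i + 3] == "ATG" and not (spec.uorf is not None and i == 0)
        ]
        if not stray:
            break
    else:
        raise GenerationError("could not sample a 5'-UTR free of stray AUGs")

    utr3 = _sample_noncoding(spec.utr3_len, rng)
    t = Transcript(id=tid, seq=utr5 + main_cds + utr3)

    main_start = spec.utr5_len + 1
    entry = ManifestEntry(
        id=tid,
        utr5_len=spec.utr5_len,
        main_start=main_start,
        main_end=main_start + len(main_cds) - 1,
    )
    if spec.uorf is not None:
        entry.uorf_start, entry.uorf_end = 1, len(spec.uorf)
    if spec.anrf is not None:
        a = spec.anrf
        entry.anrf_start = spec.utr5_len + a.offset_in_orf
        entry.anrf_end = entry.anrf_start + 3 * (a.length_aa + 1) - 1
        entry.anrf_len_aa = a.length_aa
        entry.context_class = a.context_class
        entry.peptide_class = a.peptide_class
        if a.pp_block is not None:
            entry.pp_start = entry.anrf_start - a.pp_block.distance - a.pp_block.length
            entry.pp_len = a.pp_block.length
            entry.pp_distance = a.pp_block.distance
    return t, entry


def _screen_and_finalize(
    t: Transcript, entry: ManifestEntry, spec: PlantSpec,
    cfg: ScanConfig, model: Optional[HexamerModel],
) -> bool:
    """Reject accidental confounders; fill in expected scan outcomes."""
    main = find_main_orf(t)
    if (main.start, main.end) != (entry.main_start, entry.main_end):
        return False
    planted = (entry.anrf_start, entry.anrf_end)
    for orf in nested_sorfs(t, main, cfg.min_aa, cfg.max_aa):
        if (orf.start, orf.end) == planted:
            continue
        if extract_context(t, orf.start).favorable:
            return False
    if spec.anrf is not None and spec.anrf.pp_block is None:
        if find_polypurine(t, entry.anrf_start, cfg.pp_window, cfg.pp_min_len):
            return False

    if spec.anrf is not None:
        a = spec.anrf
        anrf_ctx = extract_context(t, entry.anrf_start)
        main_ctx = extract_context(t, main.start)
        favorable = anrf_ctx.favorable
        in_band = cfg.min_aa <= a.length_aa <= cfg.max_aa
        translatable = False
        if model is not None and 3 * a.length_aa >= 9:
            cds = t.seq[entry.anrf_start - 1 : entry.anrf_end - 3]
            entry.anrf_llr = score_sequence(cds, model)
            translatable = entry.anrf_llr >= cfg.coding_threshold
        entry.expected_passes_abc = in_band and favorable and translatable
        entry.expected_i = (
            anrf_ctx.weighted_score > main_ctx.weighted_score
            or (anrf_ctx.weighted_score == main_ctx.weighted_score
                and anrf_ctx.optimality_matches > main_ctx.optimality_matches)
        )
        entry.expected_ii = a.pp_block is not None and a.pp_block.distance < cfg.pp_window
        entry.expected_iii = (
            cfg.sig_min_aa <= a.length_aa <= cfg.sig_max_aa and a.peptide_class == "AH"
        )
    return True


def realize_plant(
    tid: str,
    spec: PlantSpec,
    rng: np.random.Generator,
    model: Optional[HexamerModel] = None,
    cfg: Optional[ScanConfig] = None,
) -> tuple[Transcript, ManifestEntry]:
    """Realize one transcript from a :class:`PlantSpec`, with screening."""
    spec.validate()
    cfg = cfg or ScanConfig()
    for _ in range(MAX_ATTEMPTS):
        try:
            t, entry = _assemble_once(tid, spec, rng, model)
        except GenerationError:
            continue
        if _screen_and_finalize(t, entry, spec, cfg, model):
            return t, entry
    raise GenerationError(f"could not realize a clean transcript for spec of {tid}")


# ---------------------------------------------------------------------------
# transcriptome-level generation


@dataclass
class GeneratorParams:
    """Distribution of plant specs across a synthetic transcriptome.

    Defaults mirror the layout of the reference KPI-like transcript: a 23-nt
    5'-UTR (start-stop uORF planted with probability ``p_uorf``), a 201-aa
    main ORF in an unfavorable start context, and — in a ``frac_anrf``
    fraction of transcripts — a favorable-context nested sORF in the 30-53 aa
    signature band with an AH peptide and an 18-25 nt polypurine block
    25-45 nt upstream.
    """

    frac_anrf: float = 0.5
    p_uorf: float = 0.5
    utr5_len: int = 23
    main_len_aa: int = 201
    utr3_len: int = 50
    anrf_len_range: tuple[int, int] = (30, 53)
    p_favorable_context: float = 1.0
    p_pp_block: float = 1.0
    p_ah: float = 1.0
    pp_len_range: tuple[int, int] = (18, 25)
    pp_distance_range: tuple[int, int] = (25, 45)


def _draw_spec(params: GeneratorParams, rng: np.random.Generator) -> PlantSpec:
    anrf = None
    if rng.random() < params.frac_anrf:
        length = int(rng.integers(params.anrf_len_range[0], params.anrf_len_range[1] + 1))
        pp = None
        if rng.random() < params.p_pp_block:
            pp = PpBlockSpec(
                length=int(rng.integers(params.pp_len_range[0], params.pp_len_range[1] + 1)),
                distance=int(rng.integers(params.pp_distance_range[0], params.pp_distance_range[1] + 1)),
            )
        room = (pp.length + pp.distance + 8) if pp else 12
        last = 3 * params.main_len_aa - 3 * (length + 1) + 1
        offsets = [o for o in range(max(room, 12), last + 1) if (o - 1) % 3 in (1, 2)]
        if not offsets:
            raise InfeasibleSpecError("no feasible anrf offset for the drawn plant")
        anrf = AnrfPlant(
            offset_in_orf=int(offsets[rng.integers(0, len(offsets))]),
            length_aa=length,
            context_class="favorable" if rng.random() < params.p_favorable_context else "unfavorable",
            pp_block=pp,
            peptide_class="AH" if rng.random() < params.p_ah else "non-AH",
        )
    return PlantSpec(
        utr5_len=params.utr5_len,
        uorf="ATGCATTAA" if rng.random() < params.p_uorf else None,
        main_len_aa=params.main_len_aa,
        anrf=anrf,
        utr3_len=params.utr3_len,
        main_context_class="unfavorable",
    )


def default_training_sets(
    rng: np.random.Generator, n_seqs: int = 200, seq_len: int = 300
) -> tuple[list[str], list[str]]:
    """Matched coding (codon-usage) and noncoding (uniform i.i.d.) training sets."""
    coding = [_sample_coding(seq_len // 3, rng) for _ in range(n_seqs)]
    noncoding = [_sample_noncoding(seq_len, rng) for _ in range(n_seqs)]
    return coding, noncoding


def default_model(seed: int) -> HexamerModel:
    """The generator's own coding-potential model (self-contained default)."""
    rng = np.random.default_rng(seed)
    coding, noncoding = default_training_sets(rng)
    return train_hexamer_model(
        coding, noncoding, trained_on=f"synthetic codon-usage/uniform sets, seed {seed}"
    )


def generate_transcriptome(
    n: int,
    params: Optional[GeneratorParams] = None,
    seed: int = 0,
    model: Optional[HexamerModel] = None,
    cfg: Optional[ScanConfig] = None,
    out_prefix: Optional[str | Path] = None,
) -> tuple[list[Transcript], list[ManifestEntry], HexamerModel]:
    """Generate ``n`` transcripts plus a ground-truth manifest.

    When ``out_prefix`` is given, ``<prefix>.fasta`` and ``<prefix>.manifest.tsv``
    are written. The returned model is the one used for the manifest's
    translatability expectations (trained from the seed when not supplied);
    scanning with the same model and config reproduces the manifest exactly.
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    if model is None:
        model = default_model(seed)
    transcripts: list[Transcript] = []
    manifest: list[ManifestEntry] = []
    for i in range(n):
        spec = _draw_spec(params, rng)
        t, entry = realize_plant(f"synth{i + 1:04d}", spec, rng, model, cfg)
        transcripts.append(t)
        manifest.append(entry)
    if out_prefix is not None:
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        write_fasta(transcripts, prefix.with_name(prefix.name + ".fasta"))
        write_manifest(manifest, prefix.with_name(prefix.name + ".manifest.tsv"))
    return transcripts, manifest, model


# ---------------------------------------------------------------------------
# manifest I/O and independent verification

_MANIFEST_COLUMNS = list(ManifestEntry.__dataclass_fields__)


def write_manifest(manifest: list[ManifestEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_MANIFEST_COLUMNS) + "\n")
        for e in manifest:
            row = []
            for col in _MANIFEST_COLUMNS:
                v = getattr(e, col)
                if v is None:
                    row.append(".")
                elif isinstance(v, float):
                    row.append(repr(v))
                else:
                    row.append(str(v))
            fh.write("\t".join(row) + "\n")


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            vals = dict(zip(header, line.rstrip("\n").split("\t")))
            kwargs = {}
            for col, raw in vals.items():
                if raw == ".":
                    kwargs[col] = None
                elif col in ("id", "context_class", "peptide_class"):
                    kwargs[col] = raw
                elif col.startswith("expected_"):
                    kwargs[col] = raw == "True"
                elif col == "anrf_llr":
                    kwargs[col] = float(raw)
                else:
                    kwargs[col] = int(raw)
            entries.append(ManifestEntry(**kwargs))
    return entries


def verify_manifest(transcripts: list[Transcript], manifest: list[ManifestEntry]) -> None:
    """Check every planted coordinate directly against the emitted sequence.

    Raises ``AssertionError`` on any mismatch; deliberately re-derives each
    feature from raw string operations rather than the scan machinery.
    """
    by_id = {t.id: t for t in transcripts}
    assert len(by_id) == len(transcripts), "duplicate transcript ids"
    for e in manifest:
        s = by_id[e.id].seq
        assert s[e.main_start - 1 : e.main_start + 2] == "ATG", f"{e.id}: main start"
        assert s[e.main_end - 3 : e.main_end] in STOPS, f"{e.id}: main stop"
        span = e.main_end - e.main_start + 1
        assert span % 3 == 0, f"{e.id}: main span"
        main_cds = s[e.main_start - 1 : e.main_end - 3]
        assert "*" not in translate_cds(main_cds), f"{e.id}: main-frame stop"
        if e.uorf_start is not None:
            u = s[e.uorf_start - 1 : e.uorf_end]
            assert u.startswith("ATG") and u[-3:] in STOPS, f"{e.id}: uorf"
            assert e.uorf_end < e.main_start, f"{e.id}: uorf not upstream"
        if e.anrf_start is not None:
            assert s[e.anrf_start - 1 : e.anrf_start + 2] == "ATG", f"{e.id}: anrf start"
            assert s[e.anrf_end - 3 : e.anrf_end] in STOPS, f"{e.id}: anrf stop"
            assert (e.anrf_end - e.anrf_start + 1) == 3 * (e.anrf_len_aa + 1), f"{e.id}: anrf span"
            cds = s[e.anrf_start - 1 : e.anrf_end - 3]
            assert "*" not in translate_cds(cds), f"{e.id}: anrf internal stop"
            assert (e.anrf_start - e.main_start) % 3 in (1, 2), f"{e.id}: anrf frame"
            window_up = s[e.anrf_start - 6 : e.anrf_start - 1]
            expected_up = FAVORABLE_UP if e.context_class == "favorable" else UNFAVORABLE_UP
            assert window_up == expected_up, f"{e.id}: context stamp"
            if e.pp_start is not None:
                block = s[e.pp_start - 1 : e.pp_start - 1 + e.pp_len]
                assert set(block) <= {"A", "G"}, f"{e.id}: pp purity"
                assert s[e.pp_start - 2] not in "AG", f"{e.id}: pp left flank"
                assert s[e.pp_start - 1 + e.pp_len] not in "AG", f"{e.id}: pp right flank"
                assert e.pp_start + e.pp_len + e.pp_distance == e.anrf_start, f"{e.id}: pp distance"
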