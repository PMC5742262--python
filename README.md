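# anrfscan

Detection of **alternative nested reading frames (ANRFs)** — "matryoshka
gene" organization — in transcript sequences.

Some plant mRNAs carry a second, translatable short ORF *inside* their main
protein-coding ORF, read in a shifted (+1/+2) frame on the same strand. In
the *Solanaceae* Kunitz-peptidase-inhibitor-like (KPILP) gene group this
nested ORF encodes a 30–53 aa membrane-targeted peptide with an amphipathic
helix, its AUG sits in a stronger Kozak context than the main start codon,
and an 18–25 nt polypurine block lies a few tens of nucleotides upstream —
a configuration that lets the nested peptide repress accumulation of its
own maternal mRNA. `anrfscan` is a desk-scale scanning pipeline for this
signature, aimed at anyone annotating transcriptomes for dual-coding
candidates.

## What the scan computes

For each transcript the pipeline locates the main ORF (annotated hint, or
longest AUG-initiated ORF), inventories 5′-UTR uORFs, and evaluates every
alternative-frame nested sORF against three **scan criteria**:

* **(a)** encoded product of 10–100 aa;
* **(b)** translatable: mean in-frame hexamer log-likelihood ratio
  `LLR = (1/n) Σ ln(f_coding(h) / f_background(h)) ≥ 0` under a trained
  dicodon-hexamer model;
* **(c)** AUG in a favorable Kozak context, consensus `aMN-AUG-gS`
  (M = A/C, N = any, S = G/C; constrained positions −3, −2, +4, +5).

Candidates passing (a)–(c) are ANRFs; each is further annotated with the
three-part **matryoshka signature**: (i) start context strictly stronger
than the main ORF's (weighted consensus score, dicot-optimum
`aaA(A/C)a-AUG-GCu` as tie-break), (ii) a ≥18-nt polypurine block ending
within 60 nt upstream of the nested AUG, (iii) a 30–53 aa peptide whose
Eisenberg hydrophobic moment

```
μH = (1/w) √[ (Σᵢ Hᵢ sin iδ)² + (Σᵢ Hᵢ cos iδ)² ],   δ = 100°/residue, w = 18
```

reaches 0.4 with non-negative window-mean hydrophobicity.

A synthetic-transcriptome generator (`simulate`) plants all of these
features with a ground-truth manifest, so every stage is testable without
downloads.

## Worked example

Generate ten synthetic transcripts (five with planted nested sORFs) and
scan them:

```
$ anrfscan simulate --n 10 --seed 3 --out demo
wrote 10 transcripts (5 with planted nested sORFs) to demo.*

$ anrfscan scan --fasta demo.fasta --model demo.model.tsv --out scanout
scanned 10 transcripts: 5 ANRF(s) on 5 matryoshka transcript(s)

$ anrfscan stats --reports scanout
transcripts scanned     10
ANRFs   5
matryoshka transcripts  5
% with 1 ANRF   100.0
% with 2 ANRFs  0.0
% with >=3 ANRFs        0.0
```

`scanout.candidates.tsv` holds one row per nested sORF with its context
window (11 characters, `?`-padded at transcript edges), consensus and
optimality scores, coding LLR, polypurine blocks (`start:length:distance`),
maximum μH, and the per-criterion calls; `scanout.features.gff3` carries
`main_ORF` / `uORF` / `ANRF` features in 1-based inclusive coordinates, and
`scanout.summary.txt` the ANRF-count distribution. On the reference KPI-like
layout (23-nt 5′-UTR opening with the start-stop uORF `AUG-CAU-UAA`, 606-nt
main ORF), the scan reports a 201-aa main protein and a single passing
candidate: a 53-aa nested ORF at main-ORF nt 407–568, i.e. with 429 nt
upstream of its AUG, context window `AGAAAATGGGA` (favorable, 4/4 consensus
matches), a 20-nt polypurine block 39 nt upstream, and a positive
amphipathic-helix call — signature-positive on all of (i)–(iii).

## Layout

```
src/anrfscan/
  seqio.py              FASTA ingestion, ORF enumeration, main/nested/uORF logic
  start_context.py      Kozak consensus + dicot-optimality scoring
  coding_potential.py   hexamer LLR translatability model
  upstream_features.py  polypurine-block detection
  amphipathicity.py     Eisenberg hydrophobic-moment profiling
  anrf_scan.py          per-transcript scan, summary, TSV/GFF3 output
  synthetic_data.py     planted-transcriptome generator + manifest verifier
  cli.py                `anrfscan` command group (scan / stats / simulate / train-model)
```

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
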