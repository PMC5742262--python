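# Methods

## Scope and model

`anrfscan` detects nested alternative-frame short ORFs (ANRFs) on the
forward (mRNA sense) strand of transcript sequences and classifies the
"matryoshka" signature described for the KPI-like gene group. The unit of
analysis is a single transcript; splicing, genomic context and non-AUG
starts are out of scope (the gene family motivating the design is
intronless, and the biological ANRFs initiate at AUG). Reverse-strand
scanning is deliberately omitted: the repression mechanism the signature
reflects operates on the sense transcript, and scanning the antisense
strand of an mRNA has no comparable interpretation.

### ORF model (`seqio`)

An ORF is AUG…first-in-frame-stop, reported in 1-based inclusive
coordinates with the stop codon inside the span but outside the peptide, so
a 606-nt ORF encodes 201 aa and a 162-nt nested ORF encodes 53 aa. The main
ORF is the annotated hint when supplied, else the longest AUG-initiated ORF
with ties broken 5′-most — the standard convention, and the one that
reproduces the annotated CDS of the reference transcript. A nested sORF
must start strictly downstream of the main AUG, end at or before the main
stop's last nucleotide, and lie at frame offset 1 or 2; in-frame internal
AUGs are truncations of the main product, not nested genes, and are
excluded. uORFs (any ORF ending before the main AUG, ≥1 aa) are reported
separately and never counted as ANRFs. Codons containing `N` never match a
start or stop codon — conservative and deterministic; `N`-containing codons
inside a peptide translate to `X`, and peptides with `X` receive no
amphipathicity call.

### Start-codon context (`start_context`)

The context window is upstream 5 nt + AUG + downstream 3 nt (positions
−5…−1, +4…+6), `?`-padded at transcript edges; `?` never matches. The
binary favorable call requires all four constrained positions of the plant
consensus `aMN-AUG-gS` (−3 = A, −2 = A/C, +4 = G, +5 = G/C). Because the
signature needs a *strict ordering* of two contexts and the consensus alone
is binary, a graded score doubles the two positions with the dominant
effect on initiation (−3 and +4), giving 0–6 with 6 ≡ favorable; ties are
broken by the match count (0–8) against the dicot optimal context
`aaA(A/C)a-AUG-GCu`, which is otherwise reporting-only. Both the weighting
and the tie-break are package design choices — documented, configurable,
and chosen so that the printed favorable reference context
(`agAaaAUGGga`) scores maximally.

### Coding potential (`coding_potential`)

Translatability is scored by a dicodon-hexamer log-likelihood ratio — the
classic CDS-likeness statistic of coding-potential tools — rather than by
any specific external predictor. In-frame (step-3) hexamer frequencies from
CDS-aligned coding training sequences and all-offset (step-1) frequencies
from noncoding training sequences are add-pseudocount smoothed (default 1)
over all 4096 hexamers; a candidate's score is the mean natural-log ratio
over its in-frame hexamers, stop codon excluded, and "translatable" means
score ≥ 0 (likelihood favors coding). A candidate must span ≥12 nt so at
least two hexamers exist. This stage is the one place where scan *counts*
depend on user-supplied training data; by default the model is trained on
the synthetic generator's own coding/noncoding output so the package is
self-contained, and models serialize to a flat hexamer/frequency text
format for reproducibility.

### Polypurine blocks (`upstream_features`)

A block is a maximal uninterrupted A/G run of ≥18 nt whose last nucleotide
falls within a window upstream of the nested AUG. The window defaults to
60 nt because the observed distances in the gene group are quoted both as
"~30 nt" and "39 nt"; 60 covers both with margin and is a flag. Runs longer
than 25 nt are reported at true length — the 18–25 nt figure is treated as
the observed range across the characterized genes, not a cap — and the
report annotates whether any block lies inside that band. Interruption
tolerance defaults to zero (a polypurine block with no stated mismatch
allowance is taken literally).

### Amphipathicity (`amphipathicity`)

Membrane-targeted amphipathic-helix character is quantified by the
Eisenberg hydrophobic moment on the consensus scale, δ = 100°/residue
(ideal α-helix) over 18-residue windows (≈5 helical turns, and no longer
than the shortest 30-aa signature peptide). The AH call requires max
μH ≥ 0.4 — the conventional boundary in hydrophobic-moment-plot analyses —
*and* non-negative mean hydrophobicity over the best window; the
co-threshold is an explicit, declared stand-in for a transmembrane-topology
prediction, which this package does not attempt. At w·δ = 1800° the moment
of any homopolymer vanishes in exact arithmetic; floating-point sine sums
leave residuals near 1e−15, so tests assert |μH| ≤ 1e−12.

### The scan (`anrf_scan`)

Criteria (a) length 10–100 aa, (b) translatable, (c) favorable context are
evaluated per candidate; a transcript is matryoshka when ≥1 candidate
passes all three. Signature criteria are annotated per candidate:
(i) context strictly stronger than the main ORF's, (ii) any qualifying
polypurine block in the window, (iii) peptide in the 30–53 aa signature
band with a positive AH call. All candidates are reported regardless of
outcome; row order is (transcript id, start), making TSV/GFF3/summary
output byte-deterministic for fixed input, config and seed. Percentages in
the ANRF-count distribution are rounded to one decimal; the full histogram
is always reported alongside them so grouped classes ("3 or more") stay
unambiguous.

## Synthetic data and what passing tests mean

The generator emulates the layout the scan assumes: a 23-nt 5′-UTR
(optionally opening with the start-stop uORF AUG-CAU-UAA), a 201-aa main
ORF whose AUG sits in a deliberately weak context, optionally one nested
alternative-frame sORF (default 30–53 aa, favorable context, AH peptide,
18–25 nt polypurine block 25–45 nt upstream), and a 50-nt 3′-UTR. These
defaults mirror the characterized reference transcript; sample size for the
end-to-end recovery suite is 100 transcripts with plants in roughly half —
large enough that every feature combination is exercised while the whole
suite runs in seconds.

Main-ORF codons are drawn from a stylized codon-usage table: per amino acid
one *shift-safe* preferred codon (no T in a position that can seed a stop
codon in an overlapping frame — echoing the pyrimidine-ending bias of
highly expressed genes) at weight 0.7, the rest sharing 0.3. No
species-realism is claimed; any user table is accepted, with the caveat
that the coding model must be trained to match (a uniform-synonymous table
carries so little hexamer information that translatability calls on short
peptides become unstable). Noncoding regions are i.i.d. uniform
nucleotides. Planted nested sORFs draw their codons from the same table *in
the nested frame*, choosing synonyms greedily by hexamer LLR while keeping
the main frame stop-free (bounded local repair, then bounded best-of-10
resampling), so plants carry the same signal the model is trained on —
in-band plants measure ≈1.5 nat/hexamer. AH peptides are deterministic
periodic designs (hydrophobic face {L,I,F,V}, polar face {K,S,E,T},
period 3.6 residues) verified against the classifier at build time; non-AH
plants are seeded scrambles verified to fall below threshold.

The manifest records every planted coordinate plus the expected scan
outcome. Context, length, polypurine and AH expectations follow from the
construction; the translatability expectation is *measured* at generation
time with the same model the matched scan will use. To keep the manifest an
exact ground truth the generator rejection-samples (bounded at 1000
attempts, seeded) realizations with accidental confounders: stray UTR AUGs,
favorable-context in-band nested sORFs other than the plant, a longest ORF
different from the planted main, or chance ≥18-nt purine runs in the window
when no block was requested. An independent verifier re-derives every
manifest coordinate from raw string operations.

Passing the recovery suite therefore shows that the scan recovers exactly
what was planted under matched thresholds and rejects out-of-band plants —
it does **not** show that real transcriptome scan counts are reproduced.
Real 5′-UTRs contain uncontrolled uORFs, real codon usage and hexamer
composition differ from the stylized table, and the translatability
criterion here is a hexamer LLR, not the external predictor used for the
published transcriptome totals; those totals (hundreds of thousands of
sORFs, ~1.4 k ANRFs) additionally depend on a specific external
transcriptome assembly and are explicit non-goals.

## Numerical choices and degenerate inputs

* Natural logarithms throughout; hexamer tables sum to 1 within 1e−9.
* Unknown hexamers score at the pseudocount floor; hexamers containing `N`
  are skipped in both training and scoring.
* Empty profile (peptide shorter than the window) ⇒ AH call false, not an
  error; zero matryoshka transcripts ⇒ percentages reported absent rather
  than 0/0.
* Ties in main-ORF selection go to the smaller start coordinate; ties in
  context comparison are *not* "more favorable" (strictness on both the
  weighted score and the optimality tie-break).
* All randomness flows through a single seeded `numpy` generator per run;
  identical seed ⇒ byte-identical FASTA, manifest, TSV, GFF3 and summary.

## Known limitations

* Forward strand only; one transcript at a time; no splice awareness.
* The hexamer LLR is a generic CDS-likeness measure: absolute
  translatability calls shift with the training sets supplied.
* The AH stage scores helical amphipathicity only; it is not a
  transmembrane-topology or structure predictor, and the mean-hydrophobicity
  co-threshold is a coarse proxy for membrane association.
* The polypurine detector requires uninterrupted runs; a single pyrimidine
  interruption splits a block.
* The synthetic generator plants at most one nested sORF per transcript, so
  multi-ANRF count classes arise only in real data.
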