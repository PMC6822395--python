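# Methods

This note documents the models, conventions and design choices behind
`tenest`, in the order the pipeline runs them.

## Coordinates and formats

All internal coordinates are 0-based, half-open, matching the native start
convention of the UCSC `rmsk.txt` / `refGene.txt` dumps and of BED;
conversion to 1-based closed happens only at report boundaries
(`io_formats.to_one_based`).  Tables are accepted with or without the
leading `bin` column (auto-detected by column count) and transparently
gzip-decompressed.  RepeatMasker's `C` strand notation is normalised to
`-`; unknown `repClass` values are preserved verbatim.  FASTA parsing goes
through Biopython; characters outside {A,C,G,T,N} are rejected by default
or masked to N on request.

## Combination detection

Annotation rows are grouped by `(chrom, id, repName, strand)`; a group
with more than one row is a *fragmented* element — the annotation
signature of an insertion that was itself disrupted.  "Together" is
defined two ways, because nesting and adjacency have different biology:

* **nested** — the guest's span lies strictly inside the outer span of a
  fragmented host.  This is the configuration of sequential integration
  and is the default analysis.
* **adjacent** — consecutive elements with `gap <= max_gap` (default 0).
  Kept configurable for sensitivity analysis; nested takes precedence and
  a pair is reported at most once.

Counts are reported both per assembled element and per raw row, since the
two differ exactly by fragmentation.  Queries match `repName` or
`repFamily` exactly and case-sensitively, as in rmsk.

## TPRT hallmarks

The poly-A tract is measured immediately outside the element's 3' end
(A-run after the end on `+`, T-run before the start on `-`).  The default
is a pure homopolymer run; the purity threshold is exposed
(`polya_purity`, with 0.8 a reasonable relaxed setting for real, decayed
tails) and tracts shorter than `polya_min_len` (default 8 nt) are reported
as 0.  The default is strict because a pure run makes the reported length
a well-defined quantity; relaxed purity makes it depend on where a
fraction dips below threshold.

The TSD search then compares the flank 5' of the element with the
sequence just past the poly-A, taking the longest duplication of length
2–20 with at most `max_mismatch` mismatches (default 0).  TSDs shorter
than 5 bp are flagged low-confidence: terminal matches that short arise
easily by chance, and a 3-nt candidate should be treated as suggestive
only.

## Genomic context

A combination is *intragenic* only when fully contained in a transcript —
the conservative reading of "inside the gene"; partial overhang is
intergenic.  Intronic means zero exonic base overlap.  Intron ordinals
are transcription-order (strand-aware) by default, so "intron 4" is the
4th intron transcribed; genomic-order indexing is available via
`transcription_order=False`.  One call is emitted per containing
transcript (no isoform collapsing); non-coding (NR_-style) transcripts
are included like any other.

## Exonization

Only canonical AG/GT dinucleotides are considered.  Candidate exons pair
every acceptor with every transcript-downstream donor within length
bounds (default 25–500 nt, the scale of SINE-derived cassette exons);
several acceptors sharing one donor give several candidates — the
alternative-3'SS situation.  ORF finding uses the first-start rule: among
ATG-initiated frames that reach an in-frame stop, the one whose ATG is
5'-most is reported; no minimum ORF length is imposed by default.
`compare_peptides` flags a premature stop whenever the shared prefix ends
before the reference's C-terminus — covering both outright truncation and
a frame-shifted, longer-but-different C-terminus, which both destroy the
reference's terminal domain.

## Branch-point model

The scorer is a deliberately transparent stand-in for trained tools
(BPP, svm-BPfinder): a PWM over a 7-nt window whose 6th position is the
BP adenosine, built from a yUnAy-style mammalian consensus (frequencies
in `DEFAULT_PWM_FREQS`, log-odds vs uniform background, pseudocount
0.01); plus a distance prior that is 0 inside the canonical 21–25 nt band
and decreases by `distance_penalty` (default 0.05) per nt outside it;
plus `py_weight` (default 1.0) times the pyrimidine fraction between BP
and 3'SS (the U2AF65 rationale).  Distance is counted from the candidate
A to the intron's 3' end inclusive, so the A immediately before the AG
has distance 3.  The search window is 15–100 nt, covering the canonical
region with margin.  Ties break toward the 3'SS.  Scores are not
comparable to BPP/svm-BPfinder scores; candidate *rankings* are the
reproducible output, and all weights round-trip through YAML.

## Insertion dating

Single-gain, no-loss (Dollo): a retrotransposon insertion arises once and
is never precisely excised, so carriers must form a clade and the
insertion happened on that clade's stem.  The inferred window is
[age(clade root), age(parent)], open above on the root stem.  Profiles
violating monophyly raise a typed `HomoplasyError` rather than attempting
loss-aware reconstruction.  `unknown` taxa are excluded from the
monophyly test but reported.  Amplicon-size profiling classifies a band
within tolerance of the insertion-bearing expectation as present, of the
empty-site expectation as absent, and anything else (including a missing
band) as unknown — sizes alone can mislead when an unrelated insertion of
similar length sits in the amplicon, which is exactly the failure mode
the `unknown` state exists for.

The packaged 10-leaf primate tree (hominoids; four Old World monkeys; two
New World monkeys; a lemur) treats its calibrations — root 63 myr,
catarrhine/platyrrhine 40 myr, hominoid/cercopithecoid 25 myr, with
conventional values for the uncalibrated internal splits — as exact
inputs; interval semantics of "approximately" are not modelled.

## Synthetic data: what it emulates and what it does not

The generator plants, deterministically per seed: solo and nested
insertions (a nested host is always emitted as exactly two fragments
sharing a linkage id); TSDs of 4–16 bp (within the 2–20 bp definition)
and poly-A tails of 8–30 nt, literally present in the emitted sequence;
host divergence 0.30 (mid range of an ancient MIR's 25–35%) and guest
divergence 0.10; and, in genes, an antisense nested pair in the 4th
intron carrying an AG in the guest, a GT in the downstream host fragment,
and the PWM-consensus branch-point heptamer 21–25 nt upstream of the AG
with a pyrimidine-rich tract.  Host and guest consensi are fixed
*synthetic* toy sequences of realistic SINE lengths (262 and 300 nt), not
Repbase extracts.

Divergence is substitution-only (each hit site moves to a different base,
so the expected observed divergence equals the rate); an indel mode
exists on `apply_divergence` but the simulator never uses it, keeping
every planted coordinate exactly reconcilable with the truth manifest.
Two generator conventions exist purely to make ground truth unambiguous:
the duplicated target site never starts with the tail base (so the
planted tail length equals the observed homopolymer run) and is mildly
aperiodic (so the duplication length is unique).  Consequences for
interpretation: passing tests demonstrate algorithmic correctness on
annotations whose fragment ids are intact and whose hallmarks are
unweathered; they do not measure robustness to annotation errors, indel
decay, or hallmark erosion in real genomes.

`make_v1_v2_locus` additionally builds a fully controlled two-acceptor
locus: the TE region is scrubbed of all AG/GT before planting exactly two
acceptors sharing one donor, the reference mRNA is constructed as
19 nt 5'UTR + 429 nt CDS (142 codons + stop) + 760 nt 3'UTR over five
exons with the CDS ending inside the last exon, and candidate exons carry
stop codons in all three frames — so exonization provably diverges the
peptide and terminates it prematurely, independent of the random seed.

## Problem sizes and numerical choices

The test suite runs the detection stack on twenty 1-Mb genomes with ≥20
planted nested pairs each (seeds 1–20), classification against a
per-base oracle on 1,000 combination/gene pairs, branch-point scoring
against an exhaustive re-scorer on 200 random introns and a 500-trial
planted-recovery experiment; the whole suite completes in a few seconds.
Ultrametricity is checked to a relative tolerance of 1e-6; the
branch-point PWM uses natural logs; `percent_same` uses banker-free
`round()` on a single value.  Degenerate inputs follow typed errors
throughout (empty presence sets, non-monophyletic profiles, insufficient
flanks, infeasible packing, malformed table lines with line numbers).

## Known limitations

No indel-aware coordinate reconciliation; no loss-aware (non-Dollo)
dating; no non-canonical splice sites; no trained splice-strength or BP
models; no multi-fragment (>2) nesting in the generator; no network
fetching of real annotations.  The CLI `full` pipeline reports candidate
counts on *unscrubbed* simulated TEs, where chance AG/GT motifs are
abundant — that count is a property of random sequence, not a prediction
of functional exons.
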