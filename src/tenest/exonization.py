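"""TE-derived exonization candidates, transcript assembly and peptide effects.

An antisense SINE pair inside an intron can donate everything a new exon
needs: an AG splice acceptor (3'SS), a downstream GT donor (5'SS), and —
scored separately in :mod:`tenest.branchpoint` — a branch point with a
polypyrimidine tract.  This module enumerates such candidate exons, splices
them into reference transcripts, finds the first-start ORF of the resulting
mRNA, and reports how the variant peptide departs from the reference.

Positions are genomic, 0-based; a splice-site ``position`` is the leftmost
genomic base of the dinucleotide, whose letters are always reported as read
5'→3' on the *gene's sense strand* (so an acceptor of a − strand gene
appears as ``CT`` in the genome).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from Bio.Seq import Seq, reverse_complement

from .io_formats import SequenceRecord

__all__ = [
    "SpliceSite",
    "ExonizationCandidate",
    "TranscriptModel",
    "PeptideReport",
    "PeptideComparison",
    "scan_splice_sites",
    "enumerate_candidates",
    "splice_in",
    "make_transcript",
    "find_first_orf",
    "compare_peptides",
]

MIN_EXON_LEN = 25
MAX_EXON_LEN = 500


def _seq_of(genome: Union[str, SequenceRecord]) -> str:
    return genome.seq if isinstance(genome, SequenceRecord) else genome


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class SpliceSite:
    kind: str                     # "acceptor_3ss" | "donor_5ss"
    position: int                 # genomic start of the dinucleotide
    dinucleotide: str             # on the gene's sense strand: AG or GT
    source_te: Optional[str] = None

    def __post_init__(self):
        if self.kind == "acceptor_3ss":
            if self.dinucleotide != "AG":
                raise ValueError("acceptor must be AG")
        elif self.kind == "donor_5ss":
            if self.dinucleotide != "GT":
                raise ValueError("donor must be GT")
        else:
            raise ValueError(f"bad kind {self.kind!r}")


@dataclass
class ExonizationCandidate:
    """A candidate intronic exon bounded by an AG acceptor and GT donor."""

    acceptor: SpliceSite
    donor: SpliceSite
    exon_start: int               # genomic, 0-based half-open
    exon_end: int
    strand: str                   # gene sense strand
    gene: Optional[str] = None
    intron_index: Optional[int] = None
    branch_point: Optional[object] = None  # BranchPointPrediction
    label: Optional[str] = None

    @property
    def length(self) -> int:
        return self.exon_end - self.exon_start


@dataclass
class TranscriptModel:
    """A spliced transcript: ordered genomic exons plus the mRNA they yield."""

    exons: list[tuple[int, int]]  # genomic order, 0-based half-open
    strand: str
    mrna: str
    inserted: Optional[tuple[int, int]] = None  # the candidate exon, if any

    def __post_init__(self):
        if len(self.mrna) != sum(e - s for s, e in self.exons):
            raise ValueError("spliced length must equal sum of exon lengths")


@dataclass
class PeptideReport:
    """The first-start ORF of an mRNA and its translation."""

    orf_start: Optional[int]      # mRNA coordinates, stop codon included
    orf_end: Optional[int]
    peptide: Optional[str]

    @property
    def found(self) -> bool:
        return self.peptide is not None

    @property
    def length_aa(self) -> Optional[int]:
        return len(self.peptide) if self.peptide is not None else None


@dataclass
class PeptideComparison:
    """How a variant peptide departs from a reference peptide."""

    divergence_point: Optional[int]  # 1-based first differing aa, or None
    shared_prefix_len: int
    premature_stop: bool


# ---------------------------------------------------------------------------
# Splice-site scanning and candidate enumeration
# ---------------------------------------------------------------------------

def scan_splice_sites(
    genome: Union[str, SequenceRecord],
    te_region: tuple[int, int],
    gene_strand: str = "+",
    source_te: Optional[str] = None,
) -> list[SpliceSite]:
    """All canonical AG/GT dinucleotides in a region, on the gene's sense strand.

    For a + strand gene the genome is scanned for AG and GT directly; for a
    − strand gene the genome is scanned for their reverse complements (CT
    and AC), since a sense-strand AG at genomic position p reads CT there.
    """
    seq = _seq_of(genome)
    start, end = te_region
    if not (0 <= start < end <= len(seq)):
        raise ValueError(f"region {te_region} outside the sequence")
    if gene_strand == "+":
        motifs = {"AG": "acceptor_3ss", "GT": "donor_5ss"}
    else:
        motifs = {"CT": "acceptor_3ss", "AC": "donor_5ss"}
    sites: list[SpliceSite] = []
    for p in range(start, end - 1):
        pair = seq[p:p + 2]
        kind = motifs.get(pair)
        if kind is None:
            continue
        dinuc = "AG" if kind == "acceptor_3ss" else "GT"
        sites.append(SpliceSite(kind=kind, position=p, dinucleotide=dinuc,
                                source_te=source_te))
    return sites


def enumerate_candidates(
    acceptors: Sequence[SpliceSite],
    donors: Sequence[SpliceSite],
    intron: tuple[int, int],
    strand: str = "+",
    min_len: int = MIN_EXON_LEN,
    max_len: int = MAX_EXON_LEN,
    gene: Optional[str] = None,
    intron_index: Optional[int] = None,
) -> list[ExonizationCandidate]:
    """Pair every acceptor with every downstream donor inside one intron.

    "Downstream" is in transcript orientation; several acceptors sharing a
    single donor yield several candidates that differ only at their 5' end
    — exactly the situation of two transcript variants using alternative
    3' splice sites.  The exon runs from the first base after the AG to
    the last base before the GT and must have length in
    ``[min_len, max_len]``.
    """
    i_start, i_end = intron
    out: list[ExonizationCandidate] = []
    for a in acceptors:
        if a.kind != "acceptor_3ss":
            raise ValueError("acceptors list contains a non-acceptor site")
        for d in donors:
            if d.kind != "donor_5ss":
                raise ValueError("donors list contains a non-donor site")
            if strand == "+":
                exon = (a.position + 2, d.position)
            else:
                exon = (d.position + 2, a.position)
            length = exon[1] - exon[0]
            if length < min_len or length > max_len:
                continue
            if not (i_start <= exon[0] and exon[1] <= i_end):
                continue
            out.append(ExonizationCandidate(
                acceptor=a, donor=d, exon_start=exon[0], exon_end=exon[1],
                strand=strand, gene=gene, intron_index=intron_index))
    out.sort(key=lambda c: (c.exon_start, c.exon_end))
    return out


# ---------------------------------------------------------------------------
# Transcript assembly
# ---------------------------------------------------------------------------

def make_transcript(
    genome: Union[str, SequenceRecord],
    exons: Sequence[tuple[int, int]],
    strand: str = "+",
    inserted: Optional[tuple[int, int]] = None,
) -> TranscriptModel:
    """Splice an mRNA from genomic exon intervals (transcript orientation)."""
    seq = _seq_of(genome)
    exons = sorted(exons)
    pieces = [seq[s:e] for s, e in exons]
    mrna = "".join(pieces)
    if strand == "-":
        mrna = reverse_complement(mrna)
    return TranscriptModel(exons=list(exons), strand=strand, mrna=mrna,
                           inserted=inserted)


def splice_in(
    genome: Union[str, SequenceRecord],
    reference_exons: Sequence[tuple[int, int]],
    candidate: ExonizationCandidate,
) -> TranscriptModel:
    """Insert a candidate exon between the reference exons flanking it.

    The candidate must fall strictly inside one reference intron; the new
    exon takes the correct ordinal and the mRNA is re-spliced from the
    genome.
    """
    exons = sorted(reference_exons)
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if e1 <= candidate.exon_start and candidate.exon_end <= s2:
            break
    else:
        raise ValueError(
            f"candidate exon [{candidate.exon_start}, {candidate.exon_end}) "
            "is not inside any reference intron")
    new_exons = sorted(exons + [(candidate.exon_start, candidate.exon_end)])
    return make_transcript(genome, new_exons, candidate.strand,
                           inserted=(candidate.exon_start, candidate.exon_end))


# ---------------------------------------------------------------------------
# ORFs and peptides
# ---------------------------------------------------------------------------

def find_first_orf(mrna: str) -> PeptideReport:
    """The ORF whose ATG is 5'-most among ORFs possessing an in-frame stop.

    Sense strand only, standard genetic code; the stop codon is included
    in the reported interval but excluded from the peptide.  When no
    ATG-initiated ORF reaches a stop, an absent report is returned.
    """
    if len(mrna) < 6:
        raise ValueError("mRNA shorter than 6 nt")
    mrna = mrna.upper()
    stops = {"TAA", "TAG", "TGA"}
    pos = mrna.find("ATG")
    while pos != -1:
        for j in range(pos, len(mrna) - 2, 3):
            codon = mrna[j:j + 3]
            if codon in stops:
                peptide = str(Seq(mrna[pos:j]).translate())
                return PeptideReport(orf_start=pos, orf_end=j + 3,
                                     peptide=peptide)
        pos = mrna.find("ATG", pos + 1)
    return PeptideReport(orf_start=None, orf_end=None, peptide=None)


def compare_peptides(reference: str, variant: str) -> PeptideComparison:
    """First divergence between a reference and a variant peptide.

    ``premature_stop`` flags a variant whose shared prefix ends before the
    reference's C-terminus: either it terminates earlier outright or its
    reading continues into a new, stop-derived C-terminal sequence — in
    both cases the reference C-terminus is lost.
    """
    shared = 0
    for r, v in zip(reference, variant):
        if r != v:
            break
        shared += 1
    if shared == len(reference) and shared == len(variant):
        return PeptideComparison(divergence_point=None,
                                 shared_prefix_len=shared,
                                 premature_stop=False)
    return PeptideComparison(
        divergence_point=shared + 1,
        shared_prefix_len=shared,
        premature_stop=shared < len(reference),
    )
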