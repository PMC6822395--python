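"""Classify TE combinations against gene models.

A combination is *intragenic* only when its full span lies inside a
transcript (the conservative reading of "inside the gene"); intragenic
combinations with zero exonic overlap are *intronic*, with the intron
ordinal counted in transcription order (strand-aware), so "intron 4" means
the 4th intron a polymerase transcribes, whichever strand the gene is on.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .io_formats import GeneModel
from .te_combination import TECombination

__all__ = ["ContextCall", "classify", "intron_of"]

logger = logging.getLogger(__name__)

INTERGENIC = "intergenic"
INTRONIC = "intragenic_intronic"
EXON_OVERLAP = "intragenic_exon_overlap"


@dataclass
class ContextCall:
    """The genomic context of one combination relative to one gene."""

    combination: TECombination
    status: str
    gene: Optional[str] = None
    intron_index: Optional[int] = None  # 1-based, transcription order

    def __post_init__(self):
        if self.status not in (INTERGENIC, INTRONIC, EXON_OVERLAP):
            raise ValueError(f"bad status {self.status!r}")
        if (self.intron_index is not None) != (self.status == INTRONIC):
            raise ValueError("intron_index present iff intragenic_intronic")


def intron_of(gene: GeneModel, position: int,
              transcription_order: bool = True) -> Optional[int]:
    """1-based intron ordinal containing ``position``, or None in an exon.

    With ``transcription_order`` (default) the index is strand-aware: for
    a − strand gene, intron 1 abuts the transcript's 5'-most exon, i.e.
    the genomically *last* exon.
    """
    if not (gene.tx_start <= position < gene.tx_end):
        raise ValueError(f"position {position} outside {gene.name}")
    genomic_index = None
    for i, (s, e) in enumerate(gene.exons):
        if s <= position < e:
            return None
        if position < s:
            genomic_index = i  # between exon i-1 and exon i (0-based)
            break
    if not genomic_index:  # inside/beyond terminal exons: not intronic
        return None
    n_introns = gene.n_exons - 1
    if transcription_order and gene.strand == "-":
        return n_introns - genomic_index + 1
    return genomic_index


def classify(
    combos: Iterable[TECombination],
    genes: Iterable[GeneModel],
    transcription_order: bool = True,
) -> list[ContextCall]:
    """Classify each combination: intergenic, intronic, or exon-overlapping.

    One call is emitted per (combination, containing gene) pair; a
    combination contained in no transcript yields a single intergenic
    call.  Chromosomes present in the combinations but absent from the
    gene table are logged and classified intergenic.
    """
    genes = list(genes)
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        by_chrom[g.chrom].append(g)
    for chrom, gs in by_chrom.items():
        trees[chrom] = IntervalTree.from_tuples(
            (g.tx_start, g.tx_end, gi) for gi, g in enumerate(gs))

    warned: set[str] = set()
    calls: list[ContextCall] = []
    for combo in combos:
        chrom, start, end = combo.chrom, combo.start, combo.end
        if chrom not in trees:
            if chrom not in warned:
                warned.add(chrom)
                logger.warning(
                    "chromosome %s absent from gene table; combinations "
                    "there are reported intergenic", chrom)
            calls.append(ContextCall(combo, INTERGENIC))
            continue
        containing = [
            by_chrom[chrom][iv.data]
            for iv in trees[chrom].overlap(start, end)
            if by_chrom[chrom][iv.data].tx_start <= start
            and end <= by_chrom[chrom][iv.data].tx_end
        ]
        if not containing:
            calls.append(ContextCall(combo, INTERGENIC))
            continue
        for gene in sorted(containing, key=lambda g: g.name):
            exonic = any(s < end and start < e for s, e in gene.exons)
            if exonic:
                calls.append(ContextCall(combo, EXON_OVERLAP, gene=gene.name))
            else:
                calls.append(ContextCall(
                    combo, INTRONIC, gene=gene.name,
                    intron_index=intron_of(gene, start, transcription_order)))
    return calls
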