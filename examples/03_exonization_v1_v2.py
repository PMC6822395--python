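"""The two-acceptor exonization scenario: alternative 3' splice sites.

A controlled locus carries an antisense nested TE pair in intron 4 of a
5-exon gene, with two AG acceptors in the guest sharing one GT donor in
the host.  Each acceptor defines a candidate exon; splicing either into
the reference transcript disrupts the reading frame and truncates the
original C-terminus.
"""

from tenest import (compare_peptides, enumerate_candidates, find_first_orf,
                    make_transcript, make_v1_v2_locus, scan_splice_sites,
                    splice_in)
from tenest.branchpoint import predict_best

locus = make_v1_v2_locus(seed=0)
gene = locus.gene
reference = make_transcript(locus.chrom.seq, gene.exons, gene.strand)
ref_orf = find_first_orf(reference.mrna)
print(f"reference mRNA: {len(reference.mrna)} nt "
      f"(19 nt 5'UTR + 429 nt CDS + 760 nt 3'UTR), "
      f"peptide {ref_orf.length_aa} aa")

sites = scan_splice_sites(locus.chrom.seq, locus.te_region, gene.strand)
candidates = enumerate_candidates(
    [s for s in sites if s.kind == "acceptor_3ss"],
    [s for s in sites if s.kind == "donor_5ss"],
    intron=(gene.exon_ends[3], gene.exon_starts[4]), strand=gene.strand)
print(f"candidate exons in intron 4: {len(candidates)}")

intron_start = gene.exon_ends[3]
for label, cand in zip(("V1-like", "V2-like"), candidates):
    variant = splice_in(locus.chrom.seq, gene.exons, cand)
    var_orf = find_first_orf(variant.mrna)
    cmp_ = compare_peptides(ref_orf.peptide, var_orf.peptide)
    bp = predict_best(locus.chrom.seq[intron_start:cand.acceptor.position + 2])
    print(f"{label}: exon {cand.length} nt -> {len(variant.exons)}-exon "
          f"transcript, peptide {var_orf.length_aa} aa, diverges at aa "
          f"{cmp_.divergence_point} (premature stop: {cmp_.premature_stop}); "
          f"branch point {bp.heptamer} at {bp.distance_to_3ss} nt "
          f"(canonical band: {bp.in_canonical_band})")
# the two candidates share their donor and 3' sequence but differ at the
# 5' end — the alternative-acceptor situation that yields two transcript
# variants from one TE combination
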