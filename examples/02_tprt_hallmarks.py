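"""Inspect TPRT hallmarks (TSD and poly-A tail) around planted insertions.

Target-primed reverse transcription leaves a short direct repeat (the
target-site duplication, 2-20 bp) flanking the insertion and a poly-A
tail at its 3' end; both are recovered from the raw genome sequence.
"""

from tenest import (SimulationConfig, assemble_elements, detect_tsd, simulate)

cfg = SimulationConfig(seed=4)
genome, repeats, genes, truth = simulate(cfg)
seqs = {r.id: r.seq for r in genome}
elements = {(e.chrom, e.frag_id, e.rep_name): e
            for e in assemble_elements(repeats)}

shown = 0
for planted in truth.planted_insertions:
    if planted.relation != "nested" or shown >= 5:
        continue
    guest = elements[(planted.chrom, planted.guest_frag_id, "AluSp")]
    hallmarks = detect_tsd(seqs[planted.chrom], guest)
    flag = " (low confidence)" if hallmarks.low_confidence else ""
    print(f"{planted.chrom}:{guest.start}-{guest.end} {guest.strand}  "
          f"TSD={hallmarks.tsd}{flag}  polyA={hallmarks.polya_len} nt  "
          f"[planted TSD={planted.guest_tsd}, "
          f"polyA={planted.guest_polya_len}]")
    shown += 1
# detected and planted hallmarks agree exactly at max_mismatch=0; TSDs
# shorter than 5 bp would be flagged low-confidence
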