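"""Derive the main ORF, protein, molecular weight and poly-A call.

find_morf picks the longest ATG-initiated ORF over all six frames; the
report mirrors a per-subunit summary table (residue count, average MW in
kDa, poly-A interval).
"""

from cysloop import (MotifPlan, TranscriptomeSpec, find_morf,
                     make_synthetic_transcriptome, transcript_report)

spec = TranscriptomeSpec(n_genes=1, motif_plan={"g00": MotifPlan()},
                         rng_seed=11)
truth = make_synthetic_transcriptome(spec)

models = [find_morf(t.seq, id=t.id) for t in truth.transcripts]
print(transcript_report(models).to_string(index=False))
print("\nEach row is one assembled transcript: its mORF coordinates, the "
      "translated protein length, its average molecular weight and the "
      "detected 3' poly-A interval.")
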