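"""Rule-based Cys-loop subunit characterization.

Three planted archetypes are annotated: an rdl-like anion subunit (PAR
motif, dieldrin/fipronil/picrotoxin/ivermectin sites), an nACh-alpha-like
cation subunit (vicinal Loop-C cysteines, acidic selectivity filters), and
a soluble AChBP-like protein with no transmembrane helices and a 16-residue
Cys-loop span.
"""

from cysloop import (MotifPlan, TranscriptomeSpec, annotate,
                     make_synthetic_transcriptome)

plans = {
    "g00": MotifPlan(),  # rdl-like: PAR, A2', T6', L9'
    "g01": MotifPlan(vicinal_cc=True,
                     tm2_prime_residues={-2: "S", -1: "E", 0: "Q",
                                         13: "V", 20: "E"}),
    "g02": MotifPlan(tm_count=0, cys_loop_gap=16),  # AChBP-like
}
spec = TranscriptomeSpec(n_genes=3, include_actin=False, motif_plan=plans,
                         rng_seed=31)
truth = make_synthetic_transcriptome(spec)

for gene in plans:
    rep = annotate(truth.transcript(gene).protein, id=gene)
    print(f"{gene}: class={rep.class_call}, Cys-loop span={rep.cys_loop_gap}, "
          f"vicinal CC={rep.vicinal_cc_loop_c}, TMs={rep.tm_count}, "
          f"PAR={rep.par_motif}, selectivity={rep.selectivity}")
    if rep.flags:
        on = [k for k, v in rep.flags.items() if v]
        print(f"      pharmacology sites: {', '.join(on) or 'none'}")
print("\nThe class call follows the field's rules: vicinal Loop-C "
      "cysteines with cation filters mark an alpha nACh subunit; an "
      "arginine at TM2 position 0' marks an anion channel; a subunit with "
      "no TM helices is AChBP-like.")
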