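"""The reading-frame rule on the classic deletion pair.

Builds a 79-exon synthetic transcript with the well-known exon 45/46/47
lengths (176/148/150 nt) and contrasts the in-frame three-exon deletion
(exons 45-47, 474 nt = 158 codons -> milder BMD) with the frameshifting
single-exon deletion (exon 45, 176 nt -> severe DMD).
"""

from dystrokit import (
    MiniGeneParams,
    apply_mutations,
    exon_span_length,
    frame_verdict,
    make_minigene,
    net_exonic_length_change,
    parse_mutation,
    translate_from,
)

lengths = [120] * 79
lengths[44], lengths[45], lengths[46] = 176, 148, 150
model = make_minigene(MiniGeneParams(n_exons=79, exon_lengths=tuple(lengths), seed=5))
print(f"model: {model.n_exons} exons, protein {model.protein_length} aa")

for text in ("exon45-47del", "exon45del"):
    ms = parse_mutation(text, model)
    net = net_exonic_length_change(ms, model)
    pr = translate_from(apply_mutations(model, ms))
    print(
        f"{text}: removes {-net} nt "
        f"({exon_span_length(model, ms.specs[0].exon_first, ms.specs[0].exon_last)} nt span), "
        f"net % 3 = {net % 3}, frame rule -> {frame_verdict(ms, model)}, "
        f"mutated protein {pr.length_aa} aa "
        f"({model.protein_length - pr.length_aa} codons lost)"
    )

print(
    "\nA deletion length divisible by 3 preserves the reading frame and the "
    "protein shrinks by exactly length/3 codons; any other length shifts the "
    "frame and translation hits an off-frame (hidden) stop early."
)
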