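"""A splice-site mutation that neutralises a downstream nonsense mutation.

Hand-builds a 6-exon mini-gene where exon 4's length is not a multiple of 3
and c.90C>A creates a stop codon in exon 5.  The donor-site mutation
c.85+1G>A skips exon 4, shifting the frame so the substituted base no
longer completes a stop codon — the nonsense change becomes a missense-like
change, while the frameshift itself is what truncates the product.
"""

from dystrokit import Exon, TranscriptModel, apply_mutations, parse_mutation, translate_from

exon_seqs = (
    "ATGGCTGAATCCGGACTTAAA",
    "GCCACCGACGAACTGCAT",
    "CTGGTGAACCGTATCGCAGACGAA",
    "GCAGTCCATGAATTGGCCAAGG",       # 22 nt: skipping it shifts the frame
    "ATTACGGTCTTCAAGCCATTGAGAAGG",  # codon 30 (TAC) sits at c.88-90
    "AAGCTTGCAGAACCATTGATTAA",
)
model = TranscriptModel(
    name="demo",
    exons=tuple(Exon(i, s) for i, s in enumerate(exon_seqs, 1)),
    cds_start=1,
    cds_end=135,
)
print(f"reference protein: {model.protein_length} aa")

for text in ("c.90C>A", "c.85+1G>A", "c.85+1G>A plus c.90C>A"):
    mt = apply_mutations(model, parse_mutation(text, model))
    pr = translate_from(mt)
    state = (
        "premature stop" if pr.premature_stop
        else "no stop reached" if pr.non_stop
        else "natural stop"
    )
    notes = "; ".join(note for _, note in mt.applied)
    print(f"{text:32s} -> {pr.length_aa:3d} aa ({state})  [{notes}]")

print(
    "\nAlone, c.90C>A truncates at codon 30 (nonsense).  With the exon-4 "
    "skip, the product is identical with or without the substitution: the "
    "skip changed the nonsense mutation into a harmless one-base difference "
    "read in a shifted frame."
)
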