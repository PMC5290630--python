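"""Mutated-protein diagrams as a multi-page PDF.

Draws the domain-coloured reference protein with mutated tracks for an
in-frame deletion, a frameshifting deletion and a tandem duplication, one
page per case, into protein_diagrams.pdf.
"""

from dystrokit import DomainMap, MiniGeneParams, apply_mutations, make_minigene, parse_mutation, translate_from
from dystrokit.viz import build_protein_diagram, draw_protein

lengths = [120] * 79
lengths[44], lengths[45], lengths[46] = 176, 148, 150
model = make_minigene(MiniGeneParams(n_exons=79, exon_lengths=tuple(lengths), seed=5))
dmap = DomainMap.default_dystrophin()

specs = []
for text in ("exon45-47del", "exon45del", "exon2dup"):
    ms = parse_mutation(text, model)
    mt = apply_mutations(model, ms)
    pr = translate_from(mt)
    spec = build_protein_diagram(model, dmap, mt, pr, title=text, labels=(text,))
    specs.append(spec)
    marker = f", premature stop marked at aa {spec.stop_marker_aa}" if spec.stop_marker_aa else ""
    print(f"{text}: mutated track {spec.mut_length_aa} aa{marker}")

out = draw_protein(specs, "protein_diagrams.pdf")
print(f"\nwrote {out}: reference track shows ABD / rod / cysteine-rich / "
      "C-terminal domains; hatched = deleted, orange = duplicated, red = "
      "novel frameshifted sequence.")
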