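"""Scoring exonic splicing enhancers and calling disruptive substitutions.

Loads the bundled (synthetic) SR-protein weight matrices, plants one
matrix's consensus motif inside a toy exon, and shows that mutating the
motif's strongest position drops the site below the calling threshold —
the signature of an ESE-disrupting substitution.  The phenotype classifier
keeps this rule off by default.
"""

from dystrokit import Exon, TranscriptModel, ese_disrupted, load_default_matrices, parse_mutation, score_window

matrices = load_default_matrices()
for m in matrices:
    print(f"{m.protein_name}: width {m.width}, threshold {m.threshold}, "
          f"consensus {m.consensus()} (max score {m.max_score:.2f})")

m = matrices[0]
pad = "GCTGCTGCT"
cds = "ATG" + pad + m.consensus() + pad + "GG" + "TAA"
model = TranscriptModel(name="toy", exons=(Exon(1, cds),), cds_start=1, cds_end=len(cds))

c0 = 3 + len(pad) + 1  # c-position of the planted motif start
site = cds[c0 - 1 : c0 - 1 + m.width]
print(f"\nplanted site at c.{c0}: {site}, score {score_window(m, site):.2f}")

pos = max(range(m.width), key=lambda i: max(m.weights[i]) - min(m.weights[i]))
c = c0 + pos
ref = cds[c - 1]
alt = "ACGT"[min(range(4), key=lambda j: m.weights[pos][j])]
sub = parse_mutation(f"c.{c}{ref}>{alt}").specs[0]
mut_site = site[:pos] + alt + site[pos + 1 :]
print(f"substitution c.{c}{ref}>{alt}: window becomes {mut_site}, "
      f"score {score_window(m, mut_site):.2f} (threshold {m.threshold})")
print(f"ese_disrupted -> {ese_disrupted(model, sub, [m])}")

print(
    "\nA substitution disrupts an ESE when a window scoring at or above "
    "threshold in the reference falls below it after the change; such exonic "
    "hits can cause exon skipping rather than acting at the protein level."
)
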