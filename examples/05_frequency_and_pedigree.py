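"""Top-N mutation histograms and a two-family pedigree figure.

Builds a small cohort table in memory, counts exact exon deletions and
duplications, renders the top-N histogram, and draws a BMD-father/DMD-son
pedigree next to a second family.
"""

import pandas as pd

from dystrokit import PatientRecord, mutation_frequency
from dystrokit.viz import draw_frequency_histogram, draw_pedigrees

texts = (
    ["exon45del"] * 5 + ["exon45-47del"] * 3 + ["exon48-52del"] * 2
    + ["exon2dup"] * 2 + ["exon8-9dup"] * 1 + ["c.100A>G"] * 2
)
cohort = [PatientRecord(patient_id=f"P{i}", mutation_text=t) for i, t in enumerate(texts)]

freq_del = mutation_frequency(cohort, kind="del", top_n=10)
freq_dup = mutation_frequency(cohort, kind="dup", top_n=5)
print("top exon deletions:")
print(freq_del.to_string(index=False))
print("\ntop exon duplications:")
print(freq_dup.to_string(index=False))

draw_frequency_histogram(freq_del, "top_deletions.pdf", title="top 10 exon deletions")
draw_frequency_histogram(freq_dup, "top_duplications.pdf", title="top 5 exon duplications")

ped = pd.DataFrame(
    [
        # BMD father (proband) with an inherited in-frame deletion; DMD son
        ("F1", "11", "0", "0", "M", "affected_BMD", "1"),
        ("F1", "12", "0", "0", "F", "carrier", "0"),
        ("F1", "21", "11", "12", "M", "affected_DMD", "0"),
        ("F2", "11", "0", "0", "F", "carrier", "0"),
        ("F2", "12", "0", "0", "M", "unaffected", "0"),
        ("F2", "21", "12", "11", "M", "affected_DMD", "1"),
        ("F2", "22", "12", "11", "F", "unaffected", "0"),
    ],
    columns=["family_id", "individual_id", "father_id", "mother_id", "sex", "status", "proband"],
)
out = draw_pedigrees(ped, "pedigrees.pdf")
print(f"\nwrote top_deletions.pdf, top_duplications.pdf and {out} "
      "(squares male, circles female; dark fill DMD, grey BMD, dot carrier).")
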