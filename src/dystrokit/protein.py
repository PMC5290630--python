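"""Translate mutated transcripts and count potential stop-gains.

Two of the three phenotype rules live on top of this module: the mutated
protein length (ambush-hypothesis threshold) and the number of potential
stop-gains — in-frame stop trinucleotides encountered when reading the whole
mutated transcript from the start codon, the idea being that hidden stop
codons in shifted frames terminate erroneous off-frame translation early.
A normal transcript reads exactly one stop (its natural terminator).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .mutations import MutatedTranscript
from .reference import STOP_CODONS


@dataclass(frozen=True)
class ProteinResult:
    """Outcome of translating one (possibly mutated) transcript.

    ``premature_stop``: translation terminated at a stop codon other than the
    natural terminator.  ``non_stop``: no stop codon before the end of the
    transcript.  For the unmutated reference both flags are False and
    ``stop_gain_count`` is 1.
    """

    protein_sequence: str
    length_aa: int
    premature_stop: bool
    non_stop: bool
    stop_gain_count: int

    def __post_init__(self) -> None:
        assert self.length_aa == len(self.protein_sequence)
        assert not (self.premature_stop and self.non_stop)


def count_stop_gains(mt: MutatedTranscript) -> int:
    """Count in-frame stop trinucleotides from the start codon to the end of
    the mutated transcript (any 3'UTR included; trailing partial codon
    ignored).  The natural terminator counts, so the reference value is 1.
    """
    if mt.transcript_absent or mt.cds_start is None:
        return 0
    seq = mt.sequence
    return sum(
        1
        for i in range(mt.cds_start - 1, len(seq) - 2, 3)
        if seq[i : i + 3] in STOP_CODONS
    )


def translate_from(mt: MutatedTranscript) -> ProteinResult:
    """Translate from the (possibly shifted) start codon to the first in-frame
    stop, using the standard genetic code.

    If no stop is reached, translation runs to the last complete codon and
    ``non_stop`` is set.  A transcript with no product (promoter lost, start
    codon destroyed) yields the length-0 sentinel, which downstream rules
    treat as the severe phenotype.
    """
    if mt.transcript_absent or mt.cds_start is None:
        return ProteinResult(
            protein_sequence="",
            length_aa=0,
            premature_stop=True,
            non_stop=False,
            stop_gain_count=count_stop_gains(mt),
        )
    tail = mt.sequence[mt.cds_start - 1 :]
    tail = tail[: len(tail) - len(tail) % 3]
    if len(tail) < 3:
        return ProteinResult("", 0, True, False, 0)
    aa = str(Seq(tail).translate())
    stop_idx = aa.find("*")
    if stop_idx == -1:
        return ProteinResult(
            protein_sequence=aa,
            length_aa=len(aa),
            premature_stop=False,
            non_stop=True,
            stop_gain_count=count_stop_gains(mt),
        )
    protein = aa[:stop_idx]
    stop_end_nt = mt.cds_start - 1 + 3 * (stop_idx + 1)  # last base of the stop
    premature = mt.cds_end is None or stop_end_nt != mt.cds_end
    return ProteinResult(
        protein_sequence=protein,
        length_aa=stop_idx,
        premature_stop=premature,
        non_stop=False,
        stop_gain_count=count_stop_gains(mt),
    )


def protein_fasta(name: str, result: ProteinResult) -> str:
    """Render a ProteinResult as a FASTA block (for export/visualization)."""
    seq = result.protein_sequence or "-"
    lines = [f">{name} length={result.length_aa}aa"]
    lines += [seq[i : i + 60] for i in range(0, len(seq), 60)]
    return "\n".join(lines) + "\n"
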