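"""Synthetic mini-genes and labeled patient cohorts.

Real dystrophin analyses need the 79-exon reference transcript and large
registry cohorts, neither of which ships with this package.  The simulator
replaces them with "mini-genes": randomly generated multi-exon transcripts
with a valid ORF (ATG start, single natural terminator, stop-free in-frame
3'UTR) and cohorts of patients carrying random mutations of the clinically
reported classes.  Every patient's ground-truth label is computed from the
mechanistic translation consequence of the mutation — severe (DMD) iff the
product is absent, truncated, never stops, or falls outside the allowed
length window; milder (BMD) otherwise — so label recovery by the classifier
is a well-defined target.

These cohorts emulate mutation mechanics, not human genetics: there are no
hotspots, no ascertainment bias, and class proportions are whatever the
parameters say.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classifier import BMD, DMD, ClassifierConfig
from .cohort import PatientRecord
from .mutations import MutationSet, apply_mutations, parse_mutation
from .protein import translate_from
from .reference import STOP_CODONS, Exon, TranscriptModel, save_model

_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
)
_STOPS = tuple(sorted(STOP_CODONS))


class GenerationError(RuntimeError):
    """Parameters admit no valid mini-gene within bounded retries."""


@dataclass(frozen=True)
class MiniGeneParams:
    """Knobs of the mini-gene generator.

    Defaults give a mid-sized model — 12 exons of 60..200 nt, about half of
    them of length 3n so in-frame and frameshifting exon deletions are both
    common, short UTRs, GC ~ 0.5 — which keeps every downstream rule
    exercisable while translating in well under a millisecond.
    """

    n_exons: int = 12
    exon_length_range: tuple[int, int] = (60, 200)
    frac_length_multiple3: float = 0.5
    gc_content: float = 0.5
    utr5_max: int = 30
    utr3_max: int = 30
    seed: int = 0
    #: explicit per-exon lengths (overrides the random draw; n_exons must match)
    exon_lengths: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.exon_length_range
        if self.n_exons < 2:
            raise ValueError("n_exons must be >= 2")
        if lo < 12 or hi < lo:
            raise ValueError("exon lengths must be >= 12 nt and lo <= hi")
        if self.exon_lengths is not None:
            object.__setattr__(self, "exon_lengths", tuple(self.exon_lengths))
            if len(self.exon_lengths) != self.n_exons:
                raise ValueError("exon_lengths must have n_exons entries")
            if any(l < 12 for l in self.exon_lengths):
                raise ValueError("explicit exon lengths must be >= 12 nt")
        if not 0 <= self.frac_length_multiple3 <= 1:
            raise ValueError("frac_length_multiple3 must be in [0, 1]")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")


def make_minigene(params: MiniGeneParams) -> TranscriptModel:
    """Generate a TranscriptModel satisfying all model invariants.

    The 5'UTR occupies the start of exon 1 and the 3'UTR the end of the last
    exon; the in-frame triplets of the 3'UTR avoid stop codons so the
    unmutated transcript reads exactly one in-frame stop (its natural
    terminator) all the way to the transcript end.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.exon_length_range

    if params.exon_lengths is not None:
        lengths = list(params.exon_lengths)
    else:
        drawn = rng.integers(lo, hi + 1, size=params.n_exons)
        want3 = rng.random(params.n_exons) < params.frac_length_multiple3
        for i in range(params.n_exons):
            r = int(drawn[i]) % 3
            if want3[i] and r:
                drawn[i] = max(int(drawn[i]) - r, 12)
            elif not want3[i] and int(drawn[i]) % 3 == 0:
                drawn[i] += 1
        lengths = [int(x) for x in drawn]
    total = sum(lengths)

    utr5 = int(rng.integers(0, params.utr5_max + 1))
    utr3 = int(rng.integers(3, params.utr3_max + 1))
    cds_len = total - utr5 - utr3
    cds_len -= cds_len % 3
    utr3 = total - utr5 - cds_len
    if cds_len < 9:
        raise GenerationError("exons too short for a CDS of at least 3 codons")

    n_codons = cds_len // 3  # includes start and terminator
    body = rng.choice(_NONSTOP_CODONS, size=n_codons - 2)
    cds = "ATG" + "".join(body) + str(rng.choice(_STOPS))

    utr5_seq = _random_bases(rng, utr5, params.gc_content)
    utr3_seq = _stopfree_tail(rng, utr3)
    seq = utr5_seq + cds + utr3_seq
    assert len(seq) == total

    exons, off = [], 0
    for i, ln in enumerate(lengths, start=1):
        exons.append(Exon(index=i, sequence=seq[off : off + ln]))
        off += ln
    return TranscriptModel(
        name=f"minigene_seed{params.seed}",
        exons=tuple(exons),
        cds_start=utr5 + 1,
        cds_end=utr5 + cds_len,
    )


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=n, p=p)) if n else ""


def _stopfree_tail(rng: np.random.Generator, n: int) -> str:
    """A 3'UTR whose in-frame triplets (continuing the CDS frame) are not stops."""
    if n == 0:
        return ""
    codons = rng.choice(_NONSTOP_CODONS, size=(n + 2) // 3)
    return "".join(codons)[:n]


def write_minigene(model: TranscriptModel, out_dir: str | Path) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / f"{model.name}.fasta"
    table = out_dir / f"{model.name}.exons.tsv"
    save_model(model, fasta, table)
    return fasta, table


# -- cohorts ----------------------------------------------------------------

DEFAULT_CLASS_MIX: dict[str, float] = {
    "exon_del": 0.40,
    "exon_dup": 0.15,
    "small_del": 0.10,
    "small_ins": 0.05,
    "small_dup": 0.05,
    "substitution": 0.15,
    "splice": 0.05,
    "combination": 0.05,
}


@dataclass(frozen=True)
class CohortParams:
    """Cohort size, mutation-class mix and seed.

    The default mix keeps large deletions the most common class, followed by
    duplications and point mutations, echoing the relative ordering reported
    for dystrophin cohorts (deletions ~68%, duplications ~11% of large
    events) without attempting to model hotspots.
    """

    n_patients: int = 200
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    seed: int = 0
    max_del_span: int = 6  # exons
    max_dup_span: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "class_mix", dict(self.class_mix))
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        s = sum(self.class_mix.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"class mix proportions must sum to 1, got {s}")
        unknown = set(self.class_mix) - set(DEFAULT_CLASS_MIX)
        if unknown:
            raise ValueError(f"unknown mutation classes {sorted(unknown)}")


def truth_label(
    ms: MutationSet, model: TranscriptModel, cfg: ClassifierConfig
) -> str:
    """Mechanistic ground truth: DMD iff translation truncates prematurely,
    never stops, no product is made, or the product length leaves
    [length_low, length_high]; else BMD."""
    mt = apply_mutations(model, ms)
    pr = translate_from(mt)
    if (
        mt.transcript_absent
        or mt.start_lost
        or pr.premature_stop
        or pr.non_stop
        or pr.length_aa < cfg.length_low
        or pr.length_aa > cfg.length_high
    ):
        return DMD
    return BMD


def make_cohort(
    model: TranscriptModel,
    params: CohortParams,
    cfg: ClassifierConfig | None = None,
) -> list[PatientRecord]:
    """Draw a labeled synthetic cohort for `model`.

    Each patient gets a random mutation of a class drawn from the mix, a
    textual description in the clinical vocabulary, and a ground-truth
    phenotype from :func:`truth_label` using `cfg` (default: the length
    window rescaled to the model).
    """
    cfg = cfg or ClassifierConfig.scaled_to(model)
    rng = np.random.default_rng(params.seed)
    classes = sorted(params.class_mix)
    probs = np.array([params.class_mix[c] for c in classes])

    records: list[PatientRecord] = []
    for i in range(1, params.n_patients + 1):
        cls = classes[int(rng.choice(len(classes), p=probs))]
        text = _draw_mutation(rng, model, cls, params)
        ms = parse_mutation(text, model)
        label = truth_label(ms, model, cfg)
        records.append(
            PatientRecord(
                patient_id=f"P{i:04d}",
                mutation_text=text,
                observed_phenotype=label,
                source=f"synthetic:{cls}",
            )
        )
    return records


def _draw_mutation(rng, model: TranscriptModel, cls: str, params: CohortParams) -> str:
    if cls == "combination":
        # two independent non-overlapping draws, 5' first in the text
        for _ in range(100):
            a = _draw_mutation(rng, model, _simple_class(rng), params)
            b = _draw_mutation(rng, model, _simple_class(rng), params)
            try:
                ms = parse_mutation(f"{a} plus {b}", model)
                apply_mutations(model, ms)
            except Exception:
                continue
            return f"{a} plus {b}"
        raise GenerationError("could not draw a non-conflicting combination")
    if cls == "exon_del":
        first = int(rng.integers(1, model.n_exons + 1))
        span = int(rng.integers(1, params.max_del_span + 1))
        last = min(model.n_exons, first + span - 1)
        return f"exon{first}del" if first == last else f"exon{first}-{last}del"
    if cls == "exon_dup":
        # A tandem copy of a block containing the natural terminator lands
        # downstream of the stop codon and is translationally silent; only
        # duplications that land inside the translated region are drawn.
        term_exon = model.exon_of_position(model.cds_end - 2)
        if term_exon < 2:
            raise GenerationError("model too small to draw consequential duplications")
        first = int(rng.integers(1, term_exon))
        span = int(rng.integers(1, params.max_dup_span + 1))
        last = min(term_exon - 1, first + span - 1)
        return f"exon{first}dup" if first == last else f"exon{first}-{last}dup"

    seq = model.spliced_sequence
    cds_len = model.cds_length
    if cls == "small_del":
        n = int(rng.integers(1, 7))
        a = int(rng.integers(1, cds_len - n + 1))
        b = a + n - 1
        bases = seq[model.c_to_t(a) - 1 : model.c_to_t(b)]
        return f"c.{a}del{bases}" if a == b else f"c.{a}_{b}del{bases}"
    if cls == "small_ins":
        a = int(rng.integers(1, cds_len))
        bases = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 7))))
        return f"c.{a}_{a + 1}ins{bases}"
    if cls == "small_dup":
        n = int(rng.integers(1, 4))
        a = int(rng.integers(1, cds_len - n + 1))
        b = a + n - 1
        bases = seq[model.c_to_t(a) - 1 : model.c_to_t(b)]
        return f"c.{a}dup{bases}" if a == b else f"c.{a}_{b}dup{bases}"
    if cls == "substitution":
        a = int(rng.integers(4, cds_len - 3))  # spare the start/stop codons
        ref = seq[model.c_to_t(a) - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return f"c.{a}{ref}>{alt}"
    if cls == "splice":
        # donor of an exon whose last base is coding, or acceptor of one
        # whose first base is coding; the terminal exon boundaries are skipped
        donors = [
            e for e in range(1, model.n_exons)
            if model.cds_start <= model.exon_end(e) <= model.cds_end
        ]
        acceptors = [
            e for e in range(2, model.n_exons + 1)
            if model.cds_start <= model.exon_start(e) <= model.cds_end
        ]
        if donors and (not acceptors or rng.random() < 0.5):
            e = int(rng.choice(donors))
            c = model.exon_end(e) - model.cds_start + 1
            off = int(rng.integers(1, 11))
            return f"c.{c}+{off}G>A"
        if acceptors:
            e = int(rng.choice(acceptors))
            c = model.exon_start(e) - model.cds_start + 1
            off = int(rng.integers(1, 11))
            return f"c.{c}-{off}A>G"
        raise GenerationError("model has no coding exon boundaries for splice draws")
    raise ValueError(f"unknown mutation class {cls!r}")


def _simple_class(rng) -> str:
    simple = ("exon_del", "exon_dup", "small_del", "small_ins", "substitution")
    return simple[int(rng.integers(0, len(simple)))]
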