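"""Rule-based DMD-vs-BMD phenotype prediction and cohort evaluation.

Three rules vote on each patient's mutation set:

* **reading-frame rule** (Monaco rule): a net exonic length change that is
  not a multiple of 3 shifts the frame downstream -> severe (DMD); a
  multiple of 3 preserves it -> milder (BMD);
* **mutated-protein length**: the translated product must stay within the
  normal window — for dystrophin, 3000..3685 aa (an ambush-hypothesis-style
  threshold below which the dystrophin-associated complex fails) — anything
  shorter or longer is DMD;
* **potential stop-gains**: reading the whole mutated transcript in frame
  from the start codon must hit exactly one stop (the natural terminator);
  any other count is DMD.

A joint verdict combines the votes (default: DMD if ANY rule says DMD;
MAJORITY available).  Supplemental location patterns for large in-frame
deletions (domain-based exceptions to the frame rule) can override the joint
verdict, and an optional ESE rule — off by default because it degraded
accuracy on real cohorts — reinterprets ESE-disrupting nonsense
substitutions as skips of their exon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

import pandas as pd

from . import protein as _protein
from .ese import ESEMatrix, ese_disrupted
from .mutations import (
    MutationKind,
    MutationSet,
    MutationSpec,
    UnparseableMutation,
    apply_mutations,
    net_exonic_length_change,
    parse_mutation,
    resolve_splice,
)
from .reference import DomainMap, TranscriptModel

DMD = "DMD"
BMD = "BMD"
NA = "NA"


class JointCriterion(str, Enum):
    ANY = "ANY"          # DMD if any rule votes DMD
    MAJORITY = "MAJORITY"  # DMD if >= 2 rules vote DMD


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and switches of the rule-based classifier.

    Defaults are the dystrophin values: protein length must fall in
    [3000, 3685] aa, a normal transcript reads exactly 1 stop, and rod-domain
    in-frame deletions above 35 exons pattern to DMD.  For synthetic
    mini-genes use :meth:`scaled_to`, which keeps the same 3000/3685
    proportion relative to the model's own protein length.
    """

    length_low: int = 3000
    length_high: int = 3685
    stopgain_normal: int = 1
    rod_exon_limit: int = 35
    joint_criterion: JointCriterion = JointCriterion.ANY
    patterns_enabled: bool = False
    patterns_override: bool = True  # False: pattern votes alongside the rules
    ese_enabled: bool = False
    ese_action: str = "skip_exon"  # or "call_dmd"
    bmd_exon_window: tuple[int, int] = (2, 8)  # in-frame deletions here -> BMD

    def __post_init__(self) -> None:
        if not 0 < self.length_low <= self.length_high:
            raise ValueError(
                f"need 0 < length_low <= length_high, got "
                f"({self.length_low}, {self.length_high})"
            )

    @classmethod
    def scaled_to(cls, model: TranscriptModel, **overrides) -> "ClassifierConfig":
        """Config with the length window rescaled to `model`'s protein.

        The upper bound becomes the model's own protein length; the lower
        bound keeps the dystrophin 3000/3685 proportion.
        """
        high = model.protein_length
        low = max(1, round(high * 3000 / 3685))
        return cls(length_low=low, length_high=high, **overrides)


# -- individual rules -------------------------------------------------------

def _is_nonsense(spec: MutationSpec, model: TranscriptModel) -> bool:
    """Substitution that turns its reference-frame codon into a stop."""
    if spec.kind is not MutationKind.SUBSTITUTION:
        return False
    c = spec.c_start
    codon_idx = (c - 1) // 3
    cds = model.spliced_sequence[model.cds_start - 1 : model.cds_end]
    codon = list(cds[codon_idx * 3 : codon_idx * 3 + 3])
    if len(codon) < 3:
        return False
    codon[(c - 1) % 3] = spec.alt
    from .reference import STOP_CODONS

    return "".join(codon) in STOP_CODONS


def frame_verdict(ms: MutationSet, model: TranscriptModel) -> str:
    """Reading-frame rule: DMD iff the net exonic change is not 3n.

    Nonsense substitutions change no length, so the frame rule has nothing
    to say about them: they return NA and are carried by the length and
    stop-gain rules.
    """
    net = net_exonic_length_change(ms, model)
    if net % 3 != 0:
        return DMD
    if any(_is_nonsense(s, model) for s in ms):
        return NA
    return BMD


def length_verdict(pr: _protein.ProteinResult, cfg: ClassifierConfig) -> str:
    """Protein-length rule: DMD iff outside [length_low, length_high] aa."""
    if pr.length_aa < cfg.length_low or pr.length_aa > cfg.length_high:
        return DMD
    return BMD


def stopgain_verdict(count: int, cfg: ClassifierConfig) -> str:
    """Stop-gain rule: DMD iff the in-frame stop count differs from 1."""
    return DMD if count != cfg.stopgain_normal else BMD


def joint_verdict(verdicts, criterion: JointCriterion = JointCriterion.ANY) -> str:
    """Combine rule verdicts; NA votes are dropped, not counted as BMD."""
    votes = [v for v in verdicts if v != NA]
    if not votes:
        raise ValueError("all rule verdicts are NA; no joint verdict possible")
    n_dmd = sum(v == DMD for v in votes)
    criterion = JointCriterion(criterion)
    if criterion is JointCriterion.ANY:
        return DMD if n_dmd >= 1 else BMD
    return DMD if n_dmd >= 2 else BMD


# -- supplemental location patterns ----------------------------------------

def _domain_range(dmap: DomainMap, name: str) -> tuple[int, int] | None:
    for dn, first, last in dmap.entries:
        if dn == name:
            return first, last
    return None


def pattern_verdict(
    ms: MutationSet,
    model: TranscriptModel,
    dmap: DomainMap,
    cfg: ClassifierConfig | None = None,
) -> str:
    """Location patterns supplementing the frame rule (most specific first).

    1. in-frame deletion removing (part of) the ABD together with part of
       the rod -> DMD;
    2. in-frame deletion within exons 2-8 -> severe-but-BMD;
    3. in-frame rod deletion of more than `rod_exon_limit` exons -> DMD,
       at most that many -> BMD (the deletion hotspot);
    4. any mutation located in the cysteine-rich domain -> DMD;
    5. deletion within the syntrophin-binding region (exons 71-74) -> BMD;
    otherwise NA.
    """
    cfg = cfg or ClassifierConfig()
    specs = [
        resolve_splice(s, model) if s.kind is MutationKind.SPLICE_SITE else s
        for s in ms
    ]
    net = net_exonic_length_change(ms, model)
    in_frame = net % 3 == 0

    abd = _domain_range(dmap, "ABD")
    rod = _domain_range(dmap, "ROD")
    cys = _domain_range(dmap, "CYS_RICH")
    syn = _domain_range(dmap, "SYNTROPHIN_BINDING")

    # patterns 1/2/3/5 apply to a lone large in-frame deletion
    sole_del = (
        specs[0]
        if len(specs) == 1
        and specs[0].kind is MutationKind.EXON_DEL
        and not specs[0].from_splice
        else None
    )
    if sole_del is not None and in_frame:
        first, last = sole_del.exon_first, sole_del.exon_last
        if abd and rod and first <= abd[1] and last >= rod[0]:
            return DMD
        lo, hi = cfg.bmd_exon_window
        if lo <= first and last <= hi:
            return BMD
        if rod and rod[0] <= first and last <= rod[1]:
            return DMD if (last - first + 1) > cfg.rod_exon_limit else BMD
    if cys:
        for s in specs:
            exons = _spec_exons(s, model)
            if exons and any(cys[0] <= e <= cys[1] for e in exons):
                return DMD
    if sole_del is not None and syn:
        if syn[0] <= sole_del.exon_first and sole_del.exon_last <= syn[1]:
            return BMD
    return NA


def _spec_exons(spec: MutationSpec, model: TranscriptModel) -> tuple[int, ...]:
    if spec.exon_first is not None:
        return tuple(range(spec.exon_first, spec.exon_last + 1))
    if spec.c_start is not None:
        a = model.exon_of_position(model.c_to_t(spec.c_start))
        b = model.exon_of_position(model.c_to_t(spec.c_end))
        return tuple(range(a, b + 1))
    return ()


# -- per-patient pipeline ---------------------------------------------------

LARGE = "large deletions/duplications"
SMALL = "small deletions/duplications"
SPLICE = "splice sites"
NONSENSE = "nonsense"
MISSENSE = "missense"
COMBINATION = "combination"

#: classes summed into the "total" evaluation row (nonsense etc. are listed
#: separately, mirroring the conventional cohort-table layout)
TOTAL_CLASSES = (LARGE, SMALL, SPLICE)


def mutation_class(ms: MutationSet, model: TranscriptModel) -> str:
    if len(ms) > 1:
        return COMBINATION
    spec = ms.specs[0]
    k = spec.kind
    if k in (MutationKind.EXON_DEL, MutationKind.EXON_DUP):
        return SPLICE if spec.from_splice else LARGE
    if k in (MutationKind.SMALL_DEL, MutationKind.SMALL_INS, MutationKind.SMALL_DUP):
        return SMALL
    if k is MutationKind.SPLICE_SITE:
        return SPLICE
    return NONSENSE if _is_nonsense(spec, model) else MISSENSE


@dataclass(frozen=True)
class PredictionRecord:
    """One patient's per-rule verdicts and joint prediction (a *.diag row)."""

    patient_id: str
    mutation_text: str
    frame_verdict: str = NA
    length_verdict: str = NA
    stopgain_verdict: str = NA
    pattern_verdict: str = NA
    joint_verdict: str = NA
    protein_length_aa: int | None = None
    stop_gain_count: int | None = None
    mutation_class: str = ""
    observed_phenotype: str = ""
    filtered: bool = False
    notes: str = ""


def classify_patient(
    patient_id: str,
    mutation_text: str,
    model: TranscriptModel,
    cfg: ClassifierConfig | None = None,
    dmap: DomainMap | None = None,
    matrices: list[ESEMatrix] | None = None,
    observed_phenotype: str = "",
) -> PredictionRecord:
    """Run the full pipeline for one patient.

    parse -> splice-resolve -> apply -> translate/count -> three rule
    verdicts -> optional pattern override -> joint verdict.  An unparseable
    description yields a filtered (unpredicted) record rather than an error.
    """
    cfg = cfg or ClassifierConfig()
    dmap = dmap or DomainMap.default_dystrophin()
    from .mutations import MutationError

    try:
        ms = parse_mutation(mutation_text, model)
    except UnparseableMutation as exc:
        return PredictionRecord(
            patient_id=patient_id,
            mutation_text=mutation_text,
            filtered=True,
            observed_phenotype=observed_phenotype,
            notes=f"filtered: {exc.reason}",
        )

    notes: list[str] = []
    try:
        if cfg.ese_enabled and matrices:
            ms = _apply_ese_rule(ms, model, matrices, cfg, notes)

        fv = frame_verdict(ms, model)
        mt = apply_mutations(model, ms)
    except MutationError as exc:
        # mid-intronic splice offsets, overlapping edits, allele mismatches:
        # the record is filtered with a reason, not crashed on
        return PredictionRecord(
            patient_id=patient_id,
            mutation_text=mutation_text,
            filtered=True,
            observed_phenotype=observed_phenotype,
            notes=f"filtered: {exc}",
        )
    pr = _protein.translate_from(mt)
    lv = length_verdict(pr, cfg)
    sv = stopgain_verdict(pr.stop_gain_count, cfg)
    pv = pattern_verdict(ms, model, dmap, cfg) if cfg.patterns_enabled else NA

    if cfg.patterns_enabled and pv != NA and cfg.patterns_override:
        jv = pv
        notes.append("joint verdict overridden by location pattern")
    elif cfg.patterns_enabled and pv != NA:
        jv = joint_verdict((fv, lv, sv, pv), cfg.joint_criterion)
    else:
        jv = joint_verdict((fv, lv, sv), cfg.joint_criterion)

    notes.extend(
        note for _, note in mt.applied if "ignored" in note or "no transcript" in note
    )
    return PredictionRecord(
        patient_id=patient_id,
        mutation_text=mutation_text,
        frame_verdict=fv,
        length_verdict=lv,
        stopgain_verdict=sv,
        pattern_verdict=pv,
        joint_verdict=jv,
        protein_length_aa=pr.length_aa,
        stop_gain_count=pr.stop_gain_count,
        mutation_class=mutation_class(ms, model),
        observed_phenotype=observed_phenotype,
        notes="; ".join(notes),
    )


def _apply_ese_rule(
    ms: MutationSet,
    model: TranscriptModel,
    matrices: list[ESEMatrix],
    cfg: ClassifierConfig,
    notes: list[str],
) -> MutationSet:
    """Reinterpret ESE-disrupting exonic substitutions as exon skips."""
    new_specs: list[MutationSpec] = []
    for s in ms:
        if s.kind is MutationKind.SUBSTITUTION and ese_disrupted(model, s, matrices):
            if cfg.ese_action == "skip_exon":
                exon = model.exon_of_position(model.c_to_t(s.c_start))
                notes.append(f"ESE disrupted at c.{s.c_start}: exon {exon} skipped")
                new_specs.append(
                    MutationSpec(
                        kind=MutationKind.EXON_DEL,
                        raw=s.raw,
                        exon_first=exon,
                        exon_last=exon,
                        from_splice=True,
                    )
                )
                continue
            notes.append(f"ESE disrupted at c.{s.c_start}")
        new_specs.append(s)
    return MutationSet(specs=tuple(new_specs))


def classify_cohort(
    patients,
    model: TranscriptModel,
    cfg: ClassifierConfig | None = None,
    dmap: DomainMap | None = None,
    matrices: list[ESEMatrix] | None = None,
) -> list[PredictionRecord]:
    """Classify an iterable of PatientRecord-like objects."""
    return [
        classify_patient(
            p.patient_id,
            p.mutation_text,
            model,
            cfg=cfg,
            dmap=dmap,
            matrices=matrices,
            observed_phenotype=getattr(p, "observed_phenotype", "") or "",
        )
        for p in patients
    ]


# -- evaluation -------------------------------------------------------------

def _pct(num: int, den: int) -> float:
    """Percentage rounded half-up to 1 decimal (table style: 5161/5681 -> 90.8)."""
    if den == 0:
        return float("nan")
    q = (Decimal(num) * 100 / Decimal(den)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass(frozen=True)
class EvaluationSummary:
    """Accuracy / FPR / FNR per mutation class for one prediction method.

    Conventions: a false positive calls an observed BMD as DMD; a false
    negative calls an observed DMD as BMD; denominators are the full class
    row count, so accuracy + FPR + FNR = 100% up to rounding.
    """

    method: str
    table: pd.DataFrame = field(repr=False)

    def row(self, cls: str) -> pd.Series:
        return self.table.set_index("class").loc[cls]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


_METHOD_FIELD = {
    "frame": "frame_verdict",
    "length": "length_verdict",
    "stopgain": "stopgain_verdict",
    "joint": "joint_verdict",
}


def evaluate(records: list[PredictionRecord], method: str = "joint") -> EvaluationSummary:
    """Tally predictions of one method against observed phenotypes.

    Rows: one per mutation class present, plus a ``total`` row summing the
    canonical classes (large/small del-dup and splice sites); nonsense and
    other classes are reported separately.  Filtered records and NA verdicts
    are excluded from the tallies (their count appears in n_excluded).
    """
    if not records:
        raise ValueError("no prediction records to evaluate")
    fieldname = _METHOD_FIELD[method]

    counts: dict[str, dict[str, int]] = {}
    for rec in records:
        cls = rec.mutation_class or "unclassified"
        c = counts.setdefault(
            cls, {"n_total": 0, "n_correct": 0, "n_fp": 0, "n_fn": 0, "n_excluded": 0}
        )
        pred = getattr(rec, fieldname)
        obs = rec.observed_phenotype
        if rec.filtered or pred == NA or obs not in (DMD, BMD):
            c["n_excluded"] += 1
            continue
        c["n_total"] += 1
        if pred == obs:
            c["n_correct"] += 1
        elif obs == BMD and pred == DMD:
            c["n_fp"] += 1
        else:
            c["n_fn"] += 1

    total = {"n_total": 0, "n_correct": 0, "n_fp": 0, "n_fn": 0, "n_excluded": 0}
    summed = [c for c in TOTAL_CLASSES if c in counts] or list(counts)
    for cls in summed:
        for k in total:
            total[k] += counts[cls][k]
    counts["total"] = total

    order = [c for c in (*TOTAL_CLASSES, "total") if c in counts]
    order += [c for c in counts if c not in order]
    rows = []
    for cls in order:
        c = counts[cls]
        rows.append(
            {
                "class": cls,
                **c,
                "accuracy": _pct(c["n_correct"], c["n_total"]),
                "fpr": _pct(c["n_fp"], c["n_total"]),
                "fnr": _pct(c["n_fn"], c["n_total"]),
            }
        )
    return EvaluationSummary(method=method, table=pd.DataFrame(rows))


def predictions_to_frame(records: list[PredictionRecord]) -> pd.DataFrame:
    """Flatten PredictionRecords into the diag-file DataFrame layout."""
    return pd.DataFrame([vars(r) for r in records])
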