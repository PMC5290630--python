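"""Parse mutation descriptions and apply them to a reference transcript.

The vocabulary mirrors how dystrophin mutations are reported clinically:
whole-exon deletions/duplications (``exon45-47del``, ``exon2dup``), small
in-exon edits in HGVS cDNA style (``c.9204_9207delCAAA``, ``c.1898dupA``,
``c.123_124insAT``, ``c.9568C>T``) and near-exon splice-site substitutions
(``c.9563+1G>A``).  Multiple mutations in one patient are joined by
``" plus "`` (or a spaced ``" + "``).

Application follows four mechanistic assumptions:

1. a splice-site mutation (within 10 nt of an exon boundary) skips the
   nearest exon only;
2. loss of the promoter region means no transcript at all;
3. with multiple mutations the 5'-most is considered first, and any mutation
   lying downstream of where translation already stops is ignored;
4. supplemental location patterns for large in-frame deletions are handled by
   the classifier, not here.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum

from .reference import STOP_CODONS, TranscriptModel, exon_span_length


class MutationKind(str, Enum):
    EXON_DEL = "EXON_DEL"
    EXON_DUP = "EXON_DUP"
    SMALL_DEL = "SMALL_DEL"
    SMALL_INS = "SMALL_INS"
    SMALL_DUP = "SMALL_DUP"
    SUBSTITUTION = "SUBSTITUTION"
    SPLICE_SITE = "SPLICE_SITE"


class MutationError(ValueError):
    """Base class for mutation parsing/application failures."""


class UnparseableMutation(MutationError):
    """Description does not determine the exact nucleotide change.

    Such records (e.g. ``c.1335ins680``: an insertion of unknown sequence)
    are filtered from prediction, not crashed on.
    """

    def __init__(self, text: str, reason: str = "unrecognised description"):
        self.text = text
        self.reason = reason
        super().__init__(f"cannot determine nucleotide change from {text!r}: {reason}")


class SpliceSiteError(MutationError):
    """Splice-site offset too deep in the intron, or not at an exon boundary."""


class RefAlleleMismatch(MutationError):
    """Stated reference allele disagrees with the model sequence."""


class OverlappingMutations(MutationError):
    """Two mutations in one set affect overlapping transcript intervals."""


_PROMOTER_KEYWORDS = ("promoter",)

_EXON_RE = re.compile(r"exons?\s*(\d+)(?:\s*[-_]\s*(\d+))?\s*(del|dup)", re.I)
_SPLICE_RE = re.compile(r"c\.(\d+)([+-]\d+)([ACGT])>([ACGT])", re.I)
_SUB_RE = re.compile(r"c\.(\d+)([ACGT])>([ACGT])", re.I)
_DEL_RE = re.compile(r"c\.(\d+)(?:_(\d+))?del([ACGT]*)", re.I)
_DUP_RE = re.compile(r"c\.(\d+)(?:_(\d+))?dup([ACGT]*)", re.I)
_INS_RE = re.compile(r"c\.(\d+)_(\d+)ins([ACGT]+)", re.I)
_PROT_SUFFIX_RE = re.compile(r"\s+p\.\S+$")


@dataclass(frozen=True)
class MutationSpec:
    """One parsed mutation.

    Only the fields relevant to ``kind`` are populated.  ``raw`` keeps the
    original text for reporting; ``from_splice`` marks exon-deletion specs
    that arose from resolving a splice-site mutation to an exon skip, so
    frequency reports can still count them as splice mutations.
    """

    kind: MutationKind
    raw: str
    exon_first: int | None = None
    exon_last: int | None = None
    c_start: int | None = None
    c_end: int | None = None
    ref: str | None = None
    alt: str | None = None
    splice_offset: int | None = None
    includes_promoter: bool = False
    from_splice: bool = False

    def to_dict(self) -> dict:
        d = {"kind": self.kind.value, "raw": self.raw}
        for f in (
            "exon_first", "exon_last", "c_start", "c_end", "ref", "alt",
            "splice_offset", "includes_promoter", "from_splice",
        ):
            v = getattr(self, f)
            if v not in (None, False):
                d[f] = v
        return d


@dataclass(frozen=True)
class MutationSet:
    """An ordered collection of mutations carried by one patient."""

    specs: tuple[MutationSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "specs", tuple(self.specs))
        if not self.specs:
            raise MutationError("a MutationSet must contain at least one mutation")

    def __iter__(self):
        return iter(self.specs)

    def __len__(self) -> int:
        return len(self.specs)

    def sorted_by_position(self, model: TranscriptModel) -> "MutationSet":
        """Return a copy sorted 5'->3' by leftmost affected transcript position."""
        resolved = [
            resolve_splice(s, model) if s.kind is MutationKind.SPLICE_SITE else s
            for s in self.specs
        ]
        order = sorted(
            range(len(self.specs)),
            key=lambda i: spec_interval(resolved[i], model)[0],
        )
        return MutationSet(specs=tuple(self.specs[i] for i in order))

    def to_json(self) -> str:
        return json.dumps([s.to_dict() for s in self.specs], indent=2)


def _parse_token(token: str) -> MutationSpec:
    token = _PROT_SUFFIX_RE.sub("", token.strip())
    if not token:
        raise UnparseableMutation(token, "empty token")
    low = token.lower()

    if any(k in low for k in _PROMOTER_KEYWORDS):
        # "promoterdel" / "promoter-exon3del": deletion starting at the
        # promoter / first exon region -> no transcript.
        m = _EXON_RE.search(token)
        last = int(m.group(2) or m.group(1)) if (m and m.group(3).lower() == "del") else 1
        if low.endswith("del"):
            return MutationSpec(
                kind=MutationKind.EXON_DEL, raw=token,
                exon_first=1, exon_last=last, includes_promoter=True,
            )
        raise UnparseableMutation(token, "promoter region named but not a deletion")

    m = _EXON_RE.fullmatch(token)
    if m:
        first, last = int(m.group(1)), int(m.group(2) or m.group(1))
        if first > last:
            raise UnparseableMutation(token, f"exon range {first}>{last}")
        kind = MutationKind.EXON_DEL if m.group(3).lower() == "del" else MutationKind.EXON_DUP
        return MutationSpec(kind=kind, raw=token, exon_first=first, exon_last=last)

    m = _SPLICE_RE.fullmatch(token)
    if m:
        return MutationSpec(
            kind=MutationKind.SPLICE_SITE, raw=token,
            c_start=int(m.group(1)), c_end=int(m.group(1)),
            splice_offset=int(m.group(2)),
            ref=m.group(3).upper(), alt=m.group(4).upper(),
        )

    m = _SUB_RE.fullmatch(token)
    if m:
        pos = int(m.group(1))
        ref, alt = m.group(2).upper(), m.group(3).upper()
        if ref == alt:
            raise UnparseableMutation(token, "substitution with identical alleles")
        return MutationSpec(
            kind=MutationKind.SUBSTITUTION, raw=token,
            c_start=pos, c_end=pos, ref=ref, alt=alt,
        )

    m = _INS_RE.fullmatch(token)
    if m:
        a, b = int(m.group(1)), int(m.group(2))
        if b != a + 1:
            raise UnparseableMutation(token, "insertion must sit between adjacent positions")
        return MutationSpec(
            kind=MutationKind.SMALL_INS, raw=token,
            c_start=a, c_end=b, alt=m.group(3).upper(),
        )

    m = _DEL_RE.fullmatch(token)
    if m:
        a = int(m.group(1))
        b = int(m.group(2)) if m.group(2) else a
        ref = m.group(3).upper() or None
        if b < a:
            raise UnparseableMutation(token, f"deleted range {a}>{b}")
        if ref and len(ref) != b - a + 1:
            raise UnparseableMutation(
                token, f"stated bases ({len(ref)} nt) disagree with range {a}_{b}"
            )
        return MutationSpec(
            kind=MutationKind.SMALL_DEL, raw=token, c_start=a, c_end=b, ref=ref,
        )

    m = _DUP_RE.fullmatch(token)
    if m:
        a = int(m.group(1))
        b = int(m.group(2)) if m.group(2) else a
        alt = m.group(3).upper() or None
        if b < a:
            raise UnparseableMutation(token, f"duplicated range {a}>{b}")
        if alt and len(alt) != b - a + 1:
            raise UnparseableMutation(
                token, f"stated bases ({len(alt)} nt) disagree with range {a}_{b}"
            )
        return MutationSpec(
            kind=MutationKind.SMALL_DUP, raw=token, c_start=a, c_end=b, alt=alt,
        )

    raise UnparseableMutation(token)


def parse_mutation(text: str, model: TranscriptModel | None = None) -> MutationSet:
    """Parse a (possibly compound) mutation description.

    Compound descriptions join tokens with ``" plus "`` or a spaced ``" + "``
    (an unspaced ``+`` belongs to splice-site offsets like ``c.9563+1G>A``).
    With a `model`, the returned set is sorted 5'->3' by leftmost affected
    transcript position; without one, textual order is kept and
    :func:`apply_mutations` re-sorts.
    """
    if not text or not text.strip():
        raise UnparseableMutation(text, "empty description")
    tokens = re.split(r"\s+plus\s+|\s+\+\s+", text.strip(), flags=re.I)
    ms = MutationSet(specs=tuple(_parse_token(t) for t in tokens))
    if model is not None:
        ms = ms.sorted_by_position(model)
    return ms


# -- splice resolution ------------------------------------------------------

MAX_SPLICE_OFFSET = 10  # nt into the intron; deeper is mid-intronic, unsupported


def resolve_splice(spec: MutationSpec, model: TranscriptModel) -> MutationSpec:
    """Resolve a splice-site mutation to the skip of its nearest exon.

    A donor-side offset (``c.N+k``) requires c.N to be the last base of an
    exon and skips that exon; an acceptor-side offset (``c.N-k``) requires
    c.N to be the first base of an exon and skips that one.  Offsets deeper
    than 10 nt are mid-intronic and rejected.
    """
    if spec.kind is not MutationKind.SPLICE_SITE:
        raise MutationError(f"resolve_splice needs a SPLICE_SITE spec, got {spec.kind}")
    off = spec.splice_offset or 0
    if abs(off) > MAX_SPLICE_OFFSET or off == 0:
        raise SpliceSiteError(
            f"{spec.raw}: intronic offset {off:+d} beyond +/-{MAX_SPLICE_OFFSET} nt "
            "is mid-intronic and not supported"
        )
    t = model.c_to_t(spec.c_start)
    exon = model.exon_of_position(t)
    if off > 0:
        if t != model.exon_end(exon):
            raise SpliceSiteError(
                f"{spec.raw}: c.{spec.c_start} is not the last base of an exon"
            )
    else:
        if t != model.exon_start(exon):
            raise SpliceSiteError(
                f"{spec.raw}: c.{spec.c_start} is not the first base of an exon"
            )
    return MutationSpec(
        kind=MutationKind.EXON_DEL, raw=spec.raw,
        exon_first=exon, exon_last=exon, from_splice=True,
    )


# -- application ------------------------------------------------------------

def spec_interval(spec: MutationSpec, model: TranscriptModel) -> tuple[int, int]:
    """Affected interval (1-based, inclusive) in reference transcript coords.

    Insertions occupy the zero-length gap after c_start and are represented
    by the (position, position) point they follow.
    """
    k = spec.kind
    if k in (MutationKind.EXON_DEL, MutationKind.EXON_DUP):
        return model.exon_start(spec.exon_first), model.exon_end(spec.exon_last)
    if k is MutationKind.SPLICE_SITE:
        t = model.c_to_t(spec.c_start)
        exon = model.exon_of_position(t)
        return model.exon_start(exon), model.exon_end(exon)
    if k is MutationKind.SMALL_INS:
        t = model.c_to_t(spec.c_start)
        return t, t
    return model.c_to_t(spec.c_start), model.c_to_t(spec.c_end)


@dataclass(frozen=True)
class MutatedTranscript:
    """Result of applying a MutationSet to a TranscriptModel.

    ``cds_start`` / ``cds_end`` are the (shifted) positions of the original
    start codon and natural-terminator last base in the mutated sequence;
    either is None when the corresponding codon was destroyed.  ``applied``
    lists every input spec exactly once with an action note.
    """

    sequence: str
    cds_start: int | None
    cds_end: int | None
    applied: tuple[tuple[MutationSpec, str], ...]
    transcript_absent: bool = False
    start_lost: bool = False

    @classmethod
    def from_reference(cls, model: TranscriptModel) -> "MutatedTranscript":
        return cls(
            sequence=model.spliced_sequence,
            cds_start=model.cds_start,
            cds_end=model.cds_end,
            applied=(),
        )


def _stop_end(seq: str, cds_start: int | None) -> int | None:
    """1-based position of the last base of the first in-frame stop, or None."""
    if cds_start is None:
        return None
    for i in range(cds_start - 1, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return i + 3
    return None


def apply_mutations(model: TranscriptModel, ms: MutationSet) -> MutatedTranscript:
    """Apply mutations 5'->3' to the spliced transcript.

    Exon deletions remove whole exon blocks; duplications insert a tandem
    copy directly 3' of the original block; small variants edit in place
    (checking any stated reference allele).  A deletion that removes exon 1
    together with the promoter yields ``transcript_absent``.  After each
    edit, any remaining mutation lying strictly downstream of where
    translation of the current sequence stops is marked ignored.
    """
    resolved: list[MutationSpec] = []
    notes: dict[int, str] = {}
    for i, spec in enumerate(ms):
        if spec.kind is MutationKind.SPLICE_SITE:
            r = resolve_splice(spec, model)
            notes[i] = f"skipped exon {r.exon_first} (splice site)"
            resolved.append(r)
        else:
            notes[i] = ""
            resolved.append(spec)

    def _fuzzy_interval(spec: MutationSpec) -> tuple[float, float]:
        # Insertions occupy the zero-width gap after c_start: (p+0.5, p+0.5).
        a, b = spec_interval(spec, model)
        if spec.kind is MutationKind.SMALL_INS:
            return a + 0.5, a + 0.5
        return float(a), float(b)

    order = sorted(range(len(resolved)), key=lambda i: _fuzzy_interval(resolved[i]))
    intervals = [_fuzzy_interval(resolved[i]) for i in order]
    for (a1, b1), (a2, b2), i, j in zip(intervals, intervals[1:], order, order[1:]):
        if a2 <= b1:
            raise OverlappingMutations(
                f"{resolved[i].raw!r} and {resolved[j].raw!r} affect "
                f"overlapping transcript intervals {a1}-{b1} / {a2}-{b2}"
            )

    seq = model.spliced_sequence
    shift = 0
    cds_start: int | None = model.cds_start
    cds_end: int | None = model.cds_end
    start_lost = False
    absent = False
    applied: list[tuple[MutationSpec, str]] = [None] * len(resolved)  # type: ignore

    for pos_in_order, i in enumerate(order):
        spec = resolved[i]
        orig = ms.specs[i]
        base_note = notes[i]

        if absent:
            applied[i] = (orig, "ignored: no transcript")
            continue

        left0, right0 = spec_interval(spec, model)
        left = left0 + shift
        right = right0 + shift

        if not start_lost:
            stop = _stop_end(seq, cds_start)
            if stop is not None and left > stop:
                applied[i] = (orig, _join(base_note, "ignored: downstream of translation stop"))
                continue

        if (
            spec.kind is MutationKind.EXON_DEL
            and spec.includes_promoter
            and spec.exon_first == 1
        ):
            absent = True
            seq = ""
            cds_start = cds_end = None
            applied[i] = (orig, "promoter lost: no transcript")
            continue

        if spec.kind is MutationKind.EXON_DEL:
            seq, delta = seq[: left - 1] + seq[right:], -(right - left + 1)
            cds_start, cds_end, start_lost = _after_deletion(
                left, right, cds_start, cds_end, start_lost
            )
            applied[i] = (orig, _join(base_note, f"deleted exons {spec.exon_first}-{spec.exon_last}"))
        elif spec.kind is MutationKind.EXON_DUP:
            block = seq[left - 1 : right]
            seq = seq[:right] + block + seq[right:]
            delta = len(block)
            cds_start, cds_end = _after_insertion(right, delta, cds_start, cds_end)
            applied[i] = (orig, f"duplicated exons {spec.exon_first}-{spec.exon_last}")
        elif spec.kind is MutationKind.SMALL_DEL:
            found = seq[left - 1 : right]
            if spec.ref and found != spec.ref:
                raise RefAlleleMismatch(
                    f"{spec.raw}: model has {found!r} at c.{spec.c_start}_"
                    f"{spec.c_end}, description says {spec.ref!r}"
                )
            seq, delta = seq[: left - 1] + seq[right:], -(right - left + 1)
            cds_start, cds_end, start_lost = _after_deletion(
                left, right, cds_start, cds_end, start_lost
            )
            applied[i] = (orig, f"deleted {right0 - left0 + 1} nt at c.{spec.c_start}")
        elif spec.kind is MutationKind.SMALL_INS:
            seq = seq[:left] + spec.alt + seq[left:]
            delta = len(spec.alt)
            cds_start, cds_end = _after_insertion(left, delta, cds_start, cds_end)
            applied[i] = (orig, f"inserted {delta} nt after c.{spec.c_start}")
        elif spec.kind is MutationKind.SMALL_DUP:
            unit = seq[left - 1 : right]
            if spec.alt and unit != spec.alt:
                raise RefAlleleMismatch(
                    f"{spec.raw}: model has {unit!r} at c.{spec.c_start}_"
                    f"{spec.c_end}, description says {spec.alt!r}"
                )
            seq = seq[:right] + unit + seq[right:]
            delta = len(unit)
            cds_start, cds_end = _after_insertion(right, delta, cds_start, cds_end)
            applied[i] = (orig, f"duplicated {delta} nt at c.{spec.c_start}")
        elif spec.kind is MutationKind.SUBSTITUTION:
            found = seq[left - 1]
            if found != spec.ref:
                raise RefAlleleMismatch(
                    f"{spec.raw}: model has {found!r} at c.{spec.c_start}, "
                    f"description says {spec.ref!r}"
                )
            seq = seq[: left - 1] + spec.alt + seq[left:]
            delta = 0
            if cds_end is not None and cds_end - 2 <= left <= cds_end:
                if seq[cds_end - 3 : cds_end] not in STOP_CODONS:
                    cds_end = None  # natural terminator substituted away
            applied[i] = (orig, f"substituted {spec.ref}>{spec.alt} at c.{spec.c_start}")
            shift += 0
            continue
        else:  # pragma: no cover - exhaustive over kinds
            raise MutationError(f"unhandled kind {spec.kind}")

        shift += delta

    if not absent and cds_start is not None and not start_lost:
        if seq[cds_start - 1 : cds_start + 2] != "ATG":
            start_lost = True

    return MutatedTranscript(
        sequence=seq,
        cds_start=None if (absent or start_lost) else cds_start,
        cds_end=cds_end if not absent else None,
        applied=tuple(applied),
        transcript_absent=absent,
        start_lost=start_lost,
    )


def _join(a: str, b: str) -> str:
    return f"{a}; {b}" if a else b


def _after_deletion(
    left: int, right: int, cds_start: int | None, cds_end: int | None, start_lost: bool
) -> tuple[int | None, int | None, bool]:
    n = right - left + 1
    if cds_start is not None:
        if right < cds_start:
            cds_start -= n
        elif left <= cds_start + 2:  # overlaps the start codon
            start_lost = True
    if cds_end is not None:
        if right < cds_end - 2:
            cds_end -= n
        elif left <= cds_end:  # overlaps the terminator codon
            cds_end = None
    return cds_start, cds_end, start_lost


def _after_insertion(
    after: int, n: int, cds_start: int | None, cds_end: int | None
) -> tuple[int | None, int | None]:
    if cds_start is not None and after < cds_start:
        cds_start += n
    if cds_end is not None:
        if after < cds_end - 2:
            cds_end += n
        elif after < cds_end:  # splits the terminator codon
            cds_end = None
    return cds_start, cds_end


def net_exonic_length_change(ms: MutationSet, model: TranscriptModel) -> int:
    """Signed nt change of the spliced transcript: inserted minus deleted.

    Splice-site mutations count as the skip of their nearest exon;
    substitutions contribute zero.
    """
    total = 0
    for spec in ms:
        if spec.kind is MutationKind.SPLICE_SITE:
            spec = resolve_splice(spec, model)
        k = spec.kind
        if k is MutationKind.EXON_DEL:
            total -= exon_span_length(model, spec.exon_first, spec.exon_last)
        elif k is MutationKind.EXON_DUP:
            total += exon_span_length(model, spec.exon_first, spec.exon_last)
        elif k is MutationKind.SMALL_DEL:
            total -= spec.c_end - spec.c_start + 1
        elif k is MutationKind.SMALL_INS:
            total += len(spec.alt)
        elif k is MutationKind.SMALL_DUP:
            total += spec.c_end - spec.c_start + 1
        # SUBSTITUTION: 0
    return total
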