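"""Reference transcript model: exon structure, spliced sequence, CDS and domains.

The dystrophin muscle transcript (Dp427m) is the motivating case: 79 exons
whose spliced CDS encodes a 3685-aa protein organised into an N-terminal
actin-binding domain (ABD), a spectrin-repeat rod, a cysteine-rich domain and
a C-terminal domain (which contains the syntrophin-binding region, exons
71-74).  Nothing here is dystrophin-specific, though: any single-transcript
"mini-gene" with a valid ORF can be modelled, which is how the test suite and
the simulator exercise every downstream rule without external downloads.

Coordinates follow the HGVS cDNA convention: ``c.`` position 1 is the A of the
start codon; exon indices are 1-based in 5'->3' order; all spliced-transcript
offsets are 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_VALID_BASES = frozenset("ACGT")


class ModelError(ValueError):
    """Base class for transcript-model validation failures."""


class ModelFormatError(ModelError):
    """Malformed FASTA / exon table / config input."""


class AlphabetError(ModelError):
    """Sequence contains characters outside A/C/G/T (ambiguity codes rejected)."""


class LengthMismatchError(ModelError):
    """Exon table lengths do not sum to the transcript length."""


class StartCodonError(ModelError):
    """Codon at cds_start is not ATG."""


class StopCodonError(ModelError):
    """Codon ending at cds_end is not a stop codon, or CDS length is not 3n."""


class InternalStopError(ModelError):
    """An in-frame stop codon lies strictly inside the CDS."""


class ExonRangeError(ModelError):
    """Exon index outside the model's 1..n range."""


def _check_alphabet(seq: str, context: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise AlphabetError(
            f"{context}: invalid characters {sorted(bad)}; only A/C/G/T accepted"
        )
    return seq


@dataclass(frozen=True)
class Exon:
    """One exon of the spliced transcript (1-based ordinal, 5'->3')."""

    index: int
    sequence: str

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ModelError(f"exon index must be >= 1, got {self.index}")
        object.__setattr__(
            self, "sequence", _check_alphabet(self.sequence, f"exon {self.index}")
        )
        if not self.sequence:
            raise ModelError(f"exon {self.index} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript with exon structure and CDS offsets.

    Invariants (checked on construction): exon indices are 1..n contiguous;
    1 <= cds_start < cds_end <= spliced length; CDS length divisible by 3;
    ATG at cds_start; stop codon ending at cds_end; no in-frame stop strictly
    inside the CDS.
    """

    name: str
    exons: tuple[Exon, ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(self.exons))
        indices = [e.index for e in self.exons]
        if indices != list(range(1, len(self.exons) + 1)):
            raise ModelError(f"exon indices must be 1..n with no gaps, got {indices}")
        seq = self.spliced_sequence
        if not (1 <= self.cds_start < self.cds_end <= len(seq)):
            raise ModelError(
                f"CDS offsets ({self.cds_start}, {self.cds_end}) out of bounds "
                f"for transcript of length {len(seq)}"
            )
        cds = seq[self.cds_start - 1 : self.cds_end]
        if len(cds) % 3 != 0:
            raise StopCodonError(f"CDS length {len(cds)} not divisible by 3")
        if cds[:3] != "ATG":
            raise StartCodonError(f"codon at cds_start is {cds[:3]!r}, expected ATG")
        if cds[-3:] not in STOP_CODONS:
            raise StopCodonError(
                f"codon ending at cds_end is {cds[-3:]!r}, expected a stop codon"
            )
        for i in range(0, len(cds) - 3, 3):
            if cds[i : i + 3] in STOP_CODONS:
                raise InternalStopError(
                    f"in-frame stop {cds[i:i+3]} at CDS codon {i // 3 + 1} "
                    "strictly inside the CDS"
                )

    # -- structure ---------------------------------------------------------

    @property
    def spliced_sequence(self) -> str:
        return "".join(e.sequence for e in self.exons)

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def protein_length(self) -> int:
        """Length in aa of the encoded protein (terminator excluded)."""
        return self.cds_length // 3 - 1

    @property
    def protein_sequence(self) -> str:
        cds = self.spliced_sequence[self.cds_start - 1 : self.cds_end]
        return str(Seq(cds).translate()).rstrip("*")

    def exon_start(self, index: int) -> int:
        """1-based spliced-transcript offset of the first base of exon `index`."""
        self._check_exon(index)
        return 1 + sum(e.length for e in self.exons[: index - 1])

    def exon_end(self, index: int) -> int:
        """1-based spliced-transcript offset of the last base of exon `index`."""
        self._check_exon(index)
        return sum(e.length for e in self.exons[:index])

    def exon_of_position(self, pos: int) -> int:
        """Exon index containing 1-based spliced-transcript position `pos`."""
        if not 1 <= pos <= self.length:
            raise ExonRangeError(f"transcript position {pos} outside 1..{self.length}")
        acc = 0
        for e in self.exons:
            acc += e.length
            if pos <= acc:
                return e.index
        raise AssertionError("unreachable")

    def c_to_t(self, c_pos: int) -> int:
        """Map a cDNA (c.) coding position to a spliced-transcript offset.

        Only positions within the CDS (1..cds_length) are supported; 5'UTR
        (negative) and 3'UTR (``*``) coordinates are rejected.
        """
        if not 1 <= c_pos <= self.cds_length:
            raise ModelError(
                f"c.{c_pos} outside the CDS (1..{self.cds_length}); "
                "UTR coordinates are not supported"
            )
        return self.cds_start - 1 + c_pos

    def _check_exon(self, index: int) -> None:
        if not 1 <= index <= self.n_exons:
            raise ExonRangeError(
                f"exon {index} outside model range 1..{self.n_exons}"
            )


def exon_span_length(model: TranscriptModel, first: int, last: int) -> int:
    """Total nucleotide length of exons `first`..`last` inclusive.

    For the real dystrophin transcript, (45, 47) -> 474 nt and (45, 45) ->
    176 nt, the classic in-frame vs frameshifting deletion pair.
    """
    model._check_exon(first)
    model._check_exon(last)
    if first > last:
        raise ExonRangeError(f"first exon {first} > last exon {last}")
    return sum(e.length for e in model.exons[first - 1 : last])


# -- domain map -------------------------------------------------------------

DOMAIN_NAMES = ("ABD", "ROD", "CYS_RICH", "C_TERM", "SYNTROPHIN_BINDING")


@dataclass(frozen=True)
class DomainMap:
    """Exon-range -> protein-domain assignments.

    Entries are (domain_name, first_exon, last_exon).  Lookup returns the most
    specific (narrowest) matching entry, so the syntrophin-binding region
    (exons 71-74) wins over the enclosing C-terminal domain.
    """

    entries: tuple[tuple[str, int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(tuple(e) for e in self.entries))
        for name, first, last in self.entries:
            if first < 1 or last < first:
                raise ModelError(f"domain {name}: bad exon range {first}-{last}")

    @classmethod
    def default_dystrophin(cls) -> "DomainMap":
        """Conventional exon boundaries of the four dystrophin domains.

        Only the syntrophin-binding range (exons 71-74) is fixed by the
        clinical literature quoted throughout this package; the other
        boundaries follow common convention and are overridable via
        :meth:`from_config`.
        """
        return cls(
            entries=(
                ("ABD", 1, 8),
                ("ROD", 9, 63),
                ("CYS_RICH", 64, 70),
                ("C_TERM", 71, 79),
                ("SYNTROPHIN_BINDING", 71, 74),
            )
        )

    @classmethod
    def from_config(cls, path: str | Path) -> "DomainMap":
        """Read a flat ``NAME=first-last`` config file (one domain per line)."""
        entries = []
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            m = re.fullmatch(r"(\w+)\s*=\s*(\d+)\s*-\s*(\d+)", line)
            if not m:
                raise ModelFormatError(f"bad domain config line: {raw!r}")
            entries.append((m.group(1).upper(), int(m.group(2)), int(m.group(3))))
        return cls(entries=tuple(entries))

    def validate_for(self, model: TranscriptModel) -> None:
        for name, first, last in self.entries:
            if last > model.n_exons:
                raise ExonRangeError(
                    f"domain {name} ends at exon {last} but model has "
                    f"{model.n_exons} exons"
                )

    def scaled_to(self, model: TranscriptModel) -> "DomainMap":
        """Rescale exon boundaries proportionally to `model`'s exon count.

        Used for synthetic mini-genes so location patterns stay exercisable on
        models with fewer than 79 exons.
        """
        ref_n = max(last for _, _, last in self.entries) if self.entries else 1
        n = model.n_exons
        scaled = []
        for name, first, last in self.entries:
            f = max(1, round((first - 1) * n / ref_n) + 1)
            l = min(n, max(f, round(last * n / ref_n)))
            scaled.append((name, f, l))
        return DomainMap(entries=tuple(scaled))


def domain_of_exon(dmap: DomainMap, exon: int) -> str | None:
    """Most specific domain containing `exon`, or None if unmapped."""
    matches = [
        (last - first, name)
        for name, first, last in dmap.entries
        if first <= exon <= last
    ]
    if not matches:
        return None
    return min(matches)[1]


# -- I/O --------------------------------------------------------------------

def load_reference(
    fasta_path: str | Path,
    exon_table_path: str | Path,
    cds_start: int | None = None,
    cds_end: int | None = None,
) -> TranscriptModel:
    """Build a validated TranscriptModel from a spliced-transcript FASTA and
    an exon-length table.

    The FASTA must hold exactly one record (the spliced transcript).  The exon
    table is a TSV with header ``exon\\tlength`` and may carry the CDS offsets
    as comment lines ``#cds_start=N`` / ``#cds_end=N``; explicit keyword
    arguments override them.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ModelFormatError(
            f"expected exactly one FASTA record in {fasta_path}, got {len(records)}"
        )
    rec = records[0]
    seq = _check_alphabet(str(rec.seq), f"transcript {rec.id}")

    lengths, meta = _read_exon_table(exon_table_path)
    if sum(lengths) != len(seq):
        raise LengthMismatchError(
            f"exon lengths sum to {sum(lengths)} but transcript is {len(seq)} nt"
        )
    cds_start = cds_start if cds_start is not None else meta.get("cds_start")
    cds_end = cds_end if cds_end is not None else meta.get("cds_end")
    if cds_start is None or cds_end is None:
        raise ModelFormatError(
            "CDS offsets missing: supply cds_start/cds_end arguments or "
            "#cds_start=/#cds_end= comments in the exon table"
        )

    exons, off = [], 0
    for i, ln in enumerate(lengths, start=1):
        exons.append(Exon(index=i, sequence=seq[off : off + ln]))
        off += ln
    return TranscriptModel(
        name=rec.id, exons=tuple(exons), cds_start=int(cds_start), cds_end=int(cds_end)
    )


def _read_exon_table(path: str | Path) -> tuple[list[int], dict[str, int]]:
    lengths: list[int] = []
    meta: dict[str, int] = {}
    header_seen = False
    lines = Path(path).read_text().splitlines()
    for raw in lines:
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.fullmatch(r"#\s*(cds_start|cds_end)\s*=\s*(\d+)", line)
            if m:
                meta[m.group(1)] = int(m.group(2))
            continue
        cols = line.split("\t")
        if not header_seen:
            if [c.strip().lower() for c in cols[:2]] != ["exon", "length"]:
                raise ModelFormatError(
                    f"exon table must start with header 'exon\\tlength', got {raw!r}"
                )
            header_seen = True
            continue
        if len(cols) < 2:
            raise ModelFormatError(f"malformed exon table row: {raw!r}")
        try:
            idx, ln = int(cols[0]), int(cols[1])
        except ValueError as exc:
            raise ModelFormatError(f"non-integer exon table row: {raw!r}") from exc
        if idx != len(lengths) + 1:
            raise ModelFormatError(
                f"exon table rows must be ordered 1..n; row {idx} after "
                f"{len(lengths)} rows"
            )
        if ln < 1:
            raise ModelFormatError(f"exon {idx} has non-positive length {ln}")
        lengths.append(ln)
    if not header_seen or not lengths:
        raise ModelFormatError(f"exon table {path} is empty")
    return lengths, meta


def save_model(
    model: TranscriptModel, fasta_path: str | Path, exon_table_path: str | Path
) -> None:
    """Write the model as a spliced FASTA plus exon table (round-trip exact)."""
    rec = SeqRecord(Seq(model.spliced_sequence), id=model.name, description="")
    with open(fasta_path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")
    with open(exon_table_path, "w") as fh:
        fh.write(f"#cds_start={model.cds_start}\n#cds_end={model.cds_end}\n")
        fh.write("exon\tlength\n")
        for e in model.exons:
            fh.write(f"{e.index}\t{e.length}\n")


def default_domain_config_path() -> Path:
    """Path of the bundled dystrophin domain-boundary config."""
    return Path(str(resources.files("dystrokit.data") / "dystrophin_domains.cfg"))
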