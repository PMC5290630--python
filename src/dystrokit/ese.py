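"""Exonic splicing enhancer (ESE) scoring with SR-protein weight matrices.

ESEs are short exonic motifs bound by serine/arginine-rich (SR) splicing
factors; a point mutation that drops a motif's score below the caller
threshold can abolish exon inclusion.  Matrices are position weight matrices
(one additive score per position per base) with a per-matrix calling
threshold, read from a plain-text file of blocks::

    NAME <identifier>
    THRESHOLD <float>
    WIDTH <int>
    A <w numbers>
    C <w numbers>
    G <w numbers>
    T <w numbers>

The bundled file ``ese_matrices_synthetic.txt`` follows the classic
four-SR-protein layout (widths 7/8/7/6) but carries synthetic weights; any
user file in the same format is accepted.

Because the ESE rule measurably hurt accuracy on real cohorts, the phenotype
classifier keeps it off by default; it can be re-enabled for research.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .mutations import MutationKind, MutationSpec
from .reference import TranscriptModel

_BASES = "ACGT"


class ESEFormatError(ValueError):
    """Malformed ESE matrix file."""


@dataclass(frozen=True)
class ESEMatrix:
    """One SR-protein position weight matrix with its calling threshold."""

    protein_name: str
    width: int
    weights: tuple[tuple[float, float, float, float], ...]  # per position, A/C/G/T
    threshold: float

    def __post_init__(self) -> None:
        if self.width < 4:
            raise ESEFormatError(
                f"{self.protein_name}: motif width {self.width} < 4"
            )
        if len(self.weights) != self.width or any(len(w) != 4 for w in self.weights):
            raise ESEFormatError(
                f"{self.protein_name}: weights must be width x 4 finite scores"
            )

    @property
    def max_score(self) -> float:
        return sum(max(w) for w in self.weights)

    def consensus(self) -> str:
        return "".join(_BASES[max(range(4), key=w.__getitem__)] for w in self.weights)


def score_window(m: ESEMatrix, window: str) -> float:
    """Additive PWM score of a window of exactly ``m.width`` nucleotides."""
    window = window.upper()
    if len(window) != m.width:
        raise ValueError(
            f"window length {len(window)} != matrix width {m.width} "
            f"({m.protein_name})"
        )
    total = 0.0
    for pos, base in enumerate(window):
        idx = _BASES.find(base)
        if idx == -1:
            raise ValueError(f"non-ACGT base {base!r} in window")
        total += m.weights[pos][idx]
    return total


def load_matrices(path: str | Path) -> list[ESEMatrix]:
    """Parse an ESE matrix file into validated ESEMatrix objects."""
    text = Path(path).read_text()
    blocks = [b for b in text.split("\n\n") if b.strip()]
    matrices: list[ESEMatrix] = []
    for block in blocks:
        fields: dict[str, str] = {}
        rows: dict[str, list[float]] = {}
        for raw in block.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, rest = line.partition(" ")
            key = key.upper()
            if key in ("NAME", "THRESHOLD", "WIDTH"):
                fields[key] = rest.strip()
            elif key in ("A", "C", "G", "T"):
                try:
                    rows[key] = [float(x) for x in rest.split()]
                except ValueError as exc:
                    raise ESEFormatError(
                        f"matrix {fields.get('NAME', '?')}: bad {key} row"
                    ) from exc
            else:
                raise ESEFormatError(
                    f"matrix {fields.get('NAME', '?')}: unexpected line {raw!r}"
                )
        if not fields and not rows:
            continue  # comment-only block
        name = fields.get("NAME")
        if name is None:
            raise ESEFormatError("matrix block missing NAME line")
        if "THRESHOLD" not in fields or "WIDTH" not in fields:
            raise ESEFormatError(f"matrix {name}: missing THRESHOLD or WIDTH")
        if set(rows) != set("ACGT"):
            raise ESEFormatError(
                f"matrix {name}: need exactly 4 nucleotide rows A/C/G/T, "
                f"got {sorted(rows)}"
            )
        width = int(fields["WIDTH"])
        if any(len(v) != width for v in rows.values()):
            raise ESEFormatError(
                f"matrix {name}: nucleotide rows must have WIDTH={width} columns"
            )
        weights = tuple(
            (rows["A"][i], rows["C"][i], rows["G"][i], rows["T"][i])
            for i in range(width)
        )
        matrices.append(
            ESEMatrix(
                protein_name=name,
                width=width,
                weights=weights,
                threshold=float(fields["THRESHOLD"]),
            )
        )
    if not matrices:
        raise ESEFormatError(f"no matrix blocks found in {path}")
    return matrices


def default_matrices_path() -> Path:
    """Bundled synthetic SR-protein matrix file (documented format)."""
    return Path(str(resources.files("dystrokit.data") / "ese_matrices_synthetic.txt"))


def load_default_matrices() -> list[ESEMatrix]:
    return load_matrices(default_matrices_path())


def ese_disrupted(
    model: TranscriptModel,
    sub: MutationSpec,
    matrices: list[ESEMatrix],
) -> bool:
    """True iff the substitution destroys at least one called ESE site.

    A site is destroyed when, for some matrix and some window inside the
    containing exon that overlaps the substituted base, the reference window
    scores at or above threshold while the mutated window falls below it.
    Windows are confined to the exon because enhancers act on exonic
    sequence.
    """
    if sub.kind is not MutationKind.SUBSTITUTION:
        raise ValueError(f"ese_disrupted needs a SUBSTITUTION, got {sub.kind}")
    t = model.c_to_t(sub.c_start)  # raises for positions outside the CDS
    exon = model.exon_of_position(t)
    ex_start, ex_end = model.exon_start(exon), model.exon_end(exon)
    seq = model.spliced_sequence
    if seq[t - 1] != sub.ref:
        raise ValueError(
            f"{sub.raw}: model has {seq[t - 1]!r} at c.{sub.c_start}, "
            f"description says {sub.ref!r}"
        )
    mut_seq = seq[: t - 1] + sub.alt + seq[t:]
    for m in matrices:
        lo = max(ex_start, t - m.width + 1)
        hi = min(t, ex_end - m.width + 1)
        for start in range(lo, hi + 1):
            ref_w = seq[start - 1 : start - 1 + m.width]
            alt_w = mut_seq[start - 1 : start - 1 + m.width]
            if score_window(m, ref_w) >= m.threshold > score_window(m, alt_w):
                return True
    return False
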