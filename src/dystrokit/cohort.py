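"""Patient-table I/O, mutation-frequency summaries, and visit screening.

Patient tables are plain TSVs with one row per patient: an identifier, a
mutation description (possibly compound), and optionally the observed
phenotype label.  Longitudinal visit tables are wide TSVs (one row per
visit, blank cells = missing indicator) screened for the most informative
visits by a weighted completeness score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .mutations import MutationKind, UnparseableMutation, parse_mutation

logger = logging.getLogger(__name__)


class TableFormatError(ValueError):
    """Patient/visit table cannot be interpreted."""


class ScreeningConfigError(ValueError):
    """Screening configuration names an unknown indicator."""


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    mutation_text: str
    observed_phenotype: str = "unknown"  # DMD | BMD | unknown
    source: str = ""
    filtered: bool = False
    filter_reason: str = ""

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise TableFormatError("patient_id must be non-empty")


_ID_COLUMNS = ("patient_id", "id", "patient")
_MUTATION_COLUMNS = ("mutation", "mutations", "mutation_text")
_PHENOTYPE_COLUMNS = ("phenotype", "observed_phenotype", "diagnosis", "label")


def _find_column(df: pd.DataFrame, names: tuple[str, ...]) -> str | None:
    lower = {c.lower(): c for c in df.columns}
    for n in names:
        if n in lower:
            return lower[n]
    return None


def read_patient_table(path: str | Path, source: str = "") -> list[PatientRecord]:
    """Read a patient TSV.

    Requires a mutation column; the patient-id column defaults to the first
    column if none of the conventional names is present.  Rows whose mutation
    description cannot determine the exact nucleotide change are kept but
    flagged ``filtered`` (with a log line), mirroring how such records are
    dropped from prediction rather than crashed on.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise TableFormatError(f"{path}: empty patient table") from exc
    if df.empty:
        raise TableFormatError(f"{path}: patient table has no rows")

    mut_col = _find_column(df, _MUTATION_COLUMNS)
    if mut_col is None:
        raise TableFormatError(
            f"{path}: no mutation column (expected one of {_MUTATION_COLUMNS})"
        )
    id_col = _find_column(df, _ID_COLUMNS) or df.columns[0]
    if id_col == mut_col:
        raise TableFormatError(f"{path}: cannot use {mut_col!r} as both id and mutation")
    ph_col = _find_column(df, _PHENOTYPE_COLUMNS)

    records: list[PatientRecord] = []
    for _, row in df.iterrows():
        text = (row[mut_col] or "").strip() if isinstance(row[mut_col], str) else ""
        phenotype = "unknown"
        if ph_col and isinstance(row[ph_col], str) and row[ph_col].strip():
            phenotype = row[ph_col].strip().upper()
        filtered, reason = False, ""
        try:
            parse_mutation(text)
        except UnparseableMutation as exc:
            filtered, reason = True, exc.reason
            logger.warning(
                "patient %s: mutation %r filtered (%s)", row[id_col], text, exc.reason
            )
        records.append(
            PatientRecord(
                patient_id=str(row[id_col]),
                mutation_text=text,
                observed_phenotype=phenotype,
                source=source,
                filtered=filtered,
                filter_reason=reason,
            )
        )
    return records


def write_patient_table(records: list[PatientRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "mutation": [r.mutation_text for r in records],
            "phenotype": [r.observed_phenotype for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# -- mutation frequencies ---------------------------------------------------

_KIND_FILTER = {
    "del": (MutationKind.EXON_DEL,),
    "dup": (MutationKind.EXON_DUP,),
    "all": tuple(MutationKind),
}


def _spec_label(spec) -> str:
    if spec.kind in (MutationKind.EXON_DEL, MutationKind.EXON_DUP):
        suffix = "del" if spec.kind is MutationKind.EXON_DEL else "dup"
        if spec.exon_first == spec.exon_last:
            return f"{spec.exon_first}{suffix}"
        return f"{spec.exon_first}-{spec.exon_last}{suffix}"
    return spec.raw


def _spec_sort_pos(spec) -> int:
    if spec.exon_first is not None:
        return spec.exon_first
    return spec.c_start or 0


def mutation_frequency(
    records: list[PatientRecord], kind: str = "all", top_n: int = 10
) -> pd.DataFrame:
    """Exact-mutation counts of the requested kind, most frequent first.

    Splice-site mutations keep their own kind here (they are not folded into
    the exon skips they cause).  Ties break by 5'-most exon index (or cDNA
    position), then lexicographically.  Returns the ``top_n`` rows as a
    DataFrame with columns ``mutation`` and ``count``.
    """
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    if kind not in _KIND_FILTER:
        raise ValueError(f"kind must be one of {sorted(_KIND_FILTER)}, got {kind!r}")
    wanted = _KIND_FILTER[kind]

    counts: dict[str, list] = {}
    for rec in records:
        if rec.filtered:
            continue
        try:
            ms = parse_mutation(rec.mutation_text)
        except UnparseableMutation:
            continue
        for spec in ms:
            if spec.kind not in wanted:
                continue
            label = _spec_label(spec)
            entry = counts.setdefault(label, [0, _spec_sort_pos(spec)])
            entry[0] += 1

    ordered = sorted(counts.items(), key=lambda kv: (-kv[1][0], kv[1][1], kv[0]))
    rows = [{"mutation": label, "count": c[0]} for label, c in ordered[:top_n]]
    return pd.DataFrame(rows, columns=["mutation", "count"])


# -- smart screening of incomplete visit tables -----------------------------

@dataclass(frozen=True)
class ScreeningConfig:
    """Weights and hard requirements for visit screening.

    ``weights`` maps indicator name -> non-negative weight (unnamed
    indicators default to 1).  Any visit missing an ``indispensable``
    indicator is discarded outright.  ``mode`` selects what the score sums:
    ``"presence"`` (default) scores weighted completeness — a missing cell
    contributes 0, a measured one its weight — while ``"value"`` multiplies
    weights by the measured values themselves.
    """

    weights: dict[str, float] = field(default_factory=dict)
    indispensable: frozenset[str] = frozenset()
    mode: str = "presence"

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", dict(self.weights))
        object.__setattr__(self, "indispensable", frozenset(self.indispensable))
        for name, w in self.weights.items():
            if w < 0:
                raise ScreeningConfigError(f"weight for {name!r} is negative ({w})")
        if self.mode not in ("presence", "value"):
            raise ScreeningConfigError(f"unknown mode {self.mode!r}")


_META_COLUMNS = ("id", "patient_id", "visit")


def read_visit_table(path: str | Path) -> pd.DataFrame:
    """Read a wide visit TSV (blank cells = missing measurements)."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise TableFormatError(f"{path}: empty visit table") from exc
    if df.empty:
        raise TableFormatError(f"{path}: visit table has no rows")
    return df


def smart_screen(visits: pd.DataFrame, cfg: ScreeningConfig | None = None) -> pd.DataFrame:
    """Score and filter visits, most informative first.

    Score = sum over indicator columns of weight_i x indicator_i, where
    indicator_i is 1 if measured / 0 if missing (presence mode) or the
    measured value (value mode).  Visits missing any indispensable
    indicator are discarded.  Sorting is by descending score and stable, so
    the input order breaks ties; the result carries a ``score`` column.
    """
    cfg = cfg or ScreeningConfig()
    meta = [c for c in visits.columns if c.lower() in _META_COLUMNS]
    indicators = [c for c in visits.columns if c not in meta]

    for name in list(cfg.weights) + list(cfg.indispensable):
        if name not in indicators:
            raise ScreeningConfigError(
                f"indicator {name!r} not in table columns {indicators}"
            )

    present = visits[indicators].notna()
    keep = pd.Series(True, index=visits.index)
    for name in cfg.indispensable:
        keep &= present[name]

    weights = {c: cfg.weights.get(c, 1.0) for c in indicators}
    if cfg.mode == "presence":
        score = sum(present[c] * w for c, w in weights.items())
    else:
        score = sum(visits[c].fillna(0.0) * w for c, w in weights.items())

    out = visits.loc[keep].copy()
    out["score"] = score[keep]
    return out.sort_values("score", ascending=False, kind="stable")
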