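"""Vector-figure rendering: mutated-protein diagrams, frequency histograms,
and multi-family pedigrees.

All drawing is matplotlib-based and deterministic: figure geometry is
computed from the input objects only, so re-rendering a spec produces
identical segment layouts.  PDF is the primary output format; any extension
matplotlib understands (svg, png) works as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import pandas as pd
from matplotlib.backends.backend_pdf import PdfPages
from matplotlib.lines import Line2D
from matplotlib.patches import Circle, FancyArrow, Rectangle

from .mutations import MutatedTranscript, MutationKind, apply_mutations
from .protein import ProteinResult, translate_from
from .reference import DomainMap, TranscriptModel

DOMAIN_COLORS = {
    "ABD": "#d95f02",
    "ROD": "#7570b3",
    "CYS_RICH": "#1b9e77",
    "C_TERM": "#e7298a",
    "SYNTROPHIN_BINDING": "#66a61e",
}
SEGMENT_COLORS = {
    "retained": "#bbbbbb",
    "deleted": "#ffffff",
    "duplicated": "#fdbf6f",
    "novel": "#e31a1c",
}


@dataclass(frozen=True)
class Segment:
    kind: str  # retained | deleted | duplicated | novel
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if self.aa_start > self.aa_end:
            raise ValueError(f"empty segment {self.aa_start}-{self.aa_end}")


@dataclass(frozen=True)
class ProteinDiagramSpec:
    """Geometry of a one-patient protein diagram.

    The reference track shows the domain-coloured wild-type protein; the
    mutated track shows which reference regions are retained, deleted or
    duplicated plus any novel (frameshifted) C-terminal run, with a marker
    at a premature stop.  All coordinates are 1-based amino-acid positions.
    """

    title: str
    ref_length_aa: int
    domains: tuple[tuple[str, int, int], ...]  # (name, aa_start, aa_end)
    mut_segments: tuple[Segment, ...]
    mut_length_aa: int
    stop_marker_aa: int | None = None
    labels: tuple[str, ...] = ()


def _exon_aa_range(model: TranscriptModel, first: int, last: int) -> tuple[int, int] | None:
    """Project an exon span to 1-based aa coordinates of the reference protein.

    Exons wholly inside the UTRs project to nothing; boundaries use the
    cumulative coding length / 3 convention so adjacent domains tile the
    protein without gaps.
    """
    start_nt = max(model.exon_start(first), model.cds_start)
    end_nt = min(model.exon_end(last), model.cds_end - 3)  # exclude terminator
    if start_nt > end_nt:
        return None
    aa_start = (start_nt - model.cds_start) // 3 + 1
    aa_end = (end_nt - model.cds_start) // 3 + 1
    n = model.protein_length
    return max(1, min(aa_start, n)), max(1, min(aa_end, n))


def build_protein_diagram(
    model: TranscriptModel,
    dmap: DomainMap,
    mt: MutatedTranscript,
    pr: ProteinResult,
    title: str = "",
    labels: tuple[str, ...] = (),
) -> ProteinDiagramSpec:
    """Derive diagram geometry for one mutated transcript."""
    domains = []
    for name, first, last in dmap.entries:
        if last > model.n_exons:
            continue
        rng = _exon_aa_range(model, first, last)
        if rng:
            domains.append((name, rng[0], rng[1]))

    deleted: list[tuple[int, int]] = []
    duplicated: list[tuple[int, int]] = []
    shift_aa: int | None = None
    cum_net = 0
    for spec, note in mt.applied:
        if "ignored" in note or "no transcript" in note:
            continue
        if spec.kind is MutationKind.SPLICE_SITE:
            # resolved to an exon skip; find the skipped exon from the note
            rng = None
            for tok in note.split():
                if tok.isdigit():
                    rng = _exon_aa_range(model, int(tok), int(tok))
                    break
        elif spec.exon_first is not None:
            rng = _exon_aa_range(model, spec.exon_first, spec.exon_last)
        elif spec.c_start is not None:
            rng = ((spec.c_start - 1) // 3 + 1, (spec.c_end - 1) // 3 + 1)
        else:
            rng = None
        if rng is None:
            continue
        delta = _spec_delta(spec, model)
        if spec.kind in (MutationKind.EXON_DEL, MutationKind.SMALL_DEL):
            if delta % 3 == 0 and delta != 0:
                # in-frame deletion: span exactly the net codons removed
                rng = (rng[0], rng[0] + (-delta) // 3 - 1)
            deleted.append(rng)
        elif spec.kind in (MutationKind.EXON_DUP, MutationKind.SMALL_DUP):
            duplicated.append(rng)
        if shift_aa is None and (cum_net + delta) % 3 != 0 and delta % 3 != 0:
            shift_aa = rng[0]
        cum_net += delta

    segments: list[Segment] = []
    n = model.protein_length
    cursor = 1
    for a, b in sorted(deleted):
        if cursor <= a - 1:
            segments.append(Segment("retained", cursor, a - 1))
        segments.append(Segment("deleted", a, b))
        cursor = b + 1
    if cursor <= n:
        segments.append(Segment("retained", cursor, n))
    for a, b in sorted(duplicated):
        segments.append(Segment("duplicated", a, b))

    stop_marker = None
    if pr.premature_stop and pr.length_aa > 0:
        stop_marker = pr.length_aa + 1
    novel_start = shift_aa
    if novel_start is not None and pr.length_aa >= novel_start:
        segments.append(Segment("novel", novel_start, pr.length_aa))

    return ProteinDiagramSpec(
        title=title or model.name,
        ref_length_aa=n,
        domains=tuple(domains),
        mut_segments=tuple(segments),
        mut_length_aa=pr.length_aa,
        stop_marker_aa=stop_marker,
        labels=tuple(labels),
    )


def _spec_delta(spec, model: TranscriptModel) -> int:
    from .mutations import MutationSet, net_exonic_length_change

    try:
        return net_exonic_length_change(MutationSet(specs=(spec,)), model)
    except Exception:
        return 0


def _draw_one_protein(ax, spec: ProteinDiagramSpec) -> None:
    h = 0.28
    for name, a, b in spec.domains:
        # narrower entries (syntrophin region) drawn on top of their parent
        ax.add_patch(
            Rectangle(
                (a, 1.0), b - a + 1, h,
                facecolor=DOMAIN_COLORS.get(name, "#999999"),
                edgecolor="black", linewidth=0.4,
            )
        )
        if b - a > spec.ref_length_aa * 0.04:
            ax.text((a + b) / 2, 1.0 + h / 2, name, ha="center", va="center", fontsize=7)
    for seg in spec.mut_segments:
        y = 0.3 if seg.kind != "duplicated" else 0.02
        ax.add_patch(
            Rectangle(
                (seg.aa_start, y), seg.aa_end - seg.aa_start + 1, h,
                facecolor=SEGMENT_COLORS[seg.kind],
                edgecolor="black", linewidth=0.4,
                hatch="//" if seg.kind == "deleted" else None,
            )
        )
    if spec.stop_marker_aa is not None:
        ax.plot([spec.stop_marker_aa], [0.3 + h + 0.06], marker="v", color="red", ms=6)
        ax.text(spec.stop_marker_aa, 0.3 + h + 0.16, "stop", ha="center", fontsize=7, color="red")
    ax.text(0, 1.0 + h + 0.1, f"reference ({spec.ref_length_aa} aa)", fontsize=8)
    ax.text(0, 0.3 + h + 0.28, f"mutated ({spec.mut_length_aa} aa)", fontsize=8)
    for i, lab in enumerate(spec.labels):
        ax.text(0, -0.15 - 0.12 * i, lab, fontsize=7)
    ax.set_xlim(-spec.ref_length_aa * 0.02, spec.ref_length_aa * 1.05)
    ax.set_ylim(-0.2 - 0.12 * len(spec.labels), 1.75)
    ax.set_title(spec.title, fontsize=10)
    ax.set_xlabel("amino-acid position")
    ax.get_yaxis().set_visible(False)
    for side in ("left", "right", "top"):
        ax.spines[side].set_visible(False)


def draw_protein(specs, out: str | Path) -> Path:
    """Render one or more ProteinDiagramSpec pages to a vector file.

    PDF output gets one page per spec; other formats stack panels.
    """
    if isinstance(specs, ProteinDiagramSpec):
        specs = [specs]
    if not specs:
        raise ValueError("no diagram specs to draw")
    out = Path(out)
    if out.suffix.lower() == ".pdf":
        with PdfPages(out) as pdf:
            for spec in specs:
                fig, ax = plt.subplots(figsize=(9, 3.2))
                _draw_one_protein(ax, spec)
                fig.tight_layout()
                pdf.savefig(fig)
                plt.close(fig)
    else:
        fig, axes = plt.subplots(len(specs), 1, figsize=(9, 3.2 * len(specs)), squeeze=False)
        for ax, spec in zip(axes.ravel(), specs):
            _draw_one_protein(ax, spec)
        fig.tight_layout()
        fig.savefig(out)
        plt.close(fig)
    return out


def draw_protein_case(
    model: TranscriptModel,
    mutation_text: str,
    out: str | Path,
    dmap: DomainMap | None = None,
) -> ProteinDiagramSpec:
    """Convenience wrapper: parse, apply, translate and draw one case."""
    from .mutations import parse_mutation

    dmap = dmap or DomainMap.default_dystrophin()
    ms = parse_mutation(mutation_text, model)
    mt = apply_mutations(model, ms)
    pr = translate_from(mt)
    spec = build_protein_diagram(
        model, dmap, mt, pr, title=mutation_text, labels=(mutation_text,)
    )
    draw_protein(spec, out)
    return spec


# -- frequency histogram ----------------------------------------------------

def draw_frequency_histogram(freq: pd.DataFrame, out: str | Path, title: str = "") -> Path:
    """Bar chart of a mutation-frequency table (one labelled bar per row)."""
    if freq.empty:
        raise ValueError("frequency table is empty; nothing to draw")
    out = Path(out)
    fig, ax = plt.subplots(figsize=(max(4, 0.7 * len(freq) + 2), 4))
    ax.bar(range(len(freq)), freq["count"], color="#4575b4", edgecolor="black")
    for i, c in enumerate(freq["count"]):
        ax.text(i, c, str(int(c)), ha="center", va="bottom", fontsize=8)
    ax.set_xticks(range(len(freq)))
    ax.set_xticklabels(freq["mutation"], rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("patients")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
    return out


# -- pedigrees --------------------------------------------------------------

STATUSES = ("affected_DMD", "affected_BMD", "carrier", "unaffected")
_STATUS_FILL = {
    "affected_DMD": "#333333",
    "affected_BMD": "#999999",
    "carrier": "white",
    "unaffected": "white",
}


class PedigreeError(ValueError):
    """Invalid pedigree table (unknown parents, cycles, bad statuses)."""


def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Read a PED-like TSV: family_id, individual_id, father_id, mother_id,
    sex (M/F or 1/2), status, optional proband flag (0/1).  Founders use 0
    for the missing parent."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("0")
    required = ["family_id", "individual_id", "father_id", "mother_id", "sex", "status"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PedigreeError(f"pedigree table missing columns {missing}")
    if "proband" not in df.columns:
        df["proband"] = "0"
    validate_pedigree(df)
    return df


def validate_pedigree(df: pd.DataFrame) -> None:
    for fam, sub in df.groupby("family_id"):
        ids = set(sub["individual_id"])
        for _, row in sub.iterrows():
            for parent in (row["father_id"], row["mother_id"]):
                if parent != "0" and parent not in ids:
                    raise PedigreeError(
                        f"family {fam}: parent {parent!r} of "
                        f"{row['individual_id']!r} not in table"
                    )
            if row["status"] not in STATUSES:
                raise PedigreeError(
                    f"family {fam}: status {row['status']!r} not in {STATUSES}"
                )
        g = nx.DiGraph()
        g.add_nodes_from(ids)
        for _, row in sub.iterrows():
            for parent in (row["father_id"], row["mother_id"]):
                if parent != "0":
                    g.add_edge(parent, row["individual_id"])
        if not nx.is_directed_acyclic_graph(g):
            raise PedigreeError(f"family {fam}: cyclic parentage")


def _generations(sub: pd.DataFrame) -> dict[str, int]:
    g = nx.DiGraph()
    g.add_nodes_from(sub["individual_id"])
    for _, row in sub.iterrows():
        for parent in (row["father_id"], row["mother_id"]):
            if parent != "0":
                g.add_edge(parent, row["individual_id"])
    depth = {n: 0 for n in nx.topological_sort(g)}
    for n in nx.topological_sort(g):
        for child in g.successors(n):
            depth[child] = max(depth[child], depth[n] + 1)
    return depth


def draw_pedigrees(ped: pd.DataFrame, out: str | Path) -> Path:
    """Render every family in the table, one panel per family.

    Layout is generation-layered (founders on top, siblings ordered by id);
    squares are male, circles female, fill shade encodes affected status
    (dark = DMD, grey = BMD), a centre dot marks carriers and an arrow the
    proband.
    """
    validate_pedigree(ped)
    families = sorted(ped["family_id"].unique())
    fig, axes = plt.subplots(
        1, len(families), figsize=(5 * len(families), 4), squeeze=False
    )
    for ax, fam in zip(axes.ravel(), families):
        sub = ped[ped["family_id"] == fam]
        depth = _generations(sub)
        by_gen: dict[int, list[str]] = {}
        for ind in sorted(sub["individual_id"]):
            by_gen.setdefault(depth[ind], []).append(ind)
        pos = {}
        for gen, members in by_gen.items():
            for i, ind in enumerate(members):
                pos[ind] = (i - (len(members) - 1) / 2, -gen)
        r = 0.18
        for _, row in sub.iterrows():
            x, y = pos[row["individual_id"]]
            male = row["sex"].upper() in ("M", "1")
            fill = _STATUS_FILL[row["status"]]
            if male:
                ax.add_patch(
                    Rectangle((x - r, y - r), 2 * r, 2 * r, facecolor=fill,
                              edgecolor="black")
                )
            else:
                ax.add_patch(Circle((x, y), r, facecolor=fill, edgecolor="black"))
            if row["status"] == "carrier":
                ax.add_patch(Circle((x, y), r / 4, facecolor="black"))
            if row["proband"] == "1":
                ax.add_patch(
                    FancyArrow(x - 2.2 * r, y - 2.2 * r, r, r, width=0.015,
                               color="black", length_includes_head=True)
                )
            ax.text(x, y - 1.8 * r, row["individual_id"], ha="center", fontsize=7)
            for parent in (row["father_id"], row["mother_id"]):
                if parent != "0":
                    px, py = pos[parent]
                    ax.add_line(
                        Line2D([px, x], [py - r, y + r], color="black", linewidth=0.8)
                    )
        ax.set_title(f"family {fam}", fontsize=10)
        ax.set_aspect("equal")
        ax.autoscale()
        ax.margins(0.2)
        ax.axis("off")
    legend = [
        Line2D([], [], marker="s", color="w", markerfacecolor="#333333",
               markeredgecolor="black", ms=9, label="affected (DMD)"),
        Line2D([], [], marker="s", color="w", markerfacecolor="#999999",
               markeredgecolor="black", ms=9, label="affected (BMD)"),
        Line2D([], [], marker="o", color="w", markerfacecolor="white",
               markeredgecolor="black", ms=9, label="unaffected"),
    ]
    axes.ravel()[0].legend(handles=legend, fontsize=7, loc="lower left")
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
    return Path(out)
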