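# Methods

## Transcript model and coordinates

A transcript is a named, ordered list of exons with 1-based CDS offsets
into the spliced sequence.  Validation enforces a well-formed ORF: ATG at
`cds_start`, a stop codon ending at `cds_end`, CDS length divisible by 3,
and no in-frame stop strictly inside the CDS.  Ambiguity codes are
rejected; sequences are uppercased on input.  cDNA ("c.") positions follow
the HGVS convention (position 1 = A of ATG); UTR coordinates (negative or
`*`-style) are rejected rather than guessed at.

The domain map assigns exon ranges to the four dystrophin domains plus the
syntrophin-binding region.  Only exons 71–74 (syntrophin binding) are fixed
by the clinical literature; the shipped boundaries (ABD 1–8, rod 9–63,
cysteine-rich 64–70, C-terminal 71–79) follow common convention and are
fully overridable through a `NAME=first-last` config file.  Lookup returns
the narrowest matching entry, so the syntrophin region wins over the
enclosing C-terminal domain.

## Mutation grammar and application

Recognised descriptions: whole-exon deletions/duplications
(`exon45-47del`), small HGVS-style edits (`c.9204_9207delCAAA`,
`c.1898dupA`, `c.123_124insAT`, `c.9568C>T`) and near-exon splice-site
substitutions (`c.9563+1G>A`).  Compound genotypes join tokens with
`" plus "` or a spaced `" + "`; a trailing protein annotation (`p.…`) is
ignored.  A description that does not determine the exact nucleotide change
(`c.1335ins680`, `Dp427cdel`) raises a typed error and the record is
filtered from prediction rather than crashed on.

Application semantics:

* splice-site mutations within 10 nt of an exon boundary skip exactly the
  nearest exon (donor offset `+n` skips the exon ending at that boundary,
  acceptor `−n` the exon starting there); deeper offsets are mid-intronic
  and unsupported;
* duplications are tandem — the copy is inserted directly 3′ of the
  original block (placement is not otherwise specified by the clinical
  vocabulary);
* mutations apply 5′→3′; once translation of the current sequence stops
  upstream of a remaining mutation's position, that mutation is marked
  ignored;
* a deletion that names the promoter region and removes exon 1 yields no
  transcript at all; a plain `exon1del` keeps the transcript (promoter loss
  must be explicit in the description, via a configurable keyword list);
* overlapping edits in one genotype are rejected;
* stated reference alleles are checked against the model and mismatches are
  errors, not silent corrections.

Edits track the displaced positions of the start codon and natural
terminator, so downstream analysis can distinguish "stops at the (moved)
natural terminator" from "stops early".  Destroying the start codon yields
a length-0 product; destroying the terminator lets translation run into the
3′UTR.

## Translation and stop-gain counting

Translation uses the standard genetic code from the (possibly shifted)
start codon to the first in-frame stop; with no stop, it runs to the last
complete codon and sets `non_stop`.  A premature stop is any terminating
stop whose position differs from the tracked natural terminator.

The potential stop-gain count scans in-frame trinucleotides from the start
codon through the *entire* mutated transcript, 3′UTR included, because
frameshifts read through the natural terminator; the trailing partial codon
(<3 nt) is ignored.  On a valid unmutated transcript the count is exactly 1
(the terminator).  Whether the count should stop at the original CDS bounds
is ambiguous in the clinical usage; the permissive whole-transcript reading
is used, and the synthetic generator keeps reference 3′UTRs free of
in-frame stops so the baseline of 1 holds by construction.  Selenocysteine
recoding is ignored.

## The classifier

Rule thresholds (defaults, dystrophin scale):

| parameter | default | meaning |
|---|---|---|
| `length_low` | 3000 aa | products shorter than this are DMD |
| `length_high` | 3685 aa | products longer than the normal protein are DMD |
| `stopgain_normal` | 1 | any other in-frame stop count is DMD |
| `rod_exon_limit` | 35 exons | in-frame rod deletions above this are DMD |
| `joint_criterion` | ANY | DMD if any rule votes DMD (MAJORITY: ≥2 of 3) |

For synthetic mini-genes, `ClassifierConfig.scaled_to(model)` keeps the
same 3000/3685 proportion relative to the model's own protein length, so
the length rule is exercisable at any scale.

The frame rule returns NA for pure nonsense substitutions (they change no
length; the length and stop-gain rules carry them), and NA votes are
dropped — not counted as BMD — in the joint verdict.  Location patterns are
evaluated most-specific-first (ABD+rod → exons 2–8 → rod size → cysteine-
rich → syntrophin) and, when one matches, override the joint verdict by
default; a config switch (`patterns_override=False`) makes them a fourth
vote instead, since the historical behaviour is not fully specified.  The
ESE rule defaults to off; when enabled, a disrupting exonic substitution is
re-interpreted as a skip of its containing exon (`ese_action="skip_exon"`),
with a plain "call DMD" alternative behind the same switch.

Evaluation follows the clinical convention: a false positive calls an
observed BMD patient DMD, a false negative the reverse; denominators are
whole class rows, so accuracy + FPR + FNR = 100% up to rounding.
Percentages are rounded half-up to one decimal.  The `total` row sums the
three canonical classes (large deletions/duplications, small
deletions/duplications, splice sites); nonsense, missense and combination
records are reported as separate rows.

## ESE scoring

Matrices are additive position weight matrices with per-matrix calling
thresholds, read from a plain-text block format.  A substitution disrupts
an ESE when some window within the containing exon, overlapping the
substituted base, scores at or above threshold in the reference and below
it after the change; windows do not cross exon boundaries because
enhancers act on exonic sequence.  The bundled file
`ese_matrices_synthetic.txt` mirrors the classic four-SR-protein layout
(widths 7/8/7/6) but both weights and thresholds are synthetic stand-ins —
shaped around arbitrary consensus motifs, thresholds placed about one score
unit below each consensus maximum so called sites exist and strong
single-base hits can disrupt them.  Substitute a measured matrix file for
real scoring.

## Synthetic data: what it emulates and what it does not

The mini-gene generator emulates the mechanics a transcript-level predictor
needs — multi-exon structure with a mix of frame-preserving and
frame-shifting exon lengths (about half of each by default), short UTRs, a
valid ORF — at a tractable size (default 12 exons of 60–200 nt, ~500 aa).
The cohort generator draws mutation classes from a configurable mix whose
default keeps large deletions most common, then duplications and point
mutations, echoing the reported ordering in dystrophin cohorts (deletions
~68%, duplications ~11% of large events) without modelling hotspots,
X-linked ascertainment, or genotype–phenotype noise.  Ground-truth labels
are **mechanistic**: DMD iff the product is absent, truncated prematurely,
never stops, or leaves the allowed length window; BMD otherwise.  Passing
tests therefore demonstrate that the classifier recovers the consequences
of its own mechanistic model — they do not demonstrate clinical accuracy on
real patients, whose exceptions (junctional effects, splicing regulation,
modifier genes) are exactly what the location patterns approximate.

Two deliberate generator scope choices: exon duplications are drawn only
from blocks 5′ of the terminator-containing exon, because a tandem copy of
the terminal block lands downstream of the stop codon and is
translationally silent (such draws would make the frame rule "wrong" for
reasons that carry no information); and reference 3′UTRs avoid in-frame
stop triplets so the stop-gain baseline is exactly 1.

## Numerical and degenerate-input choices

* Percentage rounding: decimal half-up to 1 decimal, matching clinical
  table style (5161/5681 → 90.8).
* Frequency-table ties break by 5′-most exon index (or cDNA position),
  then lexicographically; sorting is stable everywhere else.
* Visit screening interprets the weighted score as completeness
  (presence indicators 0/1) by default, because raw indicators have
  incommensurable units; `mode="value"` provides the literal
  value-weighted sum.
* Degenerate inputs fail loudly with typed errors: empty tables, all-NA
  verdict sets, empty frequency tables, cyclic pedigrees, inverted length
  windows.
* Rendering is deterministic given the spec object; diagram geometry is
  computed from amino-acid coordinates only (cumulative coding length / 3).

## Known limitations

* Genomic (intron-containing) coordinates, alternative isoforms/promoters
  (Dp427c, Dp71, …), mid-intronic mutations (>10 nt), inversions and
  mosaicism are out of scope.
* Intron retention as an alternative outcome of splice-site mutations is
  not modelled; skipping of the nearest exon is assumed.
* Nonsense-mediated decay and protein stability are not modelled; the
  length rule is a proxy.
* The frame-rule column for nonsense mutations reported in some historical
  evaluations implies an undefined behaviour that is deliberately not
  reproduced (NA instead).
* Pedigree layout is simple generation layering without crossing
  minimisation — adequate for clinic-sized families, not large kindreds.
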