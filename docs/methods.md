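# Methods

This note documents the models, default parameters and design decisions
behind `estclean`, in the order the pipeline applies them.

## Protocol model

A protocol is a plasmid vector sequence, the coordinates of the two vector
borders VF1/VF2 flanking the cloning sites, two enzyme recognition motifs
(defaults GAATTC/CTCGAG), and one adapter in both strand forms
(GGCACGAGG / CCTCGTGCC). The terminus grammar — which ordered element lists
constitute a terminus — is expanded mechanically from these motifs. Only
variants with published evidence are generated by default (so the 3TNS
family carries no bare-VF1′ mirror of a hypothetical 5TSS-5); configs may
add more. The exact element composition of 5TSS-1/5TSS-2/3TNS-2/3TNS-5 is
inferred from the abnormality signature tables and strand symmetry rather
than stated explicitly anywhere, and should be treated as an informed
reconstruction.

**Vector borders.** No published protocol states how much flanking vector
constitutes a "border"; we use the 50 bases adjacent to each cloning site
(configurable). Long enough to align confidently, short enough to fit inside
a Sanger read end.

**Fixture vector.** The real library vectors are not published, so the
default protocol carries a deterministic synthetic 3-kb plasmid: random
backbone with GAATTC planted at position 1400 and CTCGAG at 1606,
scrubbed (see below) so no other window resembles a protocol element. Users
supply real vectors via the YAML config.

**Coordinates.** 0-based half-open internally; 1-based inclusive in every
written report.

## Element detection

* **Quality segmentation** (window 20, threshold Q16): the read is tiled in
  consecutive windows; a window is high-quality when its mean phred is ≥ 16,
  and adjacent same-label windows merge. Tiled (rather than overlapping)
  windows keep segment boundaries sharp and the procedure trivially
  deterministic; boundary resolution is one window. A read without QUAL data
  is all-high.
* **Fixed motifs**: windowed Hamming scan. Enzyme sites (6-mers) are matched
  exactly — a 6-mer at 1 mismatch is indistinguishable from noise in a
  genome-scale scan. Adapters (9-mers) allow 1 mismatch.
* **Poly(A)/(T) tails**: maximal homopolymer runs starting and ending on the
  tail base, tolerating interior impurities up to 10% of run length, minimum
  8 bases. No published threshold exists; these are conventional Sanger-era
  values.
* **Vector fragments**: deterministic ungapped k-mer seed-and-extend (k=12,
  both strands, x-drop extension scoring +1/−3 with drop 9), keeping hits of
  ≥ 20 aligned bases at ≥ 94% identity. Substitutions dominate Sanger error;
  an indel splits a hit into two collinear pieces, which downstream coverage
  logic tolerates. VF1/VF2 *border elements* are only credited when the
  alignment reaches the border edge adjacent to its cloning site — a
  fragment from a wrong-site cut therefore reads as plain vector (V), which
  is what distinguishes the wrong-cut abnormality signatures from bordered
  termini.
* **Context labels**: an interval is V (vector) when ≥ 50% of it is covered
  by vector hits, H (high quality) when ≥ 50% is covered by high segments;
  otherwise N/L. The 50% rules are ours; only the four labels HV/LV/HN/LN
  themselves are prescribed.

## Terminus assembly and scoring

Element hits chain into terminus instances when consecutive components are
at most `max_gap` = 2 bases apart (tolerates one or two ambiguous calls).
A missing fixed-length motif element (enzyme site, adapter, single base) may
be filled by a *context-anchored literal match*: the read is checked directly
at the position implied by an anchored neighbour, with a 1-mismatch budget
for enzymes/adapters and 0 for single bases. Without this rescue a single
sequencing error in a 6-mer silently demotes a terminus variant and can flip
an abnormality class; with it, a terminus is only rescued where an
independently scanned variable-length element (poly tail, vector border)
anchors the chain. Variable-length elements are never rescued.

Scores per instance (each in [0,100]):

* **A (completeness)** = 100 × weight(variant) / weight(canonical), where
  each element weighs 1 except the degenerate single-base replacements
  (the C/G standing in for an enzyme site in 5TNS-4/3TSS-4), which weigh
  0.5 — a replaced site is evidence, but weaker than the real one, and this
  keeps exactly one maximal (canonical) definition per family.
* **B (context)** = mean over both flanks of: 100 if the 30-base flank
  matches expectation (vector beside the vector-side of a terminus, insert
  beside the insert side; a read boundary counts as matching), 50 if the
  flank is low-quality non-matching, 0 if confidently non-matching. The
  published rule covers only the vector-expected upstream flank of 5TSS; we
  generalize symmetrically and average — the resolution of an open question.
* **C (identity)** = 100 × matched bases / terminus span (gap bases count as
  unmatched).
* **Confidence** = w·(A,B,C); default weights (⅓,⅓,⅓) — no published basis
  for anything else; configurable. Weights must be non-negative and sum to
  1 (tolerance 1e-9).

**Disambiguation** of overlapping instances: a sub-variant never outranks a
same-family super-variant that spans it and matches its bases essentially
as well (C within 5 points) — sub-variants exist for loci where elements are
genuinely missing, not to shadow a complete terminus whose flank happens to
look unusual. Among the rest, highest confidence wins; ties break by larger
A, then the earlier-starting, longer hit. Deterministic for any input order.

## Patterns and classification

The read is tiled left-to-right: terminus intervals emit their names;
regions between them of ≥ 20 bases emit alternating V/N tokens for their
vector/non-vector runs (runs under 20 bases are absorbed into the larger
neighbour — a 3–15-base ligation spacer therefore never creates its own
token). Rendering joins tokens with commas.

RECA classification matches the rendering exactly against per-direction
signature templates (A1–F). The type-F signature (`V,N` / `N,V`) is
dangerously generic, so F additionally requires a vector hit mapping within
300 bases of the enzyme-1 cloning side, per its wrong-cut mechanism.
Unmatched patterns in which a V token is directly bracketed by termini fall
into `RECA-other`. DBT motifs are scanned non-overlapping left-to-right with
a 2-mismatch budget per 24-mer (random-sequence false-positive probability
≈ 1e-11 per window; an exact scan would lose ~21% of motifs at a 1%
substitution rate). Consecutive hits (gap 0) form numbered repetition runs.
A DBT strictly inside a 5TNS…3TNS span of a 3′ read whose flanking termini
do not themselves overlap a DBT is trimmable; every other DBT marks a
chimera. Precedence when several classifications apply:
RECA > DBT > CASE > direction-conflict; the first is the primary call,
the rest are kept as secondary annotations.

## Trimming

Clean extraction starts at the inner edges of the best reasonable pair
(separation ≥ 200 bases, highest cumulative confidence; ties by larger
separation, then leftmost), removes any excised-DBT span keeping the larger
remainder, then shrinks both ends past overlapping vector hits and
low-quality segments. Results shorter than `min_clean_len` = 100 are
rejected ("insert too short"); a left terminus ending at or after the right
one is a "degenerate pair".

Two deliberate extensions beyond the published procedure (which describes
pair selection only): (1) when no pair exists but one confident terminus
does, the read is trimmed from that terminus' inner edge to the read's
quality/vector boundary (flag-controlled, on by default — long inserts
routinely hide the far terminus); (2) reads with no termini at all are kept
as quality/vector-trimmed sequence with an `untrimmed-no-termini` warning
rather than silently dropped.

## Synthetic read generator

Each construct layout concatenates real protocol segments (borders, sites,
adapters, 18-base poly tails, the inter-site stuffer) around random insert
DNA (GC 0.45), reproducing the expected clone, each RECA type in both
directions, DBT chimeras/rescues, and the eight frequent simple cases. The
A2/B2 layouts insert a uniform 3–15-base random spacer at the incompatible
sticky-end junction. Insert lengths default to uniform 350–450 bases.

To keep ground truth exact at zero error rate, random sequence is
*scrubbed*: no window may lie within Hamming distance 1 of an enzyme motif
or 2 of an adapter form, contain a 6-base A/T homopolymer, or hold ≥ 9
identical A/T bases in any 10-window (which would seed an impurity-tolerant
poly-tail call); additionally the three free bases flanking any planted
poly-tail junction are forced off the tail base so runs cannot bleed across
truth boundaries. The noise model applies per-base substitutions/indels
(truth coordinates are remapped through indels) and a positional phred
profile whose default is flat Q40; Sanger-like low-start/decaying-tail
shapes are available by parameter.

What passing tests on this generator do **not** show: real chromatogram
artifacts (compressions, dye blobs), true Sanger quality profiles,
polymorphism against the vector, or partially degraded adapters — real
datasets will show lower detectable-terminus rates than the synthetic 100%.

## Benchmark sizes and numerical choices

The recovery experiments use 1,800 reads (100 per layout over an 18-layout
mix) and 10,000 random 120-base sequences for the scanner-vs-oracle checks —
large enough for stable percentages, small enough to re-run interactively.
All randomness flows from a single integer seed; identical inputs and
parameters give byte-identical outputs. Degenerate inputs (empty reads,
non-DNA characters, mismatched QUAL lengths) produce per-read "invalid
input" reports, never exceptions.

## Known limitations

* Vector matching is ungapped; a hit containing an indel is reported as two
  collinear hits, slightly under-counting identity near indels.
* RECA templates are matched exactly (after V/N coarsening); heavily
  degraded abnormal reads fall into `RECA-other` or remain unclassified
  rather than being fuzzily matched.
* Only two-enzyme directional protocols are expressible; no support for
  more enzymes or non-directional cloning.
* Quality must arrive as FASTA+QUAL; chromatograms (SCF/ABI) are not parsed.
* Chimeric reads are filtered, not split into their component inserts.
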