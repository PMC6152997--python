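# Methods

## Scope and model

`premascan` predicts deletion outcomes of microhomology-mediated end
joining (MMEJ) at programmable-nuclease cut sites and recommends sites
expected to resolve into a single predominant deletion allele. The
model is purely sequence-based: it assumes MMEJ uses direct repeats of
at least 3 bp lying wholly on opposite sides of the break, that repair
deletes the span from the left arm copy to the right arm copy
(retaining one copy at the junction), and that the relative propensity
of competing deletions follows the Bae-style Pattern Score

    score = 100 · round(e^(−Δ/20), 3) · (AT + 2·GC)

with Δ the deletion length and AT/GC the base counts of one arm. No
chromatin, cell-cycle, or expression context enters the model; those
are known modifiers of end-joining pathway choice and are out of scope.

## Coordinates and conventions

All internal coordinates are 0-based, half-open; reports add 1-based
inclusive columns. `cut_index` counts the bases 5′ of the break. Arm
copies may abut the break but never straddle it — the left copy ends at
or before `cut_index`, the right copy starts at or after it. This
matches the search behaviour of the original reference implementation;
whether a straddling arm should count is not observable from published
outputs, and the stricter contract is the testable one.

## Enumeration and deduplication

Within a window (default 40 bp per side, truncated at sequence ends)
every identical substring pair with arm ≥ `min_arm` (default 3; a
comparison mode lowers it to 2 for arm-length sensitivity analyses) is
collected. A pattern is then removed if its arm is a substring of a
longer pattern's arm **and** both deletions produce the identical
resulting sequence: such nested sub-arms describe the same physical
deletion and would otherwise compete with themselves. Output order is
deterministic (left coordinate, right coordinate, arm length).

The 3-decimal rounding of the exponential length factor replicates the
reference tool's displayed arithmetic and is on by default
(`replicate_reference_rounding`); turning it off gives the unrounded
factor. The decay constant (20 bp) is exposed in `ScanConfig` but is
part of the score's definition, not a tuning knob.

## Competition metrics and grouping

Patterns are ranked by descending score with a deterministic tie-break
(longer arm, then smaller deletion, then smaller left coordinate —
invented plumbing; the model itself defines no tie rule).

* **Top/second ratio.** A single pattern is the zero-competition limit
  and reported as ∞ (criterion 2 holds). An exact tie gives 1.0 and
  fails criterion 2 — a tied allele cannot be predominant; the profile
  carries a `tie_top` flag.
* **Slope Value.** Ordinary least-squares slope of score against
  1-based rank over the top 10 patterns (all, if fewer). This is a
  reconstruction: the original calculation note is not available in the
  source text, and this definition is chosen because it reproduces the
  published −40 cutoff's units (score per rank) and the flat-vs-steep
  dichotomy. The number of ranks used is configurable (`top_n`) because
  the original choice is unknown. The slope-based classifier (slope
  < −40 ⇒ low competition) is retained behind `is_low_competition` for
  reproducing the earlier single-parameter analyses; the two-criteria
  grouping is the default recommender.
* **Criterion 1** measures the *intervening* gap between arm copies
  (≤ 5 bp), not the deletion length — arms "separated by" n bases.
* **Groups.** criterion1 ∧ criterion2 → 4; criterion1 only → 3;
  criterion2 only → 2; neither → 1. A locus with no pattern is
  ungrouped and never recommended.

## Scanning

PAMs are matched as IUPAC classes on both strands (reverse-strand hits
are matched as the reverse-complement motif on the forward strand);
ambiguous bases in the *subject* never match. The break is placed
`cut_offset` nt from the PAM-proximal end (default −3: the SpCas9 blunt
cut between protospacer positions 17 and 18). TALEN layouts place the
break at the spacer midpoint, the extra base going 5′ for odd spacers;
the 5′-overhang stagger of sticky-end TALENs is collapsed to a single
index because the scoring model is break-position based — a documented
simplification. Sites whose guide or search window is clipped by the
sequence end are flagged, not dropped. For prevalence accounting,
forward and reverse PAM hits implying the same break position share one
deletion landscape and are counted once as a unique cut site; both
guides remain in the scan report.

## Outcome accounting

Observed alleles are compared within an analysis window (±25 bp by
convention) against the predicted landscape:

* `top_mh` — matches the top-predicted deletion with ≤ 2 substitutions,
  none on the retained arm;
* `other_mmej` — matches any other enumerated pattern's deletion under
  the same tolerance (this defines the Microhomology Fraction's
  numerator; the original calculation note is unavailable and this
  all-enumerated-deletions reading is a documented reconstruction);
* `wildtype` — reference length, ≤ 2 substitutions, no indel;
* `other_mutant` — everything else; any insertion, including
  deletion+insertion compounds, is never MMEJ-consistent;
* `excluded` — invalid characters or length discrepancies beyond what
  an in-window deletion (≤ 2 × window) could produce.

Metrics: mutagenic efficiency = mutant / non-excluded reads;
Microhomology Fraction = (top_mh + other_mmej) / mutant; Top MH
Fraction = top_mh / mutant. The PreMA call requires the top predicted
allele to be strictly modal among distinct mutant alleles, Top MH
Fraction ≥ 0.5, and efficiency strictly > 0.2. Separately, loci with
efficiency < 0.2 are flagged `low_activity` (the retrospective-analysis
inclusion filter); the two thresholds are deliberately distinct
comparisons on the same constant.

`tide_adjusted_prevalence` renormalizes an indel-size decomposition
(e.g. chromatogram-decomposition output consumed as a table) to the
significant mutant signal, the decomposition analogue of the Top MH
Fraction.

## Synthetic loci

`plant_locus` emits a sequence whose in-window landscape is *exactly*
the planted repeat pair plus requested decoys. Any stray cross-break
repeat of ≥ 3 bp implies a 3-mer present on both sides of the break, so
the background is filled base by base under a no-shared-3-mer
constraint, by depth-first search with backtracking (most-constrained
positions — those wedged against planted arms — first, and a preference
for reusing 3-mers already present on a side, since only 64 exist).
Arms are drawn with internally unique 3-mers, disjoint vocabularies
across arms, and a guard against saturating any 2-mer context. Decoy
pairs are stacked outward with arm length/composition searched to
approach `decoy_strength` × planted score without displacing the top
pattern (for strength ≤ 1), preferring short arms among near-equal
candidates to conserve the 3-mer budget. Every emitted locus passes an
independent brute-force repeat audit before it is returned; the
generator retries with fresh draws (bounded, default 100) rather than
patching a failed sequence, which keeps the procedure deterministic per
seed. Consequences: background base composition follows `background_gc`
only approximately once the repeat constraint binds, and requested
decoy strengths far from what the exponential length decay allows at
the available placements are met best-effort. Real genomic windows, by
contrast, are full of incidental weak repeats; passing tests on planted
loci therefore demonstrates correctness of the machinery, not realism
of the landscape — the synthetic-gene prevalence screen (random 2 kb
sequence) is the closer-to-realistic check and lands near the ~10 %
candidate prevalence seen on real genes.

`simulate_allele_table` draws a multinomial read table over
{wildtype, top_mh, other_mmej, other_mutant} with optional uniform
off-arm substitutions and retains ground-truth labels. Other-mutant
reads rotate through four distinct 1 bp insertions so modal-allele
logic is exercised. It does not model sequencing error profiles or
NHEJ insertion spectra.

## Test and script problem sizes

The shipped suite checks oracle equivalence on 200 random loci
(length ≤ 60, window 30), exact score parity on 50 random 80-mers, 100
planted loci per group archetype, and ~2 kb synthetic genes for the
scanner — sizes chosen so the whole suite runs in well under a minute
of CPU while every code path is exercised at full fidelity; the
acceptance script uses 50 planted loci per archetype for the same
reason. The two tests that would reproduce published external-data
analyses (the 8/9/30 grouping of 47 pooled reagents; the CSF2/tp53
prevalence) require genomic context that is not distributed with the
package and report as failures where it is absent.

## Known limitations

* Insertion and templated-insertion outcomes are not predicted.
* The Slope Value and Microhomology Fraction definitions are
  reconstructions (see above) and labelled as such.
* TALEN overhang geometry is collapsed to a single break index.
* The score model ignores sequence context beyond the arms themselves.
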