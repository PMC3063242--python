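# Methods

## Site anatomy and the consensus model

A candidate window is 34 nt: a left Flp-binding element (positions
−13…−1), an 8-nt spacer (s1…s8), and a right element (1…13); there is no
position 0.  The discovery consensus is the wild-type FRT element pair
with the degeneracy known to be tolerated by evolvable Flp variants:
position 1 ∈ {A,G} (hence −1 ∈ {C,T} on the top strand), positions ±2 ∈
{A,T}, every other element position fixed at wild type.  The default
model is reverse-complement symmetric — the allowed set at −p is the
base complement of the set at p — which makes the whole rule cascade
closed under reverse complement and justifies single-strand scanning.

All rule parameters live in `ConsensusModel` (YAML-configurable through
`load_consensus`, with elements given as 13-character IUPAC strings):

| parameter | default | meaning |
|---|---|---|
| `spacer_first_base` / `spacer_last_base` | T / A | required s1 / s8 bases |
| `spacer_max_gc_bases` | 4 | max G+C in the 8-nt spacer (≤ 50%) |
| `max_homopolymer_run` | 4 | longest permitted single-base run in the 34-mer |
| `min_proximal8_matches` | 5 | class floor over positions −4…−1, 1…4 |
| `forbidden_base_minus1` / `forbidden_base_plus1` | G / C | hard exclusions at ∓1 |
| `min_element_matches_one_side` | 5 | matches required in at least one element |
| `min_consecutive_matches` | 6 | required consecutive-match run (see below) |
| `position7_rule` | on | a match at −7 or +7 required |
| `weights` | 1.0 everywhere | per-position weights for the weighted score |

Rules are applied in a fixed order (sequence alphabet, spacer ends,
spacer GC, homopolymer, proximal-8 count, adjacent same-segment
mismatches, simultaneous ±1 mismatch, forbidden bases at ±1, position-7,
per-element matches, consecutive run), so the failure reason reported
for a rejected window is deterministic.

## Design choices where the rules were ambiguous

- **Consecutive-match rule.** "At least 6 consecutive matches" within the
  binding elements is read as: the *maximum* run over the two elements
  must reach the threshold.  The stricter reading (a run in *each*
  element) is available as `require_run_both_elements`; it is off by
  default because class-5 sites with mismatches in both elements would
  otherwise be unreachable.
- **Scores annotate, never filter.** Overall (matched positions, 0–26),
  weighted (sum of per-position weights over matches) and consecutive
  (longest within-element run) scores are reported for downstream
  re-sorting; acceptance depends only on the rules above.  Default
  weights are 1.0 at every position, making the weighted score equal the
  overall score unless a custom weight vector is supplied.
- **Ambiguity codes.** Windows containing anything outside A/C/G/T after
  case-folding are rejected (not errored), so N-runs and IUPAC codes in
  assemblies are simply skipped; lowercase soft-masking is folded and
  scanned, since many genuine sites sit inside repeats.
- **Coordinates.** 0-based half-open internally and in BED export;
  1-based inclusive in TSV reports.

## Scanning and duplicate partitioning

Contigs are streamed in ~10-kb chunks with a 33-bp (window − 1)
carry-over — the minimal overlap for which chunked scanning is provably
identical to whole-string scanning, which a test asserts.  A vectorized
prefilter keeps only offsets whose s1/s8 characters can satisfy the
spacer rule before the full cascade runs.  Genome layout (ordered
contigs per chromosome with cumulative offsets) comes from a manifest
TSV rather than hard-coded filenames, generalising the original
one-build bookkeeping.  Duplicate detection keys every hit by
min(34-mer, reverse complement) and holds only keys and hit indices in
memory; groups of ≥ 2 form the duplicated pool, the rest the unique
pool, and `|hits| = |unique| + Σ copy_number` is asserted on every run.
Overlapping degenerate-palindrome readings at distinct offsets count as
distinct hits.

## Classes, subclasses and the theoretical catalogue

Class = number of proximal-8 matches (5–8).  Subclass = the concrete
proximal-8 sequence (degenerate positions included), encoded A=1, T=2,
G=3, C=4 over (−4,−3,−2,−1,1,2,3,4) and canonicalized as the minimum of
the forward code and the code of the reverse-complemented site.
`enumerate_subclasses(k)` filters all 4⁸ = 65,536 proximal-8 sequences
by the proximal-8-local rules only (element and spacer rules do not
constrain the region), collapses reverse-complement pairs, and returns
the canonical patterns.  Under the default model this yields **10**
class-8 subclasses and 120 / 558 / 696 for classes 7 / 6 / 5.  Earlier
work reported 116 / 528 / 672 for the latter three; the textual rule set
reproduces the class-8 count exactly but evidently omits one or more
constraints of the original scoring figure that trim the lower classes.
The package therefore reports its enumerated counts side by side with a
catalogue export (`frtscan enumerate --counts`; `sort` writes
`catalogue.tsv` with an observed flag) instead of treating those counts
as ground truth.  Genome-scale consequences (the published 642,151-hit
human-genome total) would inherit the same sensitivity: the counts
depend on rule details at mismatch-dense windows, so a full-build rerun
is expected to land near, not exactly on, previously reported totals.

## Spacer grouping and homology search

Within a subclass, sites are bucketed by canonical spacer
(min(spacer, revcomp)); buckets of ≥ 2 are recombination-compatible
groups, emitted before singletons, with the classic blank-line-delimited
text layout kept alongside a machine-readable TSV.  The spacer is read
in the site's canonical orientation (flag for raw strand order), so
"same subclass + same canonical spacer" is orientation-consistent.
Homology to a query 34-mer is positionwise identity, maximum over the
subject's two orientations, optionally restricted to the 26 element
positions; self-matches are excluded by coordinate, not sequence, so
exact duplicates of the query elsewhere are reported — they are exactly
the off-target risk the search exists to expose.  The subclass report
lists the query's whole subclass regardless of threshold.

## Synthetic genomes and what they show

`simulate` builds fixture genomes: i.i.d. background at configurable GC,
planted sites of chosen class drawn by rejection sampling from the rule
set (proximal-8 pattern from the valid class-k patterns, spacer from the
spacer rules, distal bases biased 0.9 toward consensus), and repeat
families (a ~300-bp unit containing a verified site, copied with
optional per-copy point mutations).  Ground truth is defined by an
exhaustive rule scan of the *assembled* sequence, because background
drawn at human-like GC legitimately contains FRT-like sites (roughly one
per 10–25 kb here) and splice junctions can create new ones; planted
coordinates alone would mislabel those as false positives.  All
randomness derives from the spec seed.

The generator emulates composition (GC), plantedness and duplication —
not chromatin, repeat-family evolution, or the long-range structure of
real genomes.  Passing recovery tests therefore demonstrates the
correctness of the scanner/classifier machinery on sequence that obeys
the stated composition model, not performance claims about any
particular genome build.  Test problem sizes — 10,000-window oracle
sweeps, a 1-Mb oracle-equivalence genome, 40–200-kb pipeline fixtures —
were chosen to exercise chunk boundaries, multi-contig layouts and
duplicate structure at desk scale.

## Numerical and degenerate-input conventions

Windows shorter than 34 nt are usage errors at the evaluator but simply
yield no hits at the scanner; contigs shorter than 34 nt scan to empty.
Ties in canonical encodings (palindromic proximal-8, palindromic
spacers) resolve to the forward reading.  Subclass files are named by
zero-padded 8-digit canonical code for stable lexicographic ordering;
all writers are deterministic (stable sorts, no timestamps).

## Known limitations

- Recombination *efficiency* is not modelled: acceptance is a rule
  verdict, and scores are heuristics, not activity predictions.
- Homology is gapless by construction; indel-containing near-sites are
  out of scope.
- The class-7/6/5 theoretical counts differ from previously reported
  values as discussed above; users comparing against that catalogue
  should rely on the exported `catalogue.tsv` of this implementation.
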