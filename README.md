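# frtscan

Genome-wide discovery, classification and comparison of **FRT-like
sequences** — degenerate pseudo-sites for the yeast Flp site-specific
recombinase — for genome-engineering applications (targeted integration,
RMCE, and the selection of counter-selection targets during directed
evolution of Flp variants).

## The problem and the method

A minimal FRT site is 34 bp: two 13-bp inverted Flp-binding elements
(positions −13…−1 and 1…13) flanking an 8-bp asymmetric spacer
(s1…s8).  A mammalian genome contains many sequences close enough to FRT
that an evolved Flp variant can recombine them; finding and organising
them is the first step of any pseudo-site-based engineering project.

`frtscan` slides a 34-nt window over every contig of a genome build and
accepts a window as a *functional FRT-like sequence* when it satisfies an
experimentally derived rule set against a degenerate consensus (wild-type
FRT with A/G tolerated at position 1, hence C/T at −1, and A/T at
positions ±2):

- spacer starts with T (s1), ends with A (s8), and is ≤ 50% G+C;
- no single-nucleotide run longer than 4 anywhere in the 34-mer;
- **proximal-8 region** (positions −4…−1, 1…4 — the most critical
  determinant of Flp recognition): ≥ 5 matches, no adjacent mismatches
  within the same 4-bp segment, not both −1 and 1 mismatched, no G at −1
  and no C at 1;
- elements: a match at −7 or 7, ≥ 5 matches in at least one element, and
  a run of ≥ 6 consecutive matches within an element.

Scanning is forward-strand only: the rule set is closed under reverse
complement, so minus-strand sites are found through their plus-strand
reading.  Accepted sites are annotated with overall / weighted /
consecutive match scores, partitioned into **unique** and **duplicated**
pools by exact orientation-independent 34-mer identity, then sorted into
**classes** (number of proximal-8 matches: 8, 7, 6 or 5) and
**subclasses** (the concrete proximal-8 sequence, encoded as an 8-digit
number with A=1, T=2, G=3, C=4 and canonicalized as the minimum of the
forward and reverse-complement codes).  Within a subclass, sites with
identical spacers — in either orientation — are grouped: such sites can,
in principle, recombine with each other through a single Flp variant.
A positionwise identity search (`compare`) ranks all discovered sites
against a query site to propose counter-selection targets.

## Worked example

Generate a 50-kb fixture genome with one planted perfect-consensus site
and a 4-copy repeat family, then run the full pipeline:

```bash
frtscan simulate --out demo --seed 5 --chromosome chrA:50000:0.41 \
    --plant chrA:8000:8 --repeat chrA:4:0.0
frtscan scan demo/fasta --manifest demo/manifest.tsv --outdir demo/run --pipeline
```

which prints

```
wrote 1 chromosome(s) under demo/fasta; truth table: demo/truth.tsv (5 sites)
hits: 5  unique: 1  duplicated (distinct): 1  duplicated (total): 4
5 sites into 2 subclass files under demo/run/subclasses
spacer-grouped 2 subclass files under demo/run/spacer_groups
```

Five FRT-like sequences were found: the planted site (unique) and the
four verbatim repeat copies, which collapse into one duplicated 34-mer
with copy number 4.  The first rows of `demo/run/hits.tsv`:

```
chromosome  chrom_linear_pos_1based  contig_id  contig_offset_1based  sequence                            spacer    class  subclass_code  overall_score  weighted_score  consecutive_score
chrA        8001                     chrA       8001                  GAAGTTCCTATTTTGATCACAAAATAGCAACTTC  TGATCACA  8      12221112       25             25.0            13
chrA        13797                    chrA       13797                 GAAGGTCCTATTCTAGAGGGAATATAGTAACTTC  TAGAGGGA  8      12123112       24             24.0            8
```

The planted site at 1-based position 8001 is class 8 (all eight
proximal-8 positions match consensus); its subclass code 12221112 is the
canonical numeric encoding of its proximal-8 sequence ATTT/AAAT; the
scores say 25 of 26 element positions match, with a longest consecutive
run of 13.  The theoretical subclass catalogue behind the `class` /
`subclass_code` columns:

```
$ frtscan enumerate --counts --k 8
class 8: 10 subclasses
class 7: 120 subclasses
class 6: 558 subclasses
class 5: 696 subclasses
```

For a real analysis, point `scan` at a directory of contig FASTA files
plus a manifest TSV (`chromosome  order  contig_id  length`) declaring
the per-chromosome contig ordering; chromosome-linear coordinates are
computed from the cumulative contig lengths.  `frtscan compare
<34-mer> --pool run/unique.tsv --pool run/duplicated.tsv --threshold 25`
ranks homologous sites for counter-selection.

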