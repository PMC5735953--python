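# Methods

## Motif model

Two grammars cover the cis-elements analysed here.

A **consensus motif** is a degenerate word over the 15-letter IUPAC DNA
alphabet (`N` = any base, `M` = A/C, ...), at least 4 nt. Matching is
exact and case-insensitive; a *sequence* character outside `{A,C,G,T}`
never matches any pattern position, including `N` — assembly gaps cannot
create hits. Published patterns written with `x` wildcards map to IUPAC
`N`, and bracketed alternatives like `[AC]` map to the corresponding
ambiguity code (`M`), which is how the built-in `CANNNNCATGTG` and
`CAMNNANGTG` entries arise from the PIF5-like elements they encode.

A **spaced dyad** is two consensus cores separated by a spacer of
`spacer_min`–`spacer_max` unconstrained nucleotides (0 ≤ min ≤ max ≤ 50),
the grammar of composite ARF sites. The spacer counts bases strictly
*between* the cores: `TGTC[N]{11}GACA` occupies a 19-nt window. Spacer
bases must be unambiguous A/C/G/T — an `N` inside the spacer voids the
match, consistent with the rule above.

### Strand algebra

Reverse complementation is defined on the full IUPAC alphabet (`M`↔`K`,
`B`↔`V`, `N`↔`N`, ...) and is an involution. Scanning uses it as follows:

- consensus motifs flagged `both_strands` are scanned in both
  orientations, **except palindromes** (pattern = own reverse
  complement, e.g. `CACGTG`), which are scanned forward only — the two
  orientations select identical windows and would otherwise be counted
  twice;
- a dyad is **self-reverse-complementary** iff `core5` is the reverse
  complement of `core3` (the everted-repeat case, `TGTC…GACA`). Its
  pattern family is closed under reverse complement for every spacer, so
  it too is scanned forward only; other dyads are scanned in both
  orientations.

All overlapping occurrences are reported (the scanner does not skip past
a match); presence/absence downstream is unaffected and occurrence counts
stay well-defined. Non-palindromic degenerate patterns can match one
window in both orientations; such windows are reported once per
orientation. The scanner is regex-based (IUPAC codes compiled to
character classes over ACGT, with lookahead for overlaps) and is verified
exhaustively against a naive enumerate-everything matcher in the test
suite.

The consensus searches default to both strands also for non-palindromic
patterns such as `CANNNNCATGTG`. For a single promoter strand this is the
conservative choice — a bHLH-type factor binds double-stranded DNA, so an
element on either strand is a candidate site — but it is a package
decision, not a property of the motifs.

## Promoters

A promoter is the fixed-length window (default 3000 nt) immediately 5′ of
a gene's annotated start, read on the gene's coding strand. Internally all
coordinates are 0-based half-open; GFF3 (1-based closed) is converted on
read. For a `+` gene starting at 0-based `s` the window is
`[max(0, s−L), s)`; for a `−` gene ending at `e` (exclusive) it is
`[e, min(chrom_len, e+L))` reverse-complemented. Windows are deliberately
*not* truncated at neighbouring genes (fixed-length bulk-retrieval
behaviour); they are clipped only at chromosome edges and flagged when
clipped. The gene feature's bounds — which span all mRNA isoforms — define
the transcription start, i.e. the 5′-most isoform start is used. Hit
coordinates can be emitted promoter-local, TSS-relative (negative
upstream offsets, the "−1538" style) or genomic BED6 via stored
provenance.

Background sets are drawn by seeded sampling without replacement from a
promoter universe minus an exclusion list (default n = 500, the control
group size of the emulated study).

## Enrichment statistics

For each motif and each ordered class pair (defaults: Class I vs
Class II, Class I vs background, Class II vs background) the 2×2 table of
containing/lacking promoters is tested with the Fisher exact test.

The two-sided p-value uses the **point-probability criterion**: the sum of
hypergeometric probabilities, over all tables with the observed margins,
that do not exceed the observed table's probability. Probabilities are
computed in log space from cached exact log-factorials, so 500-promoter
background margins are handled without overflow; ties in point
probability are included with a relative tolerance of 1e−7 (the same
guard R's `fisher.test` uses), which makes the sum robust to the platform's
floating-point rounding. The implementation agrees with an
exact-rational enumeration oracle to ≥ 10 significant digits for every
table with total ≤ 40, and with `scipy.stats.fisher_exact` on large
tables.

One-sided alternatives (`greater`/`less`) are provided alongside. The
report default is two-sided, but for the published contingency tables of
the emulated study (11/50 vs 0/20, 10/50 vs 0/20, 28/50 vs 2/20) the
values printed there (~0.02, ~0.03, 0.0003) are reproduced at printed
precision by the *one-sided* test (0.0173, 0.0259, 0.00033), not by the
two-sided one (0.0268, 0.0526, 0.00042) — evidently the study reported
one-sided values. Both are therefore computed and reported by
`scripts/acceptance.py`.

The odds ratio is the sample estimate `(a·d)/(b·c)`, `inf` when the
denominator is zero with a positive numerator, and 1 by convention when
both products vanish. Degenerate tables (an empty class or a motif absent
from — or present in — every promoter) give p = 1. No multiple-testing
correction is applied; the report carries its row count so users can
correct downstream.

## Synthetic studies

The generator emulates the study design the statistics assume: class
sizes 50 / 20 / 500, promoter length 3000 nt, and per-class planting
rates for the three discriminating motifs set to the presence fractions
observed in the emulated study (combined AuxRE 0.22 / 0 / 0.07; BZR1
G-box 0.20 / 0; Class I PIF5-like 0.56 / 0.10 / 0.112).

**Base composition.** Sequences are i.i.d. draws from a mononucleotide
distribution, default (A, C, G, T) = (0.32, 0.18, 0.18, 0.32) — 36% GC,
typical of Arabidopsis intergenic DNA. Composition matters: under this
default a 3000-nt promoter contains the G-box by chance with probability
≈ 0.27 and the combined AuxRE with probability ≈ 0.09, so chance
occurrences are a real feature of the null, as they are in genomes.

**Planting** overwrites a window with a concrete realisation of the motif
(each degenerate position drawn uniformly from its admitted bases; dyad
spacer length uniform over its range, spacer bases from the base
composition; orientation uniform where the two orientations are
distinguishable), keeping length fixed. At most one instance per (motif,
promoter) is planted, and plantings within one promoter are placed on
disjoint windows so they cannot destroy each other. Chance occurrences
from the background process are left in place and count as hits — so
*observed* presence fractions exceed planting rates by roughly the chance
rate, exactly as real presence fractions fold in low-affinity chance
matches. The ground truth (every planted instance with position, strand
and spacer) is recorded and, by construction, every planted instance is
recovered by the scanner; the test suite verifies this.

**Seeding.** One master seed; promoter *i* uses the dedicated stream
`default_rng([seed, i])`, so any promoter can be regenerated alone and
bundles are byte-identical across runs of the same design.

**What the generator does not emulate:** dinucleotide structure, TATA/
CpG-like positional composition, conservation, chromatin context, or
correlated motif co-occurrence. Tests passing on this generator show the
pipeline's bookkeeping and statistics are correct under the stated null,
not that the biological enrichment conclusions transfer to any particular
genome.

## Pipeline calibration

`dyadscan.pipeline.rejection_rate` re-runs the full generate → scan →
enrich chain on seeded replicates of the default design with a single
motif planted at chosen per-class rates. With the Class I PIF5-like motif
at rates 0.56 vs 0.10 (Class I vs Class II, n = 50 vs 20) the pipeline
detects the difference at α = 0.05 in ≈ 94% of replicates; with equal
rates the rejection rate is ≈ 2–3% — *below* the nominal 5%, as expected:
the exact test is conservative on discrete data, its attainable size
being strictly less than α at these sample sizes. The acceptance test
therefore checks power ≥ 90% and type-I ≤ α plus three binomial standard
errors, rather than a two-sided band around 5% that a correctly
conservative test would rightly fail. Calibration uses 200 replicates in both the test suite and
`scripts/acceptance.py`; the replicate counts are the package's chosen
problem sizes and are stated alongside each reported rate.

## Numerical and degenerate-input choices

- Empty sequences, empty hit lists and all-false presence columns are
  legal everywhere; enrichment on an all-false column returns p = 1.
- Hits are sorted by (start, end, strand); dyad hits additionally carry
  their spacer length, and nested occurrences with different spacers are
  all reported.
- Background sampling requires the post-exclusion universe to be at least
  the requested size and fails loudly otherwise.
- Zero-length upstream windows (gene flush against a chromosome edge) are
  rejected rather than silently empty.
- The catalog TSV round-trips the built-in catalog losslessly; malformed
  rows are rejected with their line number.

## Known limitations

- Consensus matching only: no position weight matrices, mismatch
  tolerance or binding-energy scores — a site one substitution away from
  the consensus is invisible.
- Presence/absence discards occurrence counts and positions from the
  statistics; elements whose effect depends on copy number or TSS
  distance need a different test.
- The i.i.d. background understates the clumpiness of real intergenic
  DNA, so chance presence rates in real promoter sets can differ from the
  generator's analytic expectations.
- One annotation isoform policy (5′-most start) is applied uniformly;
  genes whose dominant TSS differs will have shifted windows.
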