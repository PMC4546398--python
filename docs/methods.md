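# Methods note

`dualsage` implements a dual-species SuperSAGE differential-expression
workflow: tag extraction and library cleaning, species attribution of 26-bp
tags against two reference transcriptomes, a two-library exact test for
differential tag abundance, Gene Ontology node scoring of significant tag
sets, cross-study intersection of functional labels, and a synthetic data
generator with exact ground truth that lets every step be validated against
known answers.

## 1. Counting model and tag definition

SuperSAGE observes, for each transcript copy, a single canonical 26-bp tag:
the 26 bases starting at the 3'-most `CATG` (NlaIII anchor) that leaves at
least 26 bases up to the transcript end (EcoP15I cuts 26 bp into the
transcript, anchor included). `extract_canonical_tag` implements exactly
this rule (scan from the 3' end with `rfind`); transcripts with no
qualifying anchor yield no tag. A library is then a multinomial sample of
tags: the count of tag *t* is proportional to the summed relative abundance
of the transcripts carrying *t* as their canonical tag. All coordinates in
the package are 0-based.

Library cleaning mirrors the standard SuperSAGE bookkeeping: ditag parsing
with twin-ditag removal (`parse_ditags`), a poly-A artifact filter
(tags with > 80 % adenine or a terminal run of > 15 A's are removed), and a
singleton filter (tags with a combined count ≤ 1 across both libraries are
dropped). `clean_table` applies the filters in that order and reports the
counts removed at each step.

## 2. Synthetic data generator

`simulate_transcriptomes` + `simulate_tag_libraries` generate a paired
experiment — a control library (host only) and an infected library
(host + fungal symbiont) — with a truth table that records each
transcript's canonical tag, true fold change, direction and expected
tags-per-million in both libraries.

**Sampling scheme.** Baseline transcript abundance is log-normal,
`exp(σ·Z)` with σ = `abundance_sigma`. A fraction `de_fraction` of host
transcripts receive a true effect *f* drawn log-uniformly from
`effect_size`, up or down with equal probability. Each effect is split
symmetrically across the libraries: the control abundance is divided by
√f and the infected abundance multiplied by √f before each library is
renormalized. The between-library ratio is then exactly *f* while
unregulated transcripts keep (to first order) the same relative abundance
in both libraries. The naive alternative — applying *f* on the infected
side only and renormalizing — makes *every* unregulated transcript appear
down-regulated by the renormalization factor whenever strong up-effects
are present; this compositional artifact is a property of closed
(proportion-based) counting data, and the symmetric √f split is the
standard way to keep the null tags null in a simulator. The infected
library's composition is `(1 − symbiont_load)` host + `symbiont_load`
symbiont; the control library is symbiont-free unless `bleed_through`
is raised.

**Error and artifact injection.** Counts are drawn first
(`rng.multinomial` per library), then observation noise is injected by
*replacing* observed copies: per-tag error counts are Binomial in the
per-copy error probability `1 − (1 − error_rate)^26`, each erroneous copy
receives a truncated-Binomial(26, `error_rate`) ≥ 1 number of substitutions
at uniform positions; poly-A artifact copies (`polya_artifact_rate`) are
removed by multivariate-hypergeometric draws and replaced by A-rich junk
tags. Because injection replaces copies rather than adding them, column
sums equal the configured depths exactly and the truth table stays exact.

**Defaults and rationale.** Values fixed by the study design: library
depths 1,666,059 (control) and 3,598,159 (infected) — the sequenced totals
of the two root libraries; tag length 26 with anchor `CATG`. Values that
are the package's own modelling choices, chosen once up front:

| parameter | default | rationale |
|---|---|---|
| `n_host_transcripts` / `n_symbiont_transcripts` | 2000 / 500 | desk-scale transcriptomes; large enough for stable rate estimates, small enough to index in seconds |
| `transcript_length` | (200, 2000) nt uniform | spans typical mRNA lengths |
| `gc_content` | 0.42 | plant-transcriptome-like base composition |
| `abundance_sigma` | 1.2 | log-normal spread giving the familiar few-dominant-tags / long-tail SAGE profile |
| `de_fraction` | 0.1 | order of the observed significant fraction |
| `effect_size` | (2, 128) log-uniform | from the detection threshold to the largest observed fold changes |
| `error_rate` | 0.001 /base | typical post-filter sequencing error |
| `polya_artifact_rate` | 0.001 | small contamination consistent with the filter being worthwhile |
| `symbiont_load` | 0.10 | ≈ 10 % of annotated tags in the infected library were fungal |
| `bleed_through` | 0.0 | control roots are uninfected |

**What the generator emulates / does not.** It emulates: unequal library
depth, the one-tag-per-transcript counting model, a fungal fraction present
only in the infected library, substitution errors, poly-A artifacts, and
shared tags (distinct transcripts can share a canonical tag). It does not
emulate: biological replicate variation (the test under study is the
two-library exact test, which has none), alternative polyadenylation
(one canonical tag per transcript), sequence homology between host and
symbiont beyond chance, GC-dependent or position-dependent error profiles,
or PCR duplication.

**Reproducibility.** All randomness comes from two `numpy` Generator
streams derived from the single config seed (`default_rng([seed, 1])` for
transcriptome synthesis, `default_rng([seed, 2])` for library sampling)
with a documented draw order, so every output is byte-identical for a
given config.

## 3. Species attribution

Tags are attributed by exact Hamming-distance search against both
reference transcriptomes at three stringencies — 26/26, 24/26 and 20/26
matching bases, i.e. 0, 2 and 6 mismatches — on both strands. For 26-mers
this is strictly more sensitive than seeded BLASTN (no heuristic dropout)
and fully reproducible. A tag is `host` or `symbiont` if it matches only
that reference at the given stringency, `ambiguous` if it matches both,
`unmapped` otherwise.

`TagIndex` indexes every L-mer window of a transcriptome (numpy byte
matrix + sorted keys). Mismatch-tolerant lookup uses pigeonhole seeding:
for m ≤ 3 mismatches the tag is split into m+1 chunks, one of which must
match exactly; for 4 ≤ m ≤ 6 it is split into four larger chunks, one of
which carries at most ⌊6/4⌋ = 1 mismatch, searched by enumerating each
chunk's one-substitution variants. Larger chunks are exponentially more
selective, which keeps candidate verification cheap on multi-million-
position indexes (≈ 8 ms per tag at m = 6 against a 4.3 M + 1.1 M-position
index pair). Candidates are verified with a vectorized Hamming count; the
test suite checks equality with a brute-force scan of every window.

## 4. Differential expression

Counts are normalized to tags per million; a raw count of zero is replaced
by one *before* normalization (pseudocount), and fold change / direction
are reported on the infected/control scale. The per-tag test is the
Audic–Claverie two-library exact test: under the null that a tag is
equally represented, the infected count *y* given the control count *x*
follows NegBinom(r = x+1, p = N₁/(N₁+N₂)); the two-sided p-value is
min(1, 2·min(lower, upper)), both tails including the observed point.
The implementation uses `scipy.stats.nbinom.cdf/sf` (regularized
incomplete beta closed form) rather than series summation — stable in the
far tails and vectorized; the test suite checks it against an exact
rational-arithmetic oracle (max relative error ≈ 5 × 10⁻¹⁵ over a
count × depth grid).

Two decision rules are computed per tag: `sig_2fold` (p < 0.05 strict AND
fold-change magnitude ≥ 2 inclusive — the headline rule) and `sig_log2gt2`
(p < 0.05 AND |log₂FC| > 2 strict). Rows with zero counts in both
libraries are rejected as input errors. Benjamini–Hochberg adjustment
(`scipy.stats.false_discovery_control`) is available but off by default,
matching the per-tag reporting convention of the field.

**A note on symmetry.** The Audic–Claverie statistic is *not* exactly
symmetric under swapping the libraries together with their depths
(e.g. p(x=1, y=0) = 0.5 but p(x=0, y=1) = 1.0 at equal depths, because the
negative-binomial conditioning is on x+1). The discrepancy is bounded
(ratio ≲ 3 at moderate counts) and never changes the decision at α = 0.05
on realistic grids — the test suite asserts both properties. An exactly
symmetric alternative, the conditional binomial test
(y | x+y ~ Bin(n, N₂/(N₁+N₂))), is provided as `method="binomial"` and its
exact swap-symmetry is property-tested.

**Calibration and recovery.** `evaluation.null_type1_rate` measures the
empirical type-I error of the headline rule on null libraries (no true
effects) at 10,000 tags and 10⁶ depth: ≈ 0.043 at α = 0.05 over 20 seeds.
This calibration runs with error/artifact injection off so the tested
table holds the stated number of tags; with artifacts on, extra low-count
error tags dilute the measured fraction (≈ 0.029). `recovery_metrics`
measures, at the study's sequenced depths: sensitivity on strong
well-expressed host effects (true FC ≥ 4, expected ≥ 20 cpm in both
libraries), false-positive rate on *host* unregulated tags only (symbiont
tags are absent from the control by design, so their between-library
difference is real, not a false positive), and attribution accuracy on
tags whose truth mapping is unambiguous.

## 5. GO node scoring

The ontology is parsed with `obonet` into a child→parent `networkx`
DiGraph over `is_a` and `part_of` edges; obsolete terms are excluded,
`alt_id`s resolve to their primary term, and a cycle raises a format
error naming a member of the cycle. Annotations are propagated by the
true-path rule (every ancestor of an annotated term is annotated).
The node score of term *t* is

S_t = Σ over direct (sequence, term) annotation pairs of w^d(term, t),

where d is the shortest directed distance from the annotated term up to
*t* and w ∈ (0, 1] a decay weight. With w = 1 this is the propagated
sequence-pair count, and the score at each namespace root equals the
total number of direct annotation pairs in that namespace (conservation —
property-tested). Term *level* is the shortest distance from the
namespace root. `filter_and_compare` compares two species' score tables
above an inclusive cutoff (default 20), filling absent terms with 0.

## 6. Cross-study intersection

Free-text functional labels are normalized to token sets (lower-case,
split on non-alphanumerics, drop the hedge words *putative, probable,
like, predicted*); two labels match when their Jaccard similarity reaches
`min_jaccard` (default 1.0 — identical token sets). Matching labels
across studies form a graph whose connected components are function
clusters: *core* clusters contain labels from all studies, *pairwise*
clusters from exactly two. The result is invariant to study order, and
lowering the threshold can only merge clusters (monotonicity —
property-tested).

## 7. Numerical and interface conventions

- Percentages in summary tables are rounded to nearest at the stated
  number of decimals; whole-percent tables use 0 decimals.
- Match hits are sorted by (mismatches, transcript id, offset, strand);
  ties in every table are broken deterministically.
- The workflow writes a manifest with SHA-256 checksums of all inputs and
  no timestamps, so a rerun of the same config is byte-identical.
- Frequency classes use right-closed intervals on the maximum
  per-library cpm; fold-change histogram bins are half-open [lo, hi).

## 8. Limitations

- The two-library exact test has no biological replication; its p-values
  quantify sampling noise only, as in the original design.
- Audic–Claverie asymmetry under library swap is inherent to the
  statistic (see §4); use the binomial backend where exact symmetry
  matters.
- The node score weights all annotation evidence equally and uses
  shortest-path distance; terms reachable by multiple paths are not
  double-counted per (sequence, term) pair, which is an approximation to
  evidence strength, not a probability.
- The generator's host and symbiont sequences are independent random
  strings; cross-species ambiguity rates are therefore chance-level and
  lower than for real homologous transcriptomes.
- Token-set Jaccard matching is a transparent stand-in for the expert
  curation used in cross-study comparisons; synonyms with disjoint
  token sets will not merge at any threshold.
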