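# dualsage

Dual-species SuperSAGE differential expression: tag-level analysis of a
host–symbiont transcriptome mixture with a fully validated synthetic
counterpart.

## The problem

SuperSAGE sequences a single 26-bp tag from the 3' end of every transcript
copy (the 26 bases at the 3'-most NlaIII anchor `CATG`, cut by EcoP15I), so
a tag's count is proportional to its transcript's abundance. When the
tissue is a mixture of two organisms — here, plant roots colonized by an
arbuscular mycorrhizal fungus — one pair of libraries (uninfected control
vs. infected) simultaneously measures *both* transcriptomes, provided each
tag can be attributed to its species and tested for differential abundance
without biological replicates. `dualsage` implements that workflow
end-to-end:

1. **Tag processing** — canonical tag extraction, ditag parsing with
   twin-ditag removal, poly-A artifact and singleton filters.
2. **Species attribution** — exact Hamming-distance matching of each tag
   against host and symbiont reference transcriptomes at 26/26, 24/26 and
   20/26 stringency (0, 2, 6 mismatches), both strands, with a
   pigeonhole-seeded index that provably equals a brute-force scan.
3. **Differential expression** — the Audic–Claverie two-library exact
   test on tags-per-million-normalized counts: the infected count *y*
   given the control count *x* is NegBinom(x+1, N₁/(N₁+N₂)) under the
   null, two-sided p = min(1, 2·min(lower, upper)). Headline rule:
   p < 0.05 and fold change ≥ 2.
4. **GO node scoring** — true-path propagation over the `is_a`/`part_of`
   graph and a per-term node score (weighted count of annotation pairs),
   compared between species above a cutoff.
5. **Cross-study intersection** — token-set Jaccard matching of free-text
   functional labels across studies into core and pairwise clusters.
6. **Synthetic data generator** — paired control/infected libraries at
   realistic depths (1,666,059 / 3,598,159 tags) with exact ground truth,
   substitution errors and poly-A artifacts, used to validate every step
   (test calibration, effect recovery, attribution accuracy).

See `docs/methods.md` for the model, parameter defaults and their
rationale, numerical choices and limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
experiment (seed 1) at the real sequenced depths and write their tables to
`results/`:

```bash
for s in analysis/0*.py; do python "$s"; done
```

**01 — simulate.** 2,000 host + 500 symbiont transcripts; the infected
library carries a 10 % fungal load, the control is symbiont-free:

```
simulated 2000 host + 500 symbiont transcripts
libraries: 1,666,059 control / 3,598,159 infected tags
observed tag species: 72,279 (250 transcripts truly regulated)
```

**02 — clean.** Poly-A artifact and singleton filters:

```
input tag species: 72,279
removed poly-A artifacts: 3,403
removed singletons: 39,649
kept 29,227 tag species (99.15% of counted tags)
```

**03 — attribute.** Per-stringency species attribution (at perfect
stringency most error-bearing tag species are unmapped; at 24/26 nearly
all map back to their source transcript):

```
stringency 26/26:
 category  count  percent
 unmapped  26728     91.4
     host   2000      6.8
 symbiont    499      1.7
ambiguous      0      0.0
stringency 24/26:
 category  count  percent
     host  27718     94.8
 symbiont   1509      5.2
```

**04 — differential expression.** The exact test plus recovery against
the simulation truth:

```
tested 29,227 tags: 2,270 significant (1,037 up, 1,233 down); 2,228 pass the strict |log2FC|>2 cut
99.0% of tags at <= 1,000 copies per million
recovery of strong well-expressed effects: 100.0% of 121
false-positive rate on unregulated host tags: 0.06% of 1808
```

**05 — GO node scores.** Propagation + scoring on a synthetic
demonstration ontology; with weight 1 the root score equals the total
annotation pairs per species:

```
host: 162 significant perfectly attributed tags
symbiont: 497 significant perfectly attributed tags
6 GO terms reach node score >= 20 in either species:
      term                           name          namespace  level  score_host  score_symbiont
GO:1000000             biological_process biological_process      0       246.0           762.0
GO:1000002                      transport biological_process      1        92.0           315.0
...
```

**06 — cross-study core sets.** Token-set intersection of three mock
study lists; loosening the Jaccard threshold merges near-identical labels
into the core:

```
exact: 1 core functions shared by all three studies
  - germin protein
  pairwise-only clusters: {('medicago', 'this_study'): 2}
jaccard>=0.5: 3 core functions shared by all three studies
```

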