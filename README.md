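# lakevir

Viral metagenomics inference for deep, seasonally stratified freshwater
lakes. The package re-implements, as a tested and reusable pipeline, the
decision layer that turns assembled scaffolds from *cellular-fraction*
metagenomes into an annotated viral community: which scaffolds are
viruses, how they group into species-like populations, what their closest
relatives are, which prokaryotes they infect, how the community turns over
between photic/aphotic zones and winter/summer seasons, and how proteome
isoelectric points differ between proteomes.

It is written for microbial ecologists and developers of viral-discovery
pipelines who need a desk-scale, fully ground-truthed harness: every stage
can be exercised against a synthetic community generator that plants the
signals each stage is supposed to recover.

## The rules at the core

**Virus identification** unions three evidence channels, any of which
marks a scaffold as a putative virus (all thresholds inclusive):

* virus-sorter category ∈ {1, 2};
* virus-finder score ≥ 0.7 with p ≤ 0.05;
* ≥ 20% of the scaffold's proteins match pVOGs (e ≤ 10⁻⁵) with an added
  viral quotient AVQ ≥ 2, where AVQ = Σ over proteins of the viral
  quotient of their best-hit pVOG.

Putative viruses are curated into *bona fide* viruses by a deterministic
rule standing in for manual inspection: a hallmark viral gene (capsid,
terminase, portal, tail, baseplate, integrase, holin) or ≥ 50% of proteins
without informative annotation.

**Viral populations** cluster bona fide scaffolds at ≥ 95% ANI and ≥ 80%
shared genes (greedy representative linkage, longest scaffold first).
**Taxonomy** is closest-relative voting over filtered protein hits
(identity ≥ 30%, bit-score ≥ 50, alignment ≥ 30 aa, e ≤ 10⁻⁵): the taxon
matching the most proteins wins, ties resolved by mean identity.
**Host prediction** combines homology matches (≥ 300 bp, ≥ 50% identity,
e ≤ 10⁻³), shared tRNAs (≥ 60 bp, ≥ 90% identity, ≥ 95% query coverage,
≤ 10 mismatches, e ≤ 10⁻³) and CRISPR spacers (≥ 95% identity, ≥ 95%
coverage, ≤ 1 mismatch, e ≤ 1), with per-rank consensus: ambiguous ranks
and everything below them are removed, shallower consistent ranks kept.
**Ecology** provides Shannon (−Σ pᵢ ln pᵢ) and Gini–Simpson (1 − Σ pᵢ²)
diversity, Bray–Curtis dissimilarity, average-linkage clustering, NMDS
(SMACOF + isotonic regression, Kruskal stress-1), RPKG, grouped
abundances and paired zone/season comparisons. **Proteome adaptation**
computes isoelectric points by bisection of the Henderson–Hasselbalch net
charge (EMBOSS pKa set by default) and distribution shift statistics.

All sequence comparison runs on an internal engine: exact Smith–Waterman
for small problems, k-mer seeded chaining with edlib-backed extension for
large ones, plus ORF calling (table 11), homology-based tRNA detection
against a bundled canonical set, and an exact-repeat CRISPR detector.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
community (4 host genomes, 10 viral populations × 5 members, 50 cellular
decoy scaffolds, 10 samples in a paired depth/season design):

```bash
python analysis/01_simulate_community.py --seed 1
python analysis/02_identify_viruses.py
python analysis/03_cluster_populations.py
python analysis/05_predict_hosts.py
python analysis/06_community_ecology.py --seed 1
```

which prints, among other things:

```
bona fide calls: 50 / 100 scaffolds
precision vs ground truth: 1.000   recall: 1.000
50 bona fide scaffolds -> 10 viral populations
adjusted Rand index vs planted populations: 1.000
predictions for 15/15 viruses
genus-level recovery of planted links: 15/15
Shannon range: 2.38-3.20   Simpson range: 0.7527-0.9198
NMDS stress: 0.0000
mean |log2 ratio| depth pairing: 4.39   season pairing: 0.29
```

Read: all 50 planted viral scaffolds (and no decoys) survive
identification and curation; clustering recovers the 10 planted
populations exactly; host prediction resolves the planted virus–host
links to genus level; the ordination separates photic from aphotic
samples at essentially zero stress; and per-scaffold abundance ratios are
an order of magnitude larger across the depth pairing than across the
season pairing — depth, not season, structures the community.
`analysis/04_assign_taxonomy.py` and `analysis/07_proteome_pi.py` add
closest-relative family assignment and the viral vs cellular isoelectric
point comparison. Tables and figures land under `results/`.

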