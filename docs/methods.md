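# Methods

This note documents the models, thresholds and design choices behind
`lakevir`, and what the synthetic benchmark does and does not establish
about behaviour on real data.

## Scope and data model

The pipeline starts where assembly ends: its inputs are assembled
nucleotide scaffolds with sample provenance, predicted proteins,
per-scaffold tool-evidence tables (virus-sorter category, virus-finder
score and p-value), pVOG match tables carrying per-group viral quotients,
host genomes with GTDB-style 7-rank lineages, and scaffold × sample count
matrices. Read cleaning, assembly, and the internals of the upstream
tools are out of scope; their outputs are modelled as input tables or
replaced by simplified internal operators (below).

## Sequence comparison engine

* **Local alignment.** Pairs whose DP matrix fits in 400,000 cells
  (roughly ≤ 630 × 630) are solved by exact Smith–Waterman with a linear
  gap penalty; the in-row dependency is resolved with a running-max
  transform so rows vectorise. Multiple alignments are produced by
  masking the aligned query interval and re-solving, so reported
  alignments never overlap on the query. Larger nucleotide pairs go
  through 13-mer seeding, colinear chaining (diagonal tolerance 32,
  query-gap tolerance 200), edlib global alignment of each chained
  region, and trimming to the maximum-scoring column run (Kadane). The
  linear gap model (nucleotide +1/−2, gap −2; protein BLOSUM62, gap −11)
  keeps the exact DP simple and is sufficient for the substitution-
  dominated comparisons this pipeline makes; affine gaps would change
  scores only for long-indel alignments it never relies on.
* **E-values.** Karlin–Altschul with fixed constants: λ = 0.625,
  K = 0.41 for nucleotide +1/−2; λ = 0.267, K = 0.041 for BLOSUM62.
  Search space is the product of the two sequence lengths.
* **ANI** is the alignment-length-weighted mean identity over local
  alignments ≥ 100 bp at ≥ 30% identity; the aligned fraction is the
  covered fraction of the shorter sequence. The shorter sequence is
  always the query, which makes the statistic symmetric by construction.
  Sequences under 500 bp are rejected; with no qualifying alignment the
  result is flagged undefined rather than zero.
* **ORF calling** reports all maximal stop-to-stop regions ≥ 150 nt in
  six frames (translation table 11), trimmed to the first in-frame ATG
  when one exists; end-truncated open regions at scaffold edges are
  included. This intentionally over-calls relative to a trained gene
  finder; downstream uses (shared-gene fraction, proteome pI) are robust
  to over-calling because they are ratio- or distribution-based.
* **tRNA detection** is homology against a bundled canonical tRNA set
  (synthetic, fixed sequences of 72–90 nt) at ≥ 90% identity over
  ≥ 60 bp. The pipeline only needs virus↔host tRNA *linkage*, and the
  community generator plants tRNAs from the same set, so a covariance
  model adds nothing here; with real data this detector must be replaced
  by a genuine tRNA scanner.
* **CRISPR arrays** are maximal runs of ≥ 3 exact repeat copies
  (23–47 bp) separated by 21–72 bp spacers, found by seeding on 23-mers
  with regular spacing and extending the repeat to its maximal exact
  length. Sub-arrays nested in the span of an array with more copies are
  pruned (offset seeds and chance-shared spacer boundary bases otherwise
  produce shadows). Degenerate repeats are not modelled; the detector is
  intended for planted exact arrays.

## Identification

A scaffold is a putative virus if any channel fires: sorter category
∈ {1, 2}; finder score ≥ 0.7 and p ≤ 0.05; or pVOG fraction ≥ 0.20 with
AVQ ≥ 2. All thresholds are inclusive and missing channels simply do not
fire. AVQ sums, over proteins with pVOG hits, the viral quotient of each
protein's best hit (lowest e-value, ties to the higher quotient);
summation runs in sorted protein order so the result is exactly
permutation-invariant. A per-hit summation mode (`sum_all`) is provided
as configuration, since pVOG-based scoring can be defined either way;
best-hit is the default because it cannot double-count a protein.
Curation is a deterministic proxy for manual inspection: retain if any
protein carries a hallmark term (capsid, terminase, portal, tail,
baseplate, integrase, holin — configurable) or if ≥ 50% (configurable) of
proteins carry no informative annotation.

## Populations and taxonomy

Clustering is greedy representative linkage: scaffolds sorted by
decreasing length (ties by id) either join the first population whose
representative satisfies ANI ≥ 95% *and* shared-gene fraction ≥ 0.8, or
seed a new one. A gene is shared when some alignment window covering
≥ 80% of its length reaches ≥ 95% identity in the other scaffold; the
scaffold with fewer genes supplies both query genes and denominator, so a
fragment of a genome is not penalised for genes it does not carry (a
`query` mode is available). Greedy representative linkage rather than
all-pairs single linkage: the population definition is representative-
based and the greedy pass is deterministic and order-independent given
the sort rule.

Closest-relative taxonomy counts, per candidate taxon, the number of
scaffold proteins with at least one filtered hit (per protein and taxon
only the best-bit-score hit counts). The filter keeps hits with identity
≥ 30%, bit-score ≥ 50, alignment ≥ 30 aa and e ≤ 10⁻⁵, all inclusive.
Ties go to the taxon with the higher mean identity, second-order ties
to the lexicographically smallest name (logged as a deterministic
convention; the voting rule itself does not specify one).

## Host prediction

Three signal types with their own inclusive cutoffs (homology: ≥ 300 bp,
≥ 50% identity, e ≤ 10⁻³; tRNA: ≥ 60 bp, ≥ 90% identity, ≥ 95% query
coverage, ≤ 10 mismatches, e ≤ 10⁻³; CRISPR spacers: ≥ 95% identity,
≥ 95% query coverage, ≤ 1 mismatch, e ≤ 1). Query coverage is computed
over the spacer/tRNA (query) length. Signal types are weighted equally in
consensus; at each rank from domain downward the prediction is the taxon
shared by all implicated host lineages, and the first conflicting rank
plus everything deeper is marked `ambiguous-removed` while shallower
consistent ranks are retained — a virus hit by hosts from two phyla keeps
its domain assignment. An advisory quality ranking (descending max
bit-score, descending mean identity, ascending mean mismatches, host id)
is computed for ambiguous cases but never overrides consensus unless the
caller promotes it.

## Community ecology

Shannon uses the natural logarithm (configurable base): for communities
of ~2 × 10⁴ scaffolds the natural-log index lies in the 8–10 range, the
scale on which such communities are conventionally reported. Simpson is
reported in Gini–Simpson form 1 − Σ pᵢ², which approaches 1 for diverse
communities. Bray–Curtis is Σ|x−y| / Σ(x+y); hierarchical clustering is
scipy average linkage (deterministic smallest-index tie-breaking). NMDS
is SMACOF with isotonic regression of configuration distances on
dissimilarity ranks, Kruskal stress-1, 20 seeded random restarts, best
iterate kept (so final stress never exceeds the initial); disparities of
zero-dissimilarity pairs are pinned to zero so identical samples
coincide. RPKG = reads / ((length/1000) × gigabases), the standard
reads-per-kb-per-Gb convention. Grouped abundances collapse groups below
the display floor into `other` and conserve totals exactly. Paired
zone/season tables report log2((x+ε)/(y+ε)) with ε defaulting to 10⁻⁶ of
the mean column total; ε only sets the display floor for absences.

## Proteome isoelectric points

Net charge at a given pH is the Henderson–Hasselbalch sum over ionizable
groups (N-terminus, His, Lys, Arg positive; C-terminus, Asp, Glu, Cys,
Tyr negative); non-standard residues are ignored. The charge is strictly
decreasing in pH, so bisection on [0, 14] (to 10⁻⁶ pH) finds the unique
zero. The default pKa set is EMBOSS, with Bjellqvist as an alternative;
the table shifts absolute pI but not the sign or approximate size of
between-proteome shifts, which are the quantity of interest. Distribution
comparisons report the median shift, the two-sample KS statistic and the
fraction of proteins with pI < 7 per set.

## Synthetic community generator

The generator is first-class, tested code; it defines the study
conditions under which every downstream claim is verified.

* **Hosts** (default 4–8) are i.i.d. random genomes of 50–200 kb with
  per-genome GC drawn from 0.35–0.65 (GC is exposed because genome
  fragments are linked by GC in practice), carrying 1–3 CRISPR arrays
  (3–6 exact repeats of 23–47 bp, random 25–45 bp spacers) and 5–8 tRNA
  genes copied verbatim from the bundled canonical set. tRNA identities
  are partitioned across hosts so shared-tRNA linkage is unambiguous at
  default scale (with more hosts than library chunks they cycle, which
  deliberately reintroduces the ambiguity real tRNAs have). Lineages
  come from a configurable taxonomy; the default is distinct at genus.
* **Viral populations** (default 20 × 5 members) each derive from an
  independent random ancestor assembled from gene-sized segments
  (600–1500 bp) to a target of 15–60 kb. `within_population_divergence`
  (default 0.02) bounds the *pairwise* divergence of members, so each
  member is point-mutated at half that rate from the ancestor; gene
  replacement/deletion fractions (default 0.05 each) likewise bound the
  pairwise altered-gene fraction. Distinct populations are unrelated
  (≥ the configured between-population divergence apart). This puts
  intra-population pairs at ≈ 98% ANI and ≥ ~85% shared genes, and
  inter-population pairs far below both thresholds — the margins the
  clustering guarantees rely on.
* **Host links.** Each population is assigned one host (members of a
  population infect the same host, so near-identical siblings cannot
  plant conflicting links); each member receives, with probability
  `host_link_fraction`, a mutated 400–800 bp host segment (85% identity),
  a host tRNA copy, and a 25–40 bp spacer cut from the finished virus and
  spliced into a host CRISPR array. Decoy cellular scaffolds are host
  genome *fragments*, not random sequence, so homology-based host signals
  face realistic false-positive pressure.
* **Evidence.** Each channel fires per scaffold with its configured
  sensitivity; firing channels draw values inside the decision
  thresholds, non-firing channels draw complementary values, and decoys
  fire at `decoy_evidence_rate` (default 0). Fired channels are recorded
  in the ground truth, so recall can be compared with the exact binomial
  expectation.
* **Counts.** Per-scaffold lognormal base abundance (σ = 1.5 — the
  abundance law of real scaffold communities is not constrained here;
  lognormal is a modelling choice), damped ×0.05 in the scaffold's away
  zone; a random 20% of scaffolds also carry a ×0.5 off-season effect
  (season effects are real but weaker and affect a subset, mirroring the
  depth-dominant turnover of stratified lakes). Columns scale to 2 × 10⁵
  expected reads and are Poisson-sampled. The default design has ten
  samples: photic 5 m/20 m and aphotic 1250 m/1350 m in winter and
  summer, plus one extra sample per zone.

All stages draw from per-stage generators seeded from the single config
seed, so outputs are bit-reproducible.

**What passing these tests shows — and does not.** The synthetic
community has no sequencing error, chimeras, strain gradients, mobile
elements, real gene structure, or compositional bias; tool evidence is
drawn from the generator's distributions rather than from VirSorter/
VirFinder behaviour on real contigs. Green tests therefore establish that
the *decision layer* implements its rules exactly and recovers planted
structure whenever the signals clear the stated thresholds — not that the
upstream tools would produce such signals on a given lake.

## Problem sizes

The test suite and acceptance script run the full chain at desk scale,
chosen so each stage's guarantees are exercised with comfortable margins:
identification on 200 viral + 200 cellular scaffolds; clustering on 20
populations × 5 members (15–60 kb); host prediction on 12–15 viruses
against 4 hosts; alignment equivalence on 200 random pairs ≤ 300 bp;
NMDS and dendrograms on 10-sample matrices; pI on 100–400 proteins.
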