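# Methods

## Problem setting

A flow-sorted protistan cell yields, after whole-genome amplification and
low-coverage shotgun assembly, a single amplified genome (SAG): a bag of
contigs that may mix host DNA with bacterial prey fragments and viral
genomes. `virlink` classifies each contig, groups near-identical contigs
across SAGs into clusters, asks which viral clusters recur across
eukaryotic phyla, and tests whether virus occurrence is structured by
lineage or explicable by sorting artefacts. The package operates on
evidence tables (ORF homology hits, metagenome read recruitment, ssDNA
alignments, external viral-screen categories) rather than running the
homology searches itself; a synthetic community generator fabricates both
sequences and evidence with planted truth, so the full chain is testable
offline.

## Sketching and distance

Canonical *k*-mers (lexicographic minimum of a *k*-mer and its reverse
complement; *k* odd so no *k*-mer is self-complementary; windows containing
non-ACGT symbols skipped) are packed into 64-bit integers (2 bits/base,
A<C<G<T matching lexicographic order) and passed through a splitmix64
finaliser seeded by the hash seed. The finaliser is a bijection on 64-bit
integers, so distinct canonical *k*-mers map to distinct hashes: when the
sketch size exceeds the distinct-*k*-mer count, the sketch *is* the exact
canonical *k*-mer set under hashing, which the tests exploit as an oracle
(sketch Jaccard must equal brute-force set Jaccard on ≤1 kb sequences).

The Jaccard index is estimated from the merged bottom-*s* sketch: shared
hashes among the *s* smallest of the union, divided by min(*s*, |union|).
Distance is d = −(1/k)·ln(2j/(1+j)), capped at 1 and defined as 1 at j=0.
Defaults *k* = 21, *s* = 1000, hash seed 42 are the sketching community's
conventional values; the calibration property (median *d* within ±0.01 of
1−ANI at 95% and 99% ANI over 100 mutated pairs) holds at these settings,
with the known mild upward bias at 95% ANI (median ≈ 0.051) still inside
the band. Pairwise comparison is all-vs-all with an intersection-size
prefilter that can only skip pairs already certain to fall above the
distance threshold; at the package's intended scale (≤ ~10⁴ contigs) this
is a few seconds.

## Classifier

* **Viral-ORF fraction.** An ORF is viral when any of its top-10 nr hits
  contains a virus-associated term. Matching is token-based,
  case-insensitive, whole-word with plural folding ("viruses" counts for
  "virus"; "retailer" does not count for "tail"). The term list is the
  standard phage/virion vocabulary (capsid, terminase, portal, baseplate,
  myovirus, …) with the duplicate "tail" collapsed. Contigs with no
  nr-class ORF hits return a missing value, not 0 — absence of evidence is
  not evidence of non-virality.
* **Recruitment ratio.** log₁₀ of pseudocounted reads-per-million recruited
  from a viral versus a bacterial metagenome at ≥50% identity. The
  transform (per-million scaling, +1 pseudocounts, log) is this package's
  formalisation of a "standardised ratio"; the training set is built on
  the identical transform so the kNN sees consistent geometry.
* **kNN score.** Both features z-scored by training means/SDs (making the
  score invariant to affine rescaling of raw features), Euclidean metric,
  ties at the k-th distance resolved by including all tied points and
  renormalising. The p-value is the exact binomial tail
  P(X ≥ observed viral neighbours | n used, training base rate). With the
  default k = 5 and a balanced training set, a viral call through the kNN
  route requires all five neighbours viral (p = 0.03125 ≤ α = 0.05) —
  the p-value gate is what keeps isolated feature-noise from flipping
  eukaryotic contigs to viral.
* **ssDNA rule.** Contig < 10 kb and qualifying alignments (e < 1e-5)
  covering ≥ 20% of its length after merging overlaps. The e-value
  threshold is read as 1e-5 (the alternative reading, e < 10⁵, would
  accept essentially any alignment and is an obvious typo); both the
  threshold and the length cap are configurable.
* **Bacterial rules.** Mash match at d ≤ 0.05 (inclusive) to a bacterial
  reference contig; or a strict majority (>50%) of ORFs hitting RefSeq
  bacterial proteins (>50% identity over >75% of the ORF) *and*
  nucleotide-level verification of a bacterial rather than organellar
  origin.
* **Precedence.** viral > bacterial > eukaryote when rules conflict,
  mirroring the narrative order of the screening workflow; the call's
  `basis` field preserves every fired rule for audit.

The default training set is generated from a small noiseless synthetic
community labelled by planted truth (dsDNA phage = viral;
eukaryote/bacterial = nonviral). ssDNA viruses are excluded from training:
the two kNN features do not capture them — which is exactly why the
dedicated ssDNA rule exists — and training on them would plant viral
density in a feature region that noisy eukaryotic contigs can enter.

## Network layer

Edges at d ≤ 0.05, weight 1 − d. Community detection is Louvain modularity
optimisation (networkx implementation, fixed seed, canonically sorted node
insertion so partitions are reproducible); a `connected-components` switch
reproduces pure single linkage. Cluster category: viral at ≥ 25% viral
members (inclusive — "at least 25%"); else bacterial on any non-viral
bacterial-reference member, bacterial-16S flag (an input flag, not an rRNA
search), or ORF-majority member; else eukaryote, with the category
propagated to all members idempotently. SAGs whose contigs are all
viral/bacterial after propagation are dropped from further analysis.
Contig LCA is the modal per-ORF label at ≥ 25% frequency with hitless ORFs
("none") counting in the denominator but never winning; cluster LCA is the
modal informative member label. Inter-phylum viruses are viral clusters
spanning ≥ 2 distinct identified phyla; SAGs without a taxon are listed in
the cluster's membership but do not count toward the phylum tally.

## Co-sorting model

Co-sorted virions per drop are Poisson(λ), λ = concentration × volume,
with concentrations accepted in viruses/mL and converted at 1 mL = 10⁹ pL
(so 1e7–1e8 viruses/mL ↔ 0.01–0.1 viruses/pL). A Poisson count (rather
than a Bernoulli presence) keeps λ > 1 meaningful. P(≥1) = 1 − e^(−λ)
bounds the prevalence co-sorting alone can produce: 0.878 at the
2.1-virus-per-cell corner. Observed per-lineage prevalences exceeding that
ceiling (e.g. 100% in the high-grazing synthetic lineages) cannot be a
sorting artefact — the model's entire analytical point.

## Statistics

Pearson chi-square without continuity correction for all contingency
tables (the published survey statistics reproduce exactly as plain Pearson
statistics, confirming no Yates correction was used); zero-marginal rows
are excluded at table construction (taxa with no sampled SAGs never form
zero rows). One-way ANOVA on untransformed counts; the all-zero
within-variance degenerate case signals F = ∞ explicitly. Tukey HSD uses
the studentized-range p-values with a compact letter display assembled by
insert-and-absorb, deterministic in group order. Mann–Whitney uses
midranks; the two-sided p-value comes from exhaustive enumeration of the
permutation distribution when n₁·n₂ ≤ 400 *and* C(n₁+n₂, n₁) ≤ 2·10⁵
(full enumeration is infeasible beyond that regardless of n₁·n₂), else a
tie-corrected normal approximation.

One published inconsistency is handled explicitly: in the Gulf-of-Maine
survey table, the bacteriophage and inter-phylum blocks print statistics
(56.54, 107.43) that do not match a Pearson recomputation of their own
printed cells (57.99, 110.28), and one block's printed N disagrees with
its cell sum (292 vs 291). Those two statistics are therefore not used as
reproduction targets; the three internally consistent blocks (54.12, 2.07,
0.37) are.

## Synthetic community generator

The generator is the study-conditions oracle, not a convenience fixture.
Defaults: six lineages; grazing rates 28 (choanoflagellate-like), 5.7
(picozoan-like), 0.3–1.0 elsewhere — the high rates echo the per-cell
averages reported for those groups; co-sorting at 0.1 viruses/pL × 21 pL
(λ = 2.1, the upper corner of the published bracket); 40 virus genomes
(25% ssDNA, 3–8 kb, under the 10 kb cap; dsDNA 15–60 kb); 10 bacterial and
20 eukaryote genomes; per-channel evidence noise FP = 0.02, FN = 0.05
(documented, configurable; not estimates of real search error rates).

Planted virus copies are mutated at per-site rate (1 − ANI)/2 with
ANI = 0.98, so two copies of the same virus sit at ≈ 98% pairwise identity
— inside the 95–100% range reported for shared clusters and safely inside
the d ≤ 0.05 edge threshold (copies mutated at the full rate from the
ancestor would sit at ~2×(1−ANI) pairwise divergence and, at 95%, straddle
the threshold). Substituted bases always differ from the original, so
realised identity concentrates tightly at the target.

Background genomes are i.i.d. uniform nucleotides — no codon structure, no
gene content — because every downstream stage operates on k-mer identity
and fabricated evidence tables. ORFs are laid on a fixed grid (one per
900 bp, minimum one). Bacterial reference SAGs tile each bacterial genome.
What passing tests therefore show: the *rules* recover planted structure
under the stated noise. What they do not show: classifier accuracy on real
assemblies with MDA amplification bias, chimeric contigs, real ORF
structure or real database noise — none of which the generator emulates.
Noiseless bacterial-prey recovery flows through the ORF-majority rule
rather than the Mash-reference rule, because a prey fragment and a
reference tile of the same genome need not overlap; the reference rule is
exercised separately on constructed overlapping contigs.

## Problem sizes and study conditions of the validation runs

* End-to-end recovery: default community, ~700–800 protist contigs (~60
  SAGs), run noiseless (expect exact recovery) and at default noise
  (macro-F1 ≥ 0.9 observed ≈ 0.97–0.98); ~30 s each.
* Chi-square power: 200 runs × 4 lineages × 50 SAGs, grazing 3.0 in two
  lineages and 0 in two, co-sorting at the *lower* concentration corner
  (0.01 viruses/pL × 21 pL, λ = 0.21) — the conservative choice, since the
  upper corner makes virus presence near-universal in every lineage and
  the test's job is to detect lineage structure *above* background.
  Observed rejection rate at p < 0.01: 1.0.
* Monte-Carlo co-sort: 10⁴ count-level SAG draws at λ = 2.1; mean within
  3 standard errors of λ.
* Sketch oracle: 100 random ≤1 kb pairs, sketch size 10⁶ ≥ union size, so
  the estimate must equal brute-force Jaccard exactly.

## Known limitations

* Real-data prevalences and the survey's ANOVA/Tukey/Mann–Whitney values
  require the unpublished per-cell data and are not reproduction targets.
* The kNN training set is synthetic by construction (the original manually
  curated viral/non-viral contig set is not available); real-data users
  should supply their own via `training.tsv`-style input.
* VirSorter-style categories, 16S flags and LCA labels are consumed as
  inputs, never computed from sequence.
* Louvain determinism is guaranteed for a fixed input ordering and seed;
  different orderings may yield different (equally valid) partitions near
  modularity ties.
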