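# Methods and design notes

## The quantity being estimated

The pipeline estimates how many copies of a marker gene family (by default
the WS/DGAT acyltransferase domain family, PF03007) a microbial community
carries *per genome*. A metagenome's identified homologs are counted with a
depth correction — a sequence from the unassembled fraction represents one
observation (weight 1.0), while a gene on an assembled scaffold represents
all the reads collapsed into it (weight = scaffold read depth) — and the
corrected family count is divided by the equally corrected counts of 12
single-copy ribosomal-protein genes. Because each panel gene occurs exactly
once per genome, each ratio is an independent estimate of family copies per
genome; the mean of the 12 ratios is the reported relative abundance and
their coefficient of variation (sd with n−1 over mean) measures how
internally consistent the normalization is. Panel membership is
configurable; the default is the classic ribosomal marker set rplB, rplC,
rplD, rplE, rplF, rplN, rplP, rpsC, rpsE, rpsH, rpsK, rpsS. Panel genes are
estimated by the same depth-corrected rule as the family — symmetry is the
only reading under which the ratio has copies-per-genome units.

## Marker detection

Detection uses an ungapped position-specific scoring matrix rather than a
full insert/delete-state profile HMM: the package's focus is the community
analysis downstream, the synthetic sequences contain no indels (see below),
and real profile-HMM annotations can be supplied through
`ingest_domain_table`, which parses the common whitespace-delimited
per-domain hit dialect and keeps the best hit per protein per domain.

* Column scores are `log2(f̂/bg)` with a background-proportional Dirichlet
  pseudocount of total weight 10 (`pseudocount=0.5` per alphabet letter);
  columns with more than 50% gaps are dropped.
* E-values come from a maximum-likelihood Gumbel fit to the maximum window
  scores of ≥ 500 i.i.d. background decoys; `E(s) = N_db · SF(s)` with
  `N_db` the number of scanned proteins. The ML fit anchors the bulk of the
  null distribution; on decoy studies the far tail (the 1/1000 exceedance
  level) is reproduced only to within an order of magnitude and errs on the
  conservative side (E-values overestimated), so false-positive control at
  the 1e-5 cutoff is, if anything, stricter than nominal.
* One best (maximum-score) hit is kept per protein per domain; window ties
  resolve to the earliest offset. Proteins shorter than the profile are
  skipped with a log entry.

## The synthetic study

The generator is the package's definition of the study conditions, not a
test dial:

* **Taxonomy** — a balanced eight-rank tree (root, domain, phylum, class,
  order, family, genus, species); defaults: 4 phyla, binary splits, 128
  species.
* **Copy numbers** — zero-inflated zero-truncated Poisson: a genome carries
  the family with probability 0.35 and carriers draw ZTP(2.5) copies
  (≈ 0.96 expected copies per genome marginally — roughly one copy per
  genome, the regime where single-copy normalization is most informative).
  Per-phylum overrides are available because real censuses show strong
  phylum dependence.
* **Sequences** — i.i.d. substitutions along root-to-leaf branches at 0.05
  per site per branch, each hit site replaced by a uniformly random
  alternative residue; no indels, so expected pairwise identity is an
  analytic function of path length (within-genus ≈ 0.90, between-phylum
  ≈ 0.55, bracketing the 0.8 OPU cutoff). Paralogs within a genome diverge
  by one extra substitution round at rate 0.02. Excluding indels keeps the
  identity oracle exact; it also means the aligner's gap handling is
  exercised only by the random-sequence tests, not the fixture.
* **Communities** — two groups ("ANT"/"ARG") of replicate samples; each
  group has its own log-normal abundance offset per genome (sd 1.0) over a
  shared base profile, with per-sample jitter (sd 0.3). This plants
  reproducible between-group structure of realistic magnitude.
* **Emission** — genome coverage is `depth_scale · n · abundance` times a
  log-normal(−σ²/2, σ) factor (σ = 0.5, mean-one noise; depth_scale = 10).
  Each gene copy is assembled with probability 0.7, landing on its genome's
  scaffold whose read depth equals the coverage; otherwise it emits
  Poisson(coverage) unassembled single-protein records. Summing emitted
  weights therefore reproduces the truth table *exactly* — conservation is
  by construction, and the conservation tests verify the bookkeeping, not a
  statistical approximation. With probability 0.6 an assembled marker gets
  the conserved lipid-gene arrangement planted around it (AGPAT-HAD fusion
  upstream; acyl-CoA synthase and a second AGPAT downstream).
* Coordinates are GFF3 1-based inclusive; assembled proteins are named
  `<scaffold>_<ordinal>`; unassembled proteins carry no scaffold.

What the generator does **not** emulate: sequencing error, chimeric
assembly, fragmentary genes (all emitted proteins are full length),
strain-level microdiversity, compositional biases of real gene catalogs,
and real phylogenetic rate variation. Passing tests therefore demonstrate
the correctness of the estimators and procedures on data that obey the
model, not robustness to artifacts of real assemblies — the most fragile
real-world step, detection of highly fragmented homologs, is deliberately
out of the generator's scope.

## Taxonomic binning

`weighted_lca` keeps hits within 10% of the best bit score, lets each vote
its full lineage with weight equal to the bit score, and returns the
deepest node whose subtree holds ≥ 0.8 of the total retained weight (the
root always qualifies; with threshold > 0.5 the qualifying nodes form a
single chain, so the answer is unique; at lower thresholds ties break by
weight then id). The cited two-pass re-weighting of the original desktop
tool is not reproduced; the single-pass scheme is the documented stand-in,
with `top_percent` and `weight_threshold` configurable. Composition-based
scaffold classification is an external input; `consensus_bin` merges it
with the gene-wise assignment by LCA, falling back to whichever is
assigned.

## OPU clustering

Identity comes from a global affine-gap alignment (match +1, mismatch 0,
gap open −10, extend −1) computed by a Gotoh dynamic program with a
deterministic traceback (diagonal preferred over vertical over horizontal),
and equals identical aligned residues over the shorter sequence's length —
the convention of the standard greedy clustering tools; alignment-length
denominators are available as a switch. Direct gap-to-gap state transitions
are omitted from the recurrence: with non-negative substitution scores and
these penalties an adjacent gap pair is always dominated by aligning the
two residues. The greedy pass sorts by descending length (ties: ascending
id) and joins the first (oldest) cluster whose representative matches at
≥ cutoff, which makes the partition canonical and order-invariant, and
makes every representative the longest member of its OPU. No k-mer
prefilter is used — inputs at this scale make exact all-vs-representative
alignment affordable and fully auditable; identical sequences short-circuit
and identities to representatives are cached. The ≥ 10-sequence OPU filter
counts raw members, not corrected abundance.

## Community statistics

* **Wisconsin double standardization** divides by column (OPU) maxima then
  row (sample) totals; only this standardization precedes ordination — no
  additional transformation is applied, to avoid inflating the contribution
  of very low abundance OPUs.
* **NMDS** minimizes Kruskal stress-1,
  `sqrt(Σ(d̂−d)² / Σd²)`, alternating pool-adjacent-violators monotone
  regression (tied dissimilarities pooled into one block — ties averaged)
  with backtracking gradient steps on the configuration; the step is halved
  until stress does not increase, so the within-start stress trajectory is
  provably non-increasing. Twenty seeded random starts; the best final
  stress is reported with centered coordinates. Embedded distances are
  floored at 1e-12 to keep gradients finite on coincident points.
* **ANOSIM** uses mid-ranks of all pairwise dissimilarities and
  `R = (r̄_between − r̄_within)/(M/2)` with `M = n(n−1)/2`, the scaling
  under which complete separation gives exactly R = 1. The p-value is
  exact (all distinct label assignments enumerated) whenever there are at
  most 1000 of them, else a seeded permutation estimate
  `(1 + #{R* ≥ R})/(1 + n_perm)`, which is bounded below by
  `1/(n_perm+1)` and exactly reproducible for a fixed seed.
* **Mann–Whitney** reports U (pairs with x > y); tie-free samples with
  n₁+n₂ ≤ 25 get an exact dynamic-programming null distribution, others a
  tie-corrected normal approximation with continuity correction (matching
  the conventions of the statistical packages practitioners compare
  against). **Wilcoxon signed-rank** drops zero differences and reports the
  tie-corrected normal approximation without continuity correction (the
  convention under which Z statistics are usually quoted). **Spearman** is
  the Pearson correlation of mid-ranks, exact by enumeration for tie-free
  n ≤ 9, otherwise the t approximation with n−2 df.
* **ANCOM-W**: for OPU i, every additive log-ratio
  `log((x_i+1)/(x_j+1))`, j ≠ i, is tested across the two groups by the
  rank-sum test; Benjamini–Hochberg correction is applied *within* OPU i
  across its m−1 ratios, W_i counts rejections, and OPU i is detected when
  `W_i ≥ 0.7·(m−1)`. Pseudocount 1, α = 0.05 and the 0.7 cutoff are the
  widely used defaults and all configurable.

## Genomic context

Neighborhoods are measured in genes (default 10 per side), matching how
marker-centric gene maps are drawn, not in base pairs; gene prediction and
domain annotation are inputs (GFF3 plus per-gene domain ids). Flags for the
configured domains of interest exclude the marker gene itself and are
strand-agnostic. Nucleotide-level synteny shading between scaffolds is
replaced by a deliberate simplification: the Jaccard index of the two
scaffolds' domain-id multisets, which captures shared gene content without
any alignment; a scaffold without annotated domains compares as 0 with a
warning.

## Problem sizes and numerical choices

The default study is 2 groups × 3 samples (6 for ordination examples and
the acceptance script) over 128 genomes; parameter-recovery checks of the
single-copy normalization use 4096-genome pools over 20 seeds per planted
copy rate, where the Monte-Carlo standard error of the recovered ratio is
~2–4%, comfortably inside the 10% acceptance band. Exact-test validation
enumerates all arrangements up to 8 observations (Mann–Whitney), 7
observations (Spearman, 5040 permutations) and 6 samples (ANOSIM, 20
assignments). Permutation p-values always use the (1+b)/(1+n) estimator.
Floating-point ties in alignment tracebacks and ANOSIM comparisons use a
1e-9/1e-12 tolerance; all stochastic components take explicit integer
seeds and are reproducible bit-for-bit.

## Known limitations

* The PSSM scan has no gap states; strongly indel-divergent homologs in
  real data are better served by ingesting external profile-HMM hits.
* E-value calibration is conservative in the far tail (see above).
* The weighted-LCA stand-in is single-pass; it is validated against an
  exhaustive oracle of its own definition, not against the desktop tool.
* ANCOM is implemented in its two-group rank-sum form only.
* Greedy clustering is O(sequences × clusters) alignments; for inputs far
  beyond ~10⁴ unique sequences a prefilter would be needed.
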