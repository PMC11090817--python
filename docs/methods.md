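# Methods

This note documents the statistical procedures the package implements, the
synthetic data model used to validate them, the numerical conventions, and
the known limitations.  It is the package's own account; every empirical
number cited here is computed by the test suite or `scripts/acceptance.py`.

## 1. Transfer-event detection

**Input.** Per gene family: a rooted gene tree with branch lengths and
branch supports, and a set of DTL reconciliation replicates (tabular:
gene-tree node → event type, mapped donor and recipient species-tree
nodes), grouped by optimal root.

**Aggregation.** Replicates from all optimal roots are pooled into a
single denominator — the simplest reading of "aggregating across optimal
roots", since nothing suggests per-root weighting.  A node's support
fraction is (replicates flagging it as a transfer) / (total replicates).
Retained events need support ≥ 0.8 (inclusive) and minimum branch support
≥ 0.5 (inclusive) over the gene-tree paths between their left- and
right-descendant leaves; the minimum over all left×right leaf-pair paths is
used, which equals the minimum over the spanning subtree.  Families with
more than 50 optimal roots are excluded entirely.  Multifurcations
(nodes with > 2 children) containing 100%-identical genes from different
species are emitted as events regardless of replicate support; sequence
identity is an upstream input (a precomputed identity-pair list), not
recomputed here.

**Donor/recipient sets.** The species leaves descending from the mapped
species-tree nodes, restricted to species actually present in the family.
When replicates disagree on the mapping of a retained node, the most
frequent (donor, recipient) pair is used.

**Distances.** An event's mean gene (species) distance is the arithmetic
mean of patristic distances over all left×right descendant gene (species)
pairs; gene pairs with alignment overlap < 50% are excluded from the gene
mean only.  If every gene pair is filtered out the gene distance is
undefined and the event is kept but excluded from gene-binned analyses.

**Pair counts.** Each event increments each of its (donor leaf, recipient
leaf) OTU pairs at most once per gene family, so nested or repeated calls
within a family never double-count a pair.  The count matrix is symmetric
with a zero diagonal by construction.

## 2. Matched subsampling

Two groups are reduced to a common covariate distribution: equal-width bins
(default 80 per covariate; a 2-covariate spec forms a bin grid) over the
pooled min–max range, right-open except the last bin; within each bin the
larger group is randomly downsampled (without replacement, seeded) to the
smaller group's count.  Quantile binning is available as an option.

Two deliberate conventions: (i) bin edges come from the *pooled* range, not
per-group ranges; (ii) the records carrying each covariate's pooled
extremes are always retained when their bin survives, and the realized bin
grid is cached on the `MatchSpec`.  Together these make re-matching a
matched pair of groups an exact no-op; without the cached grid, dropping an
extreme value would shift the recomputed bin edges and idempotence could
fail through boundary effects alone.

Matched outcome distributions are compared with the Mann–Whitney U test:
exact null distribution when n_a·n_b ≤ 10,000 and the pooled sample is
tie-free, otherwise the normal approximation with tie correction (average
ranks).

## 3. Pangenome ubiquity

Ubiquity = genomes carrying the family / genomes in the species; species
with fewer than 10 genomes are excluded.  Classes: extended core (≥ 0.90),
cloud (≤ 0.15), shell (otherwise); both boundaries inclusive, so the
classes partition (0, 1].  In a transferring pair the higher-ubiquity
species is the putative donor; exact ties are left unassigned rather than
broken at random.  The transferred-vs-cloud 2×2 table is tested with the
two-sided Fisher exact test (p = sum of hypergeometric probabilities of
tables no more likely than observed — the common convention); the reported
odds ratio is the sample cross-product, with ∞/0 sentinels for zero cells.

## 4. Functional enrichment grid

Species-distance bins 1–3 are equal thirds of [0.08, 2.00]; gene-distance
bins are a (0.50, 0.75], b (0.25, 0.50], c (0.00, 0.25], d (0.00, 0.05] and
e (0.00, 0.01], with d ⊂ c and e ⊂ d, so a recent event contributes to up
to three cells.  An event is annotated to a category when its gene family
is (family annotations are the union over member genes; multi-label, no
normalization).  Each (cell, category) is tested with a two-sided exact
binomial test of k annotated among n events against the background
fraction = annotated assessed families / all assessed families.
Holm–Šidák step-down adjustment is applied across all (cell × category)
tests of a run by default ("global" family); a per-cell family is exposed
as an option since the original analysis does not state its family.

## 5. Co-occurrence and phylogenetic correction

Presence: relative abundance ≥ 10⁻⁴ (0.01%, inclusive).  Co-occurrence of
a pair is the number of shared samples divided by the sample count of the
less prevalent OTU — a conditional prevalence in [0, 1].  Eligibility:
focal OTUs exchanged ≥ 1 gene with ≥ 30 partners; pairs require both OTUs
in ≥ 20 samples (all boundaries inclusive).

The CO–PD decay is modelled as CO ≈ k·PD^a by nonlinear least squares on
the natural scale, initialized from the OLS slope/intercept of log CO on
log PD over CO > 0 pairs; pairs with PD = 0 are excluded; k is constrained
positive, a unbounded.  Residuals are natural-scale (CO − k·PD^a);
log-scale residuals are an option.  Per focal OTU the power law is fitted
over that OTU's transfer partners, and Spearman correlations (average
ranks for ties) of counts with raw CO (pre-correction) and residuals
(post-correction) are computed; the background shuffles counts *within
each focal OTU's partner list* (the conservative reading of shuffling "the
number of genes") before correlating.  Distributions are compared with the
two-sided Mann–Whitney U test.

The multi-transfer cutoff is the nearest-rank 80% quantile of counts among
pairs with ≥ 1 transfer.  Interaction enrichment consumes an external edge
list (network learning is out of scope): pairs with score > 0 are
interacting, and the fold is the ratio of interacting-pair counts between
the multi-transfer and low-transfer matched sets (matched simultaneously
on PD and CO with an 80×80 bin grid).

## 6. Abundance tiers and generalism

Preferred habitat is the argmax of the four per-environment mean
abundances; all-zero profiles and exact ties are excluded.  Tiers use the
OTU's mean abundance in its preferred environment: strictly above that
environment's 80% quantile → high, strictly below the 20% quantile → low.
Quantiles use linear interpolation (numpy default): with 10 distinct
values this yields exactly two high and two low OTUs under the strict
inequalities, which the nearest-rank convention would not.

Tier curves: pairs sorted by phylogenetic distance into 20 equal-count
bins (the bin count is this package's choice); per bin, the fraction of
pairs with ≥ 1 transfer with a Bernoulli error band √(p̂(1−p̂)/n).  The
high–high > high–low > low–low ordering is tested with one-sided Wilcoxon
rank-sum tests on the per-bin fraction vectors, Benjamini–Hochberg
corrected across the three comparisons × four environments.

Generalism: Shannon entropy (natural log, 0·ln 0 = 0) of the normalized
four-environment mean-abundance profile; range [0, ln 4]; the normalized
version entropy/ln 4 is reported alongside.  Normalization is required for
entropy to be a distribution summary, and makes the index scale-invariant.
Per environment, the top/bottom n (default 200) OTUs by entropy are
generalists/specialists, with deterministic lexicographic tie-breaks;
specialists are drawn from OTUs not already selected as generalists.

Inter-environment matrices: for each group (all, generalists, specialists)
and each of the 10 unordered environment-pair cells, pairs are subsampled
so every (group, cell) shares one phylogenetic-distance histogram (the
elementwise minimum of all cell histograms over 20 equal-width bins).  The
statistics mean, s.d. and range (max − min, as "range" is otherwise
undefined) are taken over the 10 cells.  The background re-subsamples the
all-species pairs to the same distance target n_background times (default
1000); a normal distribution is fitted and Z = (observed − μ)/σ.  By
construction the all-species group evaluated against its own background
has Z ≈ 0, which the calibration test verifies (|mean| < 0.35, s.d. in
[0.6, 1.4] over 100 replicate draws).

## 7. The synthetic world

The generator is a stand-in for reference pangenome databases and
large environmental-sample collections; the real study analyses empirical
data and prescribes no generative model, so every choice here is a
fabrication designed only to give each stage a recoverable planted truth.

* **Species tree.** Yule topology with i.i.d. exponential branch lengths,
  rescaled to mean pairwise patristic distance 1.  Exponential branch
  lengths (rather than ultrametric split times) are essential: an
  ultrametric Yule tree concentrates almost all pairwise distances near
  twice the tree depth, leaving nothing to bin or fit against, whereas
  this model spreads pair distances over ≈ 0.1–2.3, covering the
  enrichment grid's species bins.
* **Abundance.** Each OTU carries a niche position evolved by Brownian
  motion on the tree (variance 1.8 per unit branch length, d dimensions
  with d = max(1, round(−2a))) and an environment-weight vector (1 for the
  preferred environment; 0.03 elsewhere for specialists, ~0.8–0.95 for
  generalists; specialist fraction 0.5).  Samples carry an environment
  (fractions 0.35/0.30/0.20/0.15 for animal/aquatic/plant/soil) and a
  niche coordinate ~N(0, 1.5²).  Presence is Bernoulli with probability
  0.95 · env-weight · exp(−Δ²/2w²), w = 0.15; present OTUs get lognormal
  abundances (per-OTU lognormal scale, median 2×10⁻³) floored at the
  presence threshold; columns are rescaled if they exceed 1.  Averaging
  the kernel over the Brownian niche offset gives
  E[CO] ∝ (1 + σ²PD/2w²)^(−d/2) — an asymptotic power law with exponent
  −d/2, so the planted exponent maps to the niche dimension; a = 0 turns
  niche divergence off entirely.  Fitting the power law to realized data
  at 300 species × 2000 samples recovers a = −0.5 with mean error ≈ +0.12
  (10 seeds): the finite-λ flattening and the chance-co-occurrence floor
  (≈ the larger OTU's prevalence) bias the fit slightly shallow, which is
  why the recovery tolerance is ±0.15 rather than tighter.
* **Transfers.** Pair counts are Poisson with
  log λ = log r₀ − 0.8·PD + β_res·(CO − k·PD^a) + β_ab·(hi_i + hi_j −
  lo_i − lo_j) + β_spec·[same-habitat specialist pair], defaults r₀ = 0.5,
  β_res = 4, β_ab = 0.4, β_spec = 1.  The residual uses a power-law fit to
  the realized abundance matrix, so the planted effect is defined exactly
  on the scale the pipeline measures.  Tier indicators come from the
  latent per-OTU abundance scale (top/bottom 20%).  Each transferred gene
  is its own gene family; one event per family keeps the family-pair
  deduplication exact and the truth counts equal to the Poisson draws.
* **Gene families.** Each event family gets a small gene tree: a transfer
  cherry (donor, recipient) whose two branches sum to the planted gene
  distance — so the pipeline's left×right mean recovers it exactly — with
  2–6 other species attached as a caterpillar; event-node supports are
  drawn in [0.65, 1] so true events always pass the branch-support filter
  (required for the exact-recovery invariant at zero noise), other
  supports in [0.4, 1].  Reconciliation replicates flag each true event
  with probability 1 − support_noise and add a spurious transfer at a
  random other node with probability support_noise.  Pangenome rows draw a
  ubiquity class (cloud probability 0.35 for non-transferred rows, odds
  multiplied by the planted odds ratio for transferred rows) and then an
  integer genome count uniformly within the class's valid range, so
  rounding can never cross a class boundary.  Annotations are independent
  Bernoulli per category (background 0.10) with planted per-(cell,
  category) multiplicative enrichments applied to event families.
* **Gene distances.** Drawn from a five-component uniform mixture spanning
  (0.001, 0.75] with weights 0.10/0.15/0.35/0.20/0.20, so every nested
  gene bin of the enrichment grid is populated.
* **Mapping.** One OTU per species by default; a many-to-one option
  (`species_per_otu`) groups consecutive leaves under a representative
  OTU.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-count compositionality and sampling depth;
phylogenetically conserved habitat preference (environment weights are
i.i.d., so the CO–PD decay is purely niche-kernel); correlated annotations
(real functional categories co-occur); gene-tree estimation error beyond
replicate flag noise; unequal genome sampling across species; rooting
ambiguity (multi-root exclusion is exercised only in unit tests).

## 8. Problem sizes and determinism

All stochastic steps derive their generators from a single integer seed;
identical (config, seed) produce bit-identical serialized worlds, and the
pipeline writes a manifest (version, parameters, seed, stage summaries)
that is identical across repeated runs on the same inputs.  The standard
study conditions used by the tests and the acceptance script are 200–300
species, 1000–2000 samples and 1500–5000 gene families with 10–100
reconciliation replicates; the analysis scripts default to 120 species,
600 samples and 5000 families with 50 replicates.  These sizes were chosen
so each planted effect is recovered with comfortable power while a full
run of every stage completes in minutes on a single CPU.

## 9. Known limitations

* The per-focal-OTU power-law fit can fail on degenerate partner sets
  (all-zero co-occurrence); such OTUs are skipped rather than imputed.
* The co-occurrence statistic's chance floor (min-conditional prevalence
  under independence) is not subtracted; at very low prevalence it
  compresses the fitted decay.
* Exact binomial cell tests are conservative at small cell counts; the
  null calibration (raw p ≤ 0.05 in ~4–5% of tests) reflects this
  discreteness.
* The interaction-network learner is out of scope; interaction analyses
  consume an externally supplied edge list, and the shipped demonstration
  uses published interaction counts as fixed inputs.
* Species-level donor/recipient direction relies on the ubiquity
  comparison and is unassigned on ties; no phylogenetic polarity is
  inferred.
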