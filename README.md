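# hgt-ecoscape

Eco-evolutionary analysis of horizontal gene transfer (HGT) in prokaryotes:
from gene-tree/species-tree reconciliation samples to the ecological factors
— co-occurrence, abundance, habitat generalism — that shape which species
exchange genes.

## The problem

HGT events can be detected by reconciling each gene family's tree with the
species tree under a duplication–transfer–loss (DTL) model.  Because DTL
reconciliation is ambiguous, it is run as many replicates per family (and
per optimal gene-tree root), and a transfer call is only trusted when a
large fraction of replicates agree and the gene tree's branch supports are
adequate.  Once events are in hand, ecological questions follow: are
transferred genes core or accessory within pangenomes?  Do recently and
anciently transferred genes carry different functions?  Do species that
co-occur in environmental samples — beyond what their phylogenetic
relatedness predicts — exchange more genes?  Do abundant species, or
habitat specialists, transfer more?

This package implements that full analysis chain as a tested library,
together with a synthetic-world generator that plants every effect the
pipeline is supposed to detect, so each stage can be validated against a
known ground truth without any external data download.

## Core statistics

* **Event aggregation** — a gene-tree node is a transfer event when flagged
  in ≥ 80% of pooled reconciliation replicates with minimum branch support
  ≥ 0.5 on the paths between its descendant gene pairs; families with more
  than 50 optimal roots are excluded; multifurcations containing
  100%-identical cross-species genes are events regardless of support.
* **Gene ubiquity** — fraction of a species' genomes carrying a family;
  extended core ≥ 90%, cloud ≤ 15%; transferred-vs-cloud composition tested
  by two-sided Fisher exact test.
* **Binned functional enrichment** — events placed on a species-distance ×
  gene-distance grid (gene distance as a proxy for time since transfer),
  each (cell, category) tested with a two-sided exact binomial test against
  the pipeline-wide background fraction, Holm–Šidák corrected.
* **Phylogenetic correction of co-occurrence** — co-occurrence
  CO = |samples with both| / |samples of the less prevalent OTU| is fitted
  per focal OTU as CO ≈ k·PD^a (nonlinear least squares, log–log
  initialization); residuals are Spearman-correlated with transfer counts
  and compared to a shuffled-count background by Mann–Whitney U.
* **Matched subsampling** — groups are equalized on one or two covariates
  (80 equal-width bins by default) by per-bin downsampling before any
  distribution comparison.
* **Abundance tiers and generalism** — per-habitat 80%/20% abundance
  quantiles define high/low tiers; Shannon entropy over the four habitat
  means defines generalists/specialists; inter-environment transfer
  fractions are computed on distance-equalized pair sets with Z-scores
  against a resampled all-species background.

## Worked example

The numbered scripts under `analysis/` run the full chain on a synthetic
world and write tables under `results/`:

```bash
python analysis/01_simulate_world.py --seed 1
python analysis/02_detect_transfers.py
python analysis/03_pangenome_ubiquity.py
python analysis/04_functional_enrichment.py
python analysis/05_cooccurrence.py
python analysis/06_abundance_generalism.py
```

With seed 1 this prints, among other lines:

```
retained events: 3419 (planted: 3419)
gene trees with >=1 supported transfer: 3419/5000 (68.4%)
cloud odds ratio (transferred vs not): 1.95 (p = 6.90e-120)
strongest signal: category P in species bin 1, gene bin c (enriched, ...)
global power-law fit: k = 0.072, a = -0.451
median Spearman rho: pre-correction 0.557, post-correction 0.471, background -0.003
post-correction vs background MWU p = 2.51e-17
  specialist mean  +1.89  sd  +3.93  range  +3.12
```

Reading these numbers: aggregation recovered every planted event despite
5% replicate noise; about two thirds of gene trees contain a supported
transfer; the Fisher odds ratio ≈ 1.95 recovers the planted cloud
enrichment (2.0); the planted 3× excess of category P among recent
transfers between close species is the strongest enrichment cell; the
fitted decay exponent ≈ −0.45 recovers the planted co-occurrence decay
(−0.5); corrected co-occurrence still predicts transfer counts far above
the shuffled background; and specialists show the elevated spread of
inter-environment transfer rates (positive s.d. and range Z-scores) that
the generator planted.

## Library layout

| module | contents |
| --- | --- |
| `hgt_ecoscape.trees` | Newick I/O, patristic distances, branch supports, Yule simulator |
| `hgt_ecoscape.events` | reconciliation aggregation, event distances, pair counts |
| `hgt_ecoscape.matching` | distribution-matched subsampling, Mann–Whitney comparison |
| `hgt_ecoscape.pangenome` | ubiquity classes, donor/recipient labels, Fisher test |
| `hgt_ecoscape.enrichment` | distance-bin grid, binomial tests, Holm–Šidák |
| `hgt_ecoscape.cooccurrence` | co-occurrence, power-law correction, interaction folds |
| `hgt_ecoscape.ecology` | habitats, tiers, entropy, inter-environment Z-scores |
| `hgt_ecoscape.synthetic` | the planted-truth world generator |
| `hgt_ecoscape.io` | TSV/Newick round-trips, validation, pipeline orchestration |

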