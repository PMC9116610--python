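# Methods

This note documents the models, statistics and design choices behind
`bmzone`, and what the synthetic-data generators do and do not emulate.

## Registry curation

Candidate basement-membrane (BM) zone genes carry boolean
localization-evidence flags. The evidence tiering is a pure function of
those flags:

* **confirmed** — `vertebrate_immunolocalization` is set;
* **predicted** — interaction with a verified BM/CSI protein, BM-cleaving
  protease activity, or an animal-model ortholog endogenously tagged and
  localized to the BM zone;
* **insufficient** — none of the above.

Ortholog tagging in an invertebrate model never promotes a gene to
*confirmed*: localization of a worm ortholog is evidence about the worm
protein, and human-tissue immunolocalization remains the confirmation
standard. A config switch could change this policy; it defaults off.

Genes flagged as GO misannotations are removed *before* the evidence
filter, so a misannotated gene is excluded even when its flags would
classify it as confirmed. The registry is symbol-sorted; symbols are
uppercased; ortholog lists are order-preserving and deduplicated. All
tables are UTF-8 TSV with a required header and `#` comments.

## Domain enrichment

For each species, each domain accession is tested for over-representation
in the BM gene set against the whole proteome with a one-sided
hypergeometric test on gene-level presence/absence: with K of N proteome
genes carrying the domain and k of the n BM genes carrying it,
p = P[X ≥ k], X ~ Hypergeom(N, K, n). Benjamini–Hochberg FDR control is
applied across domains at α = 0.05.

Presence/absence rather than copy counting avoids pseudo-replication from
tandem repeats (EGF-like domains occur in long arrays); copy counts are
retained descriptively, and the `count_ratio` (BM-set copies / proteome
copies) reproduces the dot-sizing statistic used in cross-species
enrichment displays. The conserved set requires enrichment in human plus
at least `min_species − 1` other species (default 3 of 5, human
mandatory); the threshold is configurable because no canonical cutoff
exists for this kind of species dot-grid.

## Domain-sharing network

Nodes are registry proteins; an edge joins two proteins sharing ≥ 1
enriched domain, weighted by the number of distinct shared accessions.
Degree counts partners. Betweenness centrality uses **unweighted**
shortest paths — the edge weight counts shared domains and is not a
distance (a weighted mode with distance = 1/weight exists but is off by
default, matching common network-analyzer conventions). Normalization is
2/((n−1)(n−2)) **per connected component** of size n ≥ 3 (smaller
components score 0), so scores remain comparable when the graph is
disconnected. Rankings break ties lexicographically by symbol so output
is reproducible.

## Expression signatures

Tissue profiles are clustered agglomeratively on Spearman distance
d = 1 − ρ. Constant profiles have undefined rank correlation; ρ is
defined as 0 there (d = 1) with a warning. Complete linkage is the
default (the default of `hclust` in R); average and single are
selectable. Dendrograms export to Newick with merge heights.

Per-gene expression variance is the sample variance (ddof = 1) across
tissues, computed on the values as provided; a log2(x+1) pre-transform is
available but off by default, and the choice is recorded in output
metadata because the appropriate scale for TPM-like data is a judgment
call. Quartile cutpoints use linear interpolation; a gene exactly at a
cutpoint takes the lower bin (low ≤ Q1 < medium ≤ Q2 < high ≤ Q3 <
very_high). Rows with missing values are dropped on import with a
warning. Cross-species bin overlap maps genes through an orthology table;
with one-to-many orthology a gene overlaps when **any** ortholog shares
the bin (permissive policy), and a Jaccard index is reported per focus
bin (low, very_high).

## Interactome and abundance composition

STRING-style combined scores are binned exactly on the published
confidence scale: lowest < 0.15 ≤ low < 0.4 ≤ medium < 0.7 ≤ high ≤ 0.9 <
highest (0.9 belongs to *high* because *highest* is strictly > 0.9). The
filtered network keeps pairs with score > 0.7 and reports the fraction of
input pairs in the high + highest bins along with registry proteins left
without any retained interaction.

Tissue abundance is ranked per tissue (dense descending ranks,
symbol-sorted ties) with node size log(1 + abundance); zero means not
detected. "Common" proteins are detected in every tissue **and** within
the top quartile of ranks in each tissue — an operationalization chosen
here since no quantitative cutoff accompanies the qualitative notion of
"abundant across all tissues"; the quantile is configurable. "Variable"
proteins have a coefficient of variation (over detected tissues only)
above the top decile of CVs among proteins detected in ≥ 2 tissues; a
protein qualifying as common is excluded from the variable set by
definition, so the two calls are disjoint.

## Cohort screen

Consequence classification: a variant is pLoF iff its annotation contains
one of the seven terms stop_lost, start_lost, stop_gained,
transcript_ablation, splice_acceptor_variant, splice_donor_variant,
frameshift_variant; any pLoF member of a multi-term annotation wins.
In-cohort minor allele frequency is recomputed from genotypes — alt
alleles / (2 × non-missing samples), folded — never trusted from input,
and the rarity bound is strict (MAF < 0.01). Qualifying variants for
burden are canonical rare pLoF.

The burden unit is the **individual**: a sample is a carrier when it
holds ≥ 1 qualifying genotype in the gene under the chosen zygosity mode
(homozygous by default). Each gene (or pooled tier of genes) yields a
2×2 table of affected/unaffected × carrier/non-carrier. The p-value is
the exact (two-sided) Fisher test. The reported odds ratio is the
cross-product with Haldane–Anscombe correction (+0.5 to all cells only
when a cell is zero) and a Wald 95% CI on the log scale; the
conditional-MLE OR with its exact CI is emitted alongside, since the
"epitools-style" interval convention is ambiguous across methods.
Missing genotypes never create carriers and leave MAF denominators.
Kinship among unaffected relatives is **not** modeled — a documented
limitation shared with carrier-count screens of heterogeneous cohorts.

Constraint flags follow the published gnomAD thresholds: pLI > 0.9 and
LOEUF < 0.2.

The high-penetrance filter passes a gene iff (a) every qualifying
variant (canonical, high-confidence LoF, rare) has ≤ 1 homozygote in
gnomAD, (b) no unaffected individual is homozygous for a qualifying
variant, and (c) ≥ 1 affected individual is; genes with ≥ 2 affected
homozygotes are prioritized. Note the filter nominates candidates — in
the shipped toy fixture a background gene passes by chance, which is the
expected behavior of a screen, not an error. Compound-heterozygote
candidates (het at ≥ 2 qualifying pLoF/missense variants, at least one
pLoF) are only *confirmed* in trans when phase information says so;
without phase they are flagged "possible", never asserted.

## Synthetic-data generators

Each generator is a pure function of (config, seed) drawing from its own
substream, so outputs are byte-reproducible and adding one generator call
never perturbs another. Planted truths are returned in machine-readable
form; recovery tests never hard-code expected values.

**Proteome.** 1000 genes, 300 domains per species. Background domains
follow a Zipf-like frequency law (exponent 1.2, 1 + Poisson(2) domains
per gene). The BM set (67 genes) contains five hub-side modules of 9
members (each sharing a module core domain), one bridge-side module of 20
members, a hub carrying one core from every hub-side module (degree 46 by
construction — above any member's attainable degree), and a bridge
carrying the cores of hub-side module 0 and of the bridge-side module.
The bridge-side module touches nothing else, making the bridge the sole
articulation point: it must mediate all ≈ 20 × 46 cross-paths, so its
per-component normalized betweenness (≈ 0.43) dominates the hub's
(≈ 0.2–0.33, diluted by the ubiquitous-domain and accessory-domain
shortcuts among hub-side modules). Planted enriched domains are the six
cores, one ubiquitous EGF-like domain (30% of hub-side members, 5%
background) and six accessory domains (9 members each, dealt round-robin
so no member carries more than ~2; 2% background — a ~7-fold planted
enrichment). Two decoy domains are enriched only in the worm table to
exercise the human-anchor conservation rule.

**Expression.** 400 genes × 12 tissues in two tissue blocks. Mid genes
prefer one block at 4-fold with log-normal noise (σ = 0.4). A quarter of
genes is near-constant (σ = 0.02; truth *low*); a quarter has its block
spread inflated 20-fold on the linear scale (truth *very_high*), so the
variance classes are separated by construction — baselines span a narrow
range (80–120) precisely so baseline differences cannot reorder classes.
This is a separation device, not a model of real TPM dynamics.

**Cohort.** 1000 affected + 1000 unaffected. Unaffected homozygous-
carrier probability per gene is 0.05; risk genes multiply the carrier
odds by the planted OR. The background rate is far above real per-gene
hom-pLoF rates: it is chosen so the 2×2 tables carry ~50 carriers per
arm, where the exact test's discreteness is mild — the generator is a
calibration instrument for the statistics, not a population-genetics
model (no LD, no site-frequency spectrum, no relatedness). Carriers are
spread over 60 distinct variants per gene so every variant stays under
the MAF < 0.01 bound. Planted extras exercise each filter: common-pLoF,
non-canonical and low-confidence decoy variants; two "novel" genes
passing every high-penetrance criterion (one prioritized); a decoy with
gnomAD homozygote count 5; a decoy with a planted unaffected homozygote;
and one phased compound-het pair (one trans, one cis) on dedicated
variants. A 160-sample toy configuration backs the shipped fixture
(regenerable bit-exactly from seed 17); its size is the smallest at which
a single homozygote stays below the MAF bound (2/320 = 0.00625).

**Interactions.** Scores drawn uniformly within each confidence bin's
range at configured mixture proportions (defaults put 20% in
high + highest, mirroring the sparsity of high-confidence interaction
data for BM proteins).

## What passing tests do and do not show

The generators plant exactly the structure each stage assumes:
over-represented domains, modular hub/bridge topology, quartile-separable
variance classes, carrier enrichment at a fixed odds ratio. Recovery at
the planted conditions validates the statistical machinery and the filter
logic — it does not certify performance on real proteomes (domain
co-occurrence is far more correlated), real expression atlases (variance
classes form a continuum), or real cohorts (relatedness, population
structure, annotation error). Problem sizes in the test-suite and in
`scripts/acceptance.py` (50–200 replicate seeds, 1000-gene proteomes,
2000-sample cohorts) were chosen as the smallest at which the measured
rates are stable to a few percent.

## Numerical choices

* Hypergeometric tails via `scipy.stats.hypergeom.sf(k−1, …)`; verified
  against big-integer enumeration in the tests.
* Fisher p via `scipy.stats.fisher_exact`; conditional-MLE OR via
  `scipy.stats.contingency.odds_ratio`.
* Quartiles: linear interpolation (`numpy.percentile` default); ties to
  the lower bin.
* Spearman distance clipped to [0, 2]; diagonal forced to 0.
* All rankings tie-break by symbol; all registry output symbol-sorted.
* Dendrogram tie cases (all-equal distances) follow scipy's deterministic
  merge order; heights are preserved, topology among ties is arbitrary
  but reproducible.

## Known limitations

* No kinship or population-structure correction in the burden screen.
* Phase is consumed, never inferred; unphased compound hets stay
  "possible".
* LoF-confidence (HC/LC) and canonical-transcript flags are input
  annotations; the package never recomputes them.
* Multiallelic VCF records must be pre-split upstream.
* The synthetic generators share none of the correlation structure of
  real data (see above); absolute rates measured on them do not transfer.
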