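# Methods

## The problem

2-D "population structure" plots (PCA, t-SNE, UMAP, neural embeddings) are
ubiquitous in genetics, but there is normally no ground truth against which
to judge whether the distances they show mean anything. `pedbench` builds
populations where the truth *is* known — because the full pedigree is
simulated — and scores each visualization by how well its pairwise
Euclidean distances correlate with ancestral distance.

## The simulated world

A forward-in-time diploid simulation with complete pedigree tracking.
Defaults (all configurable in `SimulationConfig`):

| parameter | default | meaning |
|---|---|---|
| `n_founders` | 100 | founding individuals, alleles i.i.d. Bernoulli(0.5) per haplotype |
| `n_generations` | 10 | discrete, non-overlapping generations |
| `n_snps` | 24 000 | biallelic SNPs, evenly spaced |
| `n_chromosomes` × `chrom_length_mbp` | 10 × 100 Mbp | genome layout (chromosome count is not dictated by the benchmark; 10 equal autosomes is our choice) |
| `recomb_rate` | 1 cM/Mbp | constant; 100 Mbp = 1 Morgan per chromosome |
| `migration_prob` | 0.3 | per subpopulation per generation: a random half emigrates to found a new, fully isolated subpopulation |
| `offspring_range_random` | 1–4 | per monogamous random pair (uniform, inclusive) |
| `offspring_range_assortative` | 2–8 | per pair of selected parents |
| `selection_fraction` | 0.5 | truncation selection on phenotype, within subpopulation |
| `n_qtn`, `h2` | 10, 0.5 | additive trait; effects ~ N(0,1); environmental SD calibrated on the realized founder genetic variance so Var(G)/Var(P) = h² in generation 0 |

Founder alleles are drawn per haplotype, not per site frequency, so any
terminal structure is created by drift, fission and selection alone. Under
random mating this leaves the mean allele frequency at 0.5 (drift is
symmetric) with a terminal MAF band of roughly 0.24–0.5; selection pushes
sites toward fixation and roughly doubles between-subpopulation F_ST
(≈0.08 → ≈0.16 in our replicates).

Meiosis uses the Haldane (no interference) model: crossover counts per
chromosome are Poisson(length in Morgans), breakpoints uniform in bp, the
transmitted strand starting from a fair coin and alternating at each
breakpoint. Individuals are sexless (any individual can act as either
parent, no self-mating); pairing is monogamous, uniform, without
replacement, within subpopulation; an odd leftover individual leaves no
offspring. Selection, like mating, is within subpopulation — demes are
reproductively isolated after fission. Migration acts on the current
generation before it mates; emigrants found a brand-new label, there is
never back-migration or admixture.

## Ground truth

* **Pedigree path distance** — shortest path in the undirected parent-child
  graph. Undirected so that collateral relatives (siblings: 2, half the
  terminal generation's close pairs) get finite distances; pairs in
  disconnected components are masked undefined and never scored.
* **Inverse expected IBD** — the numerator relationship matrix A by the
  Henderson tabular recursion (founders a_ii = 1, a_ii = 1 + ½a_sd,
  a_ij = ½(a_j,sire + a_j,dam)); distance = 1/a_ij with a_ij = 0 pairs
  masked rather than mapped to an arbitrary ceiling. A is validated
  against hand recursion on fixtures and a 200k-replicate gene-dropping
  Monte Carlo (tolerance 0.01).
* A stress-minimizing metric MDS of a fully defined truth matrix serves as
  the visual reference configuration; it is not a scored method.

In simulation mode all terminal pairs are connected through the founders,
so both truths are complete. In real-data mode (tabular ID/SIRE/DAM
pedigree + dosage table or VCF) only defined pairs are scored; whether
that is all connected pairs or only ascendant–descendant pairs is exposed
through the mask, with all connected pairs as the default.

## Embedding methods

PCA (first two components, arpack solver — exact leading components),
metric MDS, t-SNE and UMAP run at their library defaults (scikit-learn
and umap-learn; the resolved defaults are recorded in each result's
`hyperparams`), fed the raw {0,1,2} dosage matrix with no centering and no
PCA pre-reduction. The neural methods share one architecture — fully
connected 24000→256→128→2 — and train 100 epochs with Adam:

* **AE** (lr 1e-4): mirrored decoder ending in 3 logits per site;
  categorical cross-entropy against the dosage class.
* **VAE** (lr 1e-3): batch-normalized encoder/decoder, inputs scaled to
  [0,1], binary cross-entropy + KL to N(0, I), reparameterized sampling;
  the embedding is the posterior mean; no early stopping. A warning is
  emitted if the posterior hugs the prior everywhere (collapse).
* **Contrastive** (lr 1e-4): instance discrimination; positive = the
  anchor with homozygous sites flipped to heterozygous with p = 0.1,
  negative = a uniformly drawn different sample from the batch; cosine
  similarity on ℓ2-normalized 2-D embeddings, loss −log softmax. Because
  similarity is angular the embedding organizes on a ring.
* **Random projection baseline**: the same encoder, freshly initialized
  (He), never trained. Its correlation with ancestry (~0.04) is the floor
  every trained method must beat.

The networks are plain numpy + BLAS (float32) with hand-written backprop
and a numba-fused Adam step; no GPU framework is required. Fixed defaults
the benchmark does not dictate: ReLU activations, He initialization, batch
size min(256, n). We moved the batch default from 64 to 256 after
profiling: on one CPU at the default data scale the batch-64 fit spends
most of its time in memory-bound skinny matrix products (~190 s vs ~96 s
per VAE fit) while training curves and the resulting correlations are
indistinguishable (pedigree-D r 0.642 vs 0.647 on the same replicate,
published value 0.64 ± 0.21). Both embeddings-of-record decisions the
benchmark leaves open are resolved as: the VAE embedding is the posterior
mean (not a sample), and the contrastive embedding is learned directly in
2-D (not projected down from a higher dimension).

## Scoring

Pearson r between pairwise embedding Euclidean distance and ground truth,
over defined pairs only; the log2(D) column reuses the same embedding (no
re-fit), with zero distances clamped to the smallest positive normal
double so both columns always score identical pair sets. Pearson (not
Spearman) is deliberate: the benchmark asks whether distances are
*linearly* informative (or linearly after log), and is correspondingly
outlier-sensitive. F_ST is the multi-population Weir–Cockerham θ combined
as a ratio of sums across loci, monomorphic loci skipped — the estimator
of record where the benchmark's source delegated to an external popgen
routine. Per-site summaries report MAF, observed heterozygosity and a
1-df χ² Hardy–Weinberg test.

Methods are compared per (scenario, truth, transform) column with one-way
ANOVA followed by Tukey HSD at α = 0.05, summarized as a compact letter
display (insert-and-absorb; letters ordered by descending mean).
Replicate seeds derive from a single master seed through
`numpy.random.SeedSequence`, so every report is bit-reproducible.

## What a green test establishes — and what it does not

The synthetic generator emulates discrete-generation, island-fission
populations with complete pedigrees and clean biallelic genotypes. It does
not emulate: genotyping error or ascertainment bias, missing data, partial
or shallow pedigrees, overlapping generations, sexes, unequal founder
contributions, or continuous isolation-by-distance. Green acceptance tests
therefore establish that the implementation reproduces the published
simulation benchmark, not that any method will behave the same on a real
SNP array panel — the published real-dataset columns are intentionally out
of scope (they require external downloads).

## Numerical choices and degenerate inputs

* Zero embedding distance → clamped before log2 (see above); zero-variance
  distance vectors → r = NaN, excluded from aggregation.
* Subpopulations that cannot form a pair (size 1, or <2 selected) warn and
  leave no offspring; if no subpopulation can pair, simulation aborts with
  the generation named. F_ST drops subpopulations with fewer than 2
  members.
* Pedigree parity of meiosis is computed with a uint8 accumulator
  (mod-256 wraparound is parity-safe and ~50× faster than an int64 scan).
* The Henderson recursion is O(n²) vectorized over rows; its PSD property
  and diagonal bounds [1, 2] are asserted in tests.
* Ties in truncation selection are broken by stable sort order, making
  selection deterministic under a fixed seed.

## Known limitations

* The VAE/AE/contrastive results depend on initialization; replicate SDs
  on the neural columns are accordingly wide, matching the published
  spread.
* t-SNE/UMAP "library defaults" drift across library versions; the pinned
  environment and the recorded `hyperparams` metadata define what was run.
* The acceptance protocol uses 10 replicates (5 for the VAE) rather than
  the original 100, trading precision of the replicate means for runtime
  on a single CPU.
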