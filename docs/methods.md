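# Methods

## Data model

Genes are species-scoped canonical identifiers (`GeneID`): an opaque
token, integer-like by the NCBI Entrez Gene convention, paired with a
taxon label. Identifiers never compare equal across species, which
makes it impossible to mix species accidentally in set algebra —
cross-species combination must go through an explicit orthology map.

Gene sets (`GeneSet`) are immutable, species-homogeneous, named
collections living in a `/`-separated category tree rooted at `public`
(pre-compiled annotation) or `private` (user inputs and every derived
result). All operations deposit their output under `private`; the
`public` subtree is read-only at the user surface. Each set carries a
provenance trail of operation descriptors so derived sets can be
replayed.

Identifier conversion (`convert_ids`) matches aliases
case-insensitively after whitespace trimming, against a multimap that
may hold several canonical genes per alias. Ambiguous aliases
contribute *all* their candidates and are flagged in the conversion
report rather than dropped: silently losing genes would bias the
effective input size `n` of every downstream test, whereas a flagged
extra gene is visible and removable. Duplicate inputs collapse
silently but are counted.

## Orthology mapping

An `OrthologyMap` is a many-to-many bipartite relation between exactly
two species. Mapping a set takes the union of all counterparts of all
mapped genes: one-to-many genes expand (both in-paralogs are kept by
default — the `best-one` policy keeps the token-first ortholog for
users needing size-preserving maps), many-to-one genes dedupe, and
genes without orthologs are dropped and listed, never passed through
untranslated. `map_set` is therefore a union-homomorphism
(`map(A∪B) = map(A) ∪ map(B)`) but only sub-distributes over
intersection, which the tests check on random maps.

### Coverage survey

`annotation_coverage` counts inventory genes appearing in ≥ 1 set of an
annotation type; `orthology_gain` counts target-species genes that lack
native annotation of a type but have ≥ 1 ortholog carrying it in a
source species. The combined gain across source species is the
*union* of the per-source gains (a gene reachable from two organisms
counts once); the plain sum is reported alongside, and the two
coincide exactly when contributions are disjoint. Percentages are
rounded half-up to one decimal, matching the convention of published
coverage tables.

`crossgsa.survey` reconstructs a published seven-species survey from
its printed counts: inventories are integer token ranges, each
annotated block a segment sized by the published number, and ortholog
pairs are wired so each model organism contributes exactly its
published human gain block. Two layout constraints matter. First, the
human phenotype and PPI blocks nest inside the all-annotation block so
pooled ("any") coverage equals the printed total. Second, within each
model organism the phenotype and PPI blocks are kept disjoint so a
PPI-derived gain cannot leak into the phenotype gain; yeast's
inventory (6,353) is smaller than its phenotype + PPI counts
(5,620 + 5,479), so there disjointness is impossible and the PPI-gain
partner genes are drawn only from the 733 phenotype-free PPI genes.
The memberships are synthetic stand-ins — only the counts are
published data — so the survey validates the counting, union and
rounding arithmetic, not the identity of any particular gene.

## Networks

`MolecularNetwork` stores typed edges: `pp` (protein-protein,
undirected — endpoints canonically sorted, so loading both
orientations yields one edge), `tf` and `mirna` (directed,
regulator first). The same node pair may carry edges of several types.
miRNA regulators live in a separate node namespace: they are traversed
(two genes co-targeted by one miRNA are two hops apart) but never
exported into gene sets, since the enrichment statistics are
gene-based.

`expand` grows a seed set breadth-first within a hop budget over the
selected relation types; for directed relations the `downstream` /
`upstream` / `both` policy decides which arrows may be followed. The
default spec is one hop over PPI, direction `both` — the single-step
expansion used in typical interactive workflows; deeper expansion is
available but must be explicit. Seeds absent from the network are kept
(expansion never loses genes). `hops=0` is allowed and expands
nothing, which gives `seed_components` a pure adjacency mode: seeds
are partitioned by connectivity in the subgraph induced on the seeds
plus everything reachable within the hop budget, so reached
non-seed nodes act as intermediates and isolated seeds come back as
singletons. Interactive node deletion maps to set difference before
`to_gene_set`; no interactive state exists.

## Enrichment

The hypergeometric upper tail is evaluated through the survival
function of `scipy.stats.hypergeom` (log-space internally), floored at
1e-300 so `-log10` stays finite in exports; `k = 0` returns exactly 1.
The tests compare it against an independent exact oracle — big-integer
binomial counting, and at tiny N literal enumeration of all C(N,n)
draws — over every (N, K, n, k) with N ≤ 60; the observed worst
relative error is ~9·10⁻¹⁶.

Cohen's kappa is computed from the 2×2 membership table over the
universe (`po = (a+d)/N`, `pe = [(a+b)(a+c)+(c+d)(b+d)]/N²`,
`κ = (po−pe)/(1−pe)`) and reported per row; it is *not* used for
ranking or the default significance call, and is NaN when `pe = 1`
(both margins degenerate). The association-graph threshold can be
switched from q to kappa.

Benjamini-Hochberg adjustment is implemented directly because the
family size `m` may exceed the number of listed p-values: zero-overlap
tests belong to the family (their p = 1) but are excluded from the
ranked report, where they would only add noise. The step-up value is
clamped to `max(q, p)` — mathematically BH dominates p, but
`p·m/m` in floating point can round one ulp below `p`. Where the full
family is listed, the implementation is cross-checked against
`statsmodels.stats.multitest.multipletests`.

Each private set forms its own BH family over all public sets of the
selected annotation types. Ranks are assigned by ascending p, then
descending overlap, then ascending public-set size, then public-set
name — a total order, so identical inputs produce byte-identical
result tables.

### Universe policy

The background N is the choice that moves every p-value. The default
(`annotated`) uses the genes annotated in ≥ 1 set of the selected
types — standard ORA practice, since genes that cannot be annotated
cannot be drawn; `all-genes` uses the species inventory; any explicit
gene collection is accepted. Input genes outside the universe are
dropped from `n` and reported. Published case-study p-values depend on
the (external, unstated) universe and annotation content behind them
and are therefore not re-derivable from their printed rows; the
published tables are used for structural checks (rank layout, q-cut
filter counts) only.

## Synthetic data

The generators exist so every operation is testable offline, at study
conditions chosen to mirror a small-GWAS-input scenario: a 10,000-gene
inventory, 500 public sets with log-uniform sizes between 10 and 300
(mimicking the right-skewed term-size distribution of real functional
vocabularies), orthology covering 60 % of genes with a 20 %
one-to-many rate, a 2,000-edge uniform random PPI network, and a
planted input of 5 genes with 3 inside a 22-gene target set — the
overlap geometry of a published top-ranked case hit. All randomness
flows from one integer seed through named `numpy` generator streams,
so artifacts are individually reproducible; the planted contingency is
exact by construction, which the enrichment path recovers verbatim.

What the generator does *not* emulate: term nesting and the GO DAG
(sets are drawn independently, real annotation sets are strongly
correlated), degree heterogeneity of real PPI networks (hubs), biased
ortholog coverage, and identifier noise. Passing tests therefore
demonstrate the correctness of the machinery and its detection power
under independence — not calibration on any real corpus.

The power study (100 seeded replicates at the conditions above)
requires the planted target at rank 1 with q < 0.01 in ≥ 95 % of
runs; the measured power is 100 %, consistent with the planted
p ≈ 10⁻⁷ against a 501-test family.

## Numerical and formatting choices

* percentages: half-up rounding to one decimal (`decimal.Decimal`),
  never banker's rounding;
* p/q-values in text output: scientific notation with two significant
  digits (`9.6E-08`); the reader also tolerates the dotted
  `9.6.E-08` style found in older printed tables;
* writers emit canonical order (sets by category and name, genes by
  numeric-aware token order, PPI endpoints sorted), making write∘read
  the identity on canonical files and all outputs diffable;
* empty gene sets are legal everywhere except as enrichment input
  after universe restriction, which is an error rather than a silent
  empty report.

## Known limitations

* Enrichment is overlap-based ORA; no rank-based or sample-level
  statistics.
* Orthology input is a pre-filtered pair list; no confidence scores or
  ortholog inference.
* The set-association graph is exported (SIF + edge attributes), not
  rendered.
* One species pair per ortholog file; multi-species mapping is a loop
  over maps.
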