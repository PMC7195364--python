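# Methods

## The sorting model

The unit of evidence is the orthogroup: a set of genes across species
predicted to descend from one ancestral gene. The species ladder abstracts
a rooted phylogeny into ordered rungs — rung 1 is the focal species alone,
each higher rung the next-more-distant clade — so "a gene's age" becomes
"the deepest rung at which its orthogroup shows the relevant signal".
Two signals are used:

* **Origin (single-copy genes).** Presence of any ortholog at a rung is
  evidence the gene existed in that rung's common ancestor. The age is the
  deepest rung with at least one ortholog-bearing species. This is
  phylostratigraphy restricted to orthogroup membership rather than raw
  homology hits, which suppresses spurious deep assignments from partial
  matches.

* **Duplication timing (multi-copy genes).** If the focal species carries
  *n* ≥ 2 copies, a species that also carries exactly *n* copies is
  evidence the duplication predates their split. Scanning rungs oldest to
  youngest, the age is the oldest rung with such a copy-number match; no
  match anywhere dates the duplication after the most recent split
  (rung 1).

* **WGD.** Ohnolog pairs retained from a whole-genome duplication are a
  single cohort with its own label, taken from an explicit input list.
  Inferring ohnologs (synteny analysis) is out of scope; for species with
  no recent WGD the group is simply absent.

Assumptions worth stating: orthogroup inference is trusted as given;
copy-number matching treats each non-focal species independently (no
clade-level aggregation — the evidence the rule needs is one species that
preserved the ancestral post-duplication count); and a gene absent from
every orthogroup is treated as a measured species-specific singleton
rather than an error, since orthology tools routinely leave young genes
unassigned.

### Tie-breaking between sorting rules

Loss can make copy numbers fluctuate across rungs (e.g. match at rungs 2
and 4 but not 3). The default `oldest` rule takes the deepest match — it
maximally back-dates the duplication and is robust to losses *between*
the duplication and the present. The alternative `youngest_contiguous`
rule only extends the date through an unbroken run of matching rungs from
rung 2 upward, which refuses to jump over non-matching rungs and is
therefore more conservative when deep matches might be convergent
(independent duplication in an outgroup). Both are exposed
(`--dup-rule`); neither is asserted to be uniquely correct, and on
loss-free histories they agree.

The non-core criterion is likewise a documented choice: the default
(`--noncore-mode any`) drops a gene from the core genome when *any* query
species lacks an ortholog; `all` requires absence everywhere. The default
matches the strict reading of core-genome membership — a core gene is one
conserved across the whole species panel.

## Statistics

* **DE flag:** |log2FC| > 1 and FDR < 0.01, both strict inequalities.
  The flags are monotone in the cutoffs (relaxing either never removes a
  flag).
* **Normalized enrichment ratio:** `(de_g/n_g)/(de_total/n_total)`. The
  identity Σ_g (n_g/n_total)·ratio_g = 1 holds on every input and is
  asserted in tests. When `de_total = 0` the ratio is undefined and
  reported as NaN, with rows still emitted.
* **Fisher test:** each group against all other measured genes,
  two-sided, via `scipy.stats.fisher_exact`; the test suite checks it
  against an exact rational-arithmetic enumeration of all tables with the
  observed margins (agreement to 1e-9 absolute on random tables with
  margins ≤ 30). Raw p-values are the primary statistic;
  Benjamini–Hochberg-adjusted values across the groups of one condition
  are emitted alongside because several groups are tested per condition.
* **Replicate filter:** relative standard deviation sd/mean per condition
  with the sample (n−1) standard deviation; genes with RSD > 1 in any
  compared condition, or zero mean (undefined RSD), are removed. At least
  two replicates are required.
* **TPM:** `1e6 · (count/length) / Σ(count/length)` per sample; columns
  sum to 1e6 by construction (relative tolerance 1e-6 in tests).
* **Median CI:** percentile bootstrap, default 10000 resamples,
  deterministic given a seed. Coverage for the median of n = 50 normal
  samples is verified empirically to sit at the nominal 95% ± 2%.
* **Adaptation rate:** `(100 − %identity)/divergence_myr` against the
  best congeneric hit (max bitscore, ties by identity then subject id).
  Best hits under bitscore 50 are excluded by default — below that the
  "closest homolog" premise is doubtful; the floor is configurable.
  Identity is taken from the hit table (BLAST's alignment-length
  convention); the optional internal global-alignment identity divides
  matches by alignment columns including internal gaps (terminal
  overhangs excluded), a deliberately stricter dialect for FASTA-pair
  input on small data. Divergence times are user-supplied; no molecular
  dating is performed.

## The simulator

`simulate_gene_histories` emulates exactly the structure the sorting
rules read: each family draws an origin rung (default uniform across
rungs), duplicates at most once with probability 0.3 at a rung uniform
between origin and present, and is present at copy number 1 (2 from the
duplication rung downward) in every species from its origin rung to the
present, minus independent per-species losses at `loss_rate` (default 0;
the focal species never loses genes, keeping all truth genes measurable).
One duplication per family keeps the copy-number dating rule's ground
truth unambiguous; multi-duplication histories are an extension, not the
default. `simulate_expression` plants DE with a per-age-rung probability
(default 0.1 everywhere, i.e. a null); DE genes draw |log2FC| ≥
`lfc_magnitude` (default 2, always > the cutoff 1) and FDR < 0.01,
non-DE genes FDR ≥ 0.01, so the DE filter recovers the planted truth
exactly and any disagreement downstream is attributable to the sorting,
not the filter.

Determinism: all draws come from seeded numpy generators, genes in index
order, rungs oldest to youngest; loss indicators occupy a fixed position
in the stream, so runs differing only in `loss_rate` have nested loss
sets and recovery accuracy is non-increasing in the rate for a fixed
seed.

What the simulator does **not** emulate: incomplete or erroneous
orthogroup inference (fusion/fission of groups), multiple duplications,
gene conversion, unequal rung occupancy of real species panels, count
noise (DE tables are generated at the summary level, not via read
counts), and correlated DE across conditions. Passing tests therefore
demonstrate that the sorting and statistics are correct *given* faithful
orthogroups, not that orthology inference itself is reliable.

## Problem sizes and numerical choices

Validation runs use genomes of 500–5000 families on a five-rung ladder
with two species per non-focal rung, 1000 replicate genomes for null
calibration and 1000 bootstrap-coverage replicates — sizes at which the
binomial noise on every checked quantity is far below the asserted
tolerances. Default ladder divergence times (0, 20, 120, 325, 420 Myr)
loosely follow a budding-yeast panel from the genus split out to
filamentous fungi. Degenerate inputs are defined rather than left to
chance: empty Fisher margins give p = 1, single-value or constant
bootstrap input collapses the CI to a point, empty age groups yield n = 0
rows with NaN summaries, and a gene in no orthogroup has copy number 1
and age rung 1.

## Known limitations

* Age resolution is bounded by the ladder: everything older than the
  deepest rung collapses into the oldest group.
* The duplication rule dates the *latest* event compatible with the
  copy-number evidence and cannot separate repeated duplications.
* Identifier reconciliation between proteome and transcriptome is the
  caller's responsibility; mismatched ids surface as validation errors,
  not silent drops.
* Enrichment treats genes as exchangeable within groups; co-regulation
  (operon-like clusters, shared promoters) would narrow the effective
  sample size and is not modelled.
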